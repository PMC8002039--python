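import numpy as np
import pytest

import fesdcm as fd
from fesdcm.inversion import InversionSettings


@pytest.fixture(scope="session")
def standard_paradigm():
    """The full 10-minute block paradigm (TR 3 s, 200 volumes)."""
    return fd.build_paradigm(3.0, 600.0, 9.0, 21.0, 4, seed=1)


@pytest.fixture(scope="session")
def short_paradigm():
    """A 4-minute run (8 ON blocks, 80 volumes) for fast inversion tests."""
    return fd.build_paradigm(3.0, 240.0, 9.0, 21.0, 4, seed=1)


@pytest.fixture(scope="session")
def control_model():
    return fd.default_control_model()


@pytest.fixture(scope="session")
def hemo():
    return fd.HemodynamicParams()


@pytest.fixture(scope="session")
def fast_settings():
    """Inversion settings used in cohort-scale studies: prediction
    integrated at tr/8 (deviation from the tr/16 generation grid is ~3e-4
    percent signal, far below the measurement noise)."""
    return InversionSettings(microtime_dt=3.0 / 8.0)


@pytest.fixture(scope="session")
def short_session(short_paradigm, control_model, hemo):
    """One noisy synthetic session on the short paradigm (SNR ~2)."""
    inputs = fd.build_inputs(short_paradigm)
    clean = fd.simulate_bold(control_model, hemo, short_paradigm, inputs)
    sd = float(np.mean(clean.std(axis=1))) / 2.0
    rng = np.random.default_rng(7)
    return clean + rng.normal(0.0, sd, clean.shape), clean, sd
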