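"""Experimental paradigm: block timing and experimental input timelines.

The motor task is a 2x2 factorial block design (volitional intention x
functional electrical stimulation) performed as alternating rest (OFF) and
task (ON) blocks within a single continuous run.  Three experimental input
timelines are derived from the condition schedule:

* ``V`` -- descending volitional drive, on during the two conditions that
  require voluntary effort (``vol+FES`` and ``vol``);
* ``E`` -- ascending electrical-stimulation contribution, on during the two
  stimulated conditions (``vol+FES`` and ``FES``);
* ``P`` -- proprioceptive afference from any movement, on during all four
  conditions.

Inputs are sampled on a fine "microtime" grid (default ``tr/16``) so that
they can drive the neural ODE between scan acquisitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import floor

import numpy as np
import pandas as pd

#: canonical condition labels of the 2x2 design
CONDITIONS = ("vol+FES", "FES", "vol", "passive")

#: movement pacing interval within ON blocks (seconds)
PACE_INTERVAL = 3.5

INPUT_LABELS = ("V", "E", "P")

#: which conditions each input is active in
_INPUT_CONDITIONS = {
    "V": {"vol+FES", "vol"},
    "E": {"vol+FES", "FES"},
    "P": {"vol+FES", "FES", "vol", "passive"},
}


@dataclass(frozen=True)
class Paradigm:
    """Timing of one scanning run.

    ``block_schedule`` lists ON blocks only, as ``(onset_s, duration_s,
    condition)``; OFF blocks are the gaps between them.
    """

    tr: float
    run_duration: float
    n_volumes: int
    block_off: float
    block_on: float
    pace_interval: float
    conditions: tuple
    block_schedule: tuple
    microtime_dt: float

    @property
    def n_bins(self) -> int:
        return int(round(self.run_duration / self.microtime_dt))

    @property
    def bins_per_volume(self) -> int:
        return int(round(self.tr / self.microtime_dt))

    def to_json(self) -> str:
        return json.dumps(
            {
                "tr": self.tr,
                "run_duration": self.run_duration,
                "n_volumes": self.n_volumes,
                "block_off": self.block_off,
                "block_on": self.block_on,
                "pace_interval": self.pace_interval,
                "conditions": list(self.conditions),
                "block_schedule": [list(b) for b in self.block_schedule],
                "microtime_dt": self.microtime_dt,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Paradigm":
        d = json.loads(text)
        d["conditions"] = tuple(d["conditions"])
        d["block_schedule"] = tuple(
            (float(o), float(du), str(c)) for o, du, c in d["block_schedule"]
        )
        return cls(**d)

    def onsets_table(self) -> pd.DataFrame:
        """ON-block onsets as a 3-column table (onset, duration, condition)."""
        return pd.DataFrame(
            self.block_schedule, columns=["onset", "duration", "condition"]
        )


@dataclass(frozen=True)
class InputTimeline:
    """One experimental input sampled at microtime resolution over the run."""

    label: str
    values: np.ndarray
    dt: float

    def __post_init__(self):
        if self.label not in INPUT_LABELS:
            raise ValueError(f"unknown input label {self.label!r}")
        if np.any(self.values < 0):
            raise ValueError("input values must be nonnegative")


def build_paradigm(
    tr: float = 3.0,
    run_duration: float = 600.0,
    block_off: float = 9.0,
    block_on: float = 21.0,
    n_conditions: int = 4,
    seed: int = 0,
    microtime_dt: float | None = None,
) -> Paradigm:
    """Construct an alternating OFF/ON block paradigm.

    Conditions are allocated to ON blocks in balanced counts (equal blocks
    per condition) with a seed-reproducible pseudo-random order.

    Raises
    ------
    ValueError
        If ``run_duration`` is not a whole number of OFF+ON block pairs, or
        the pair count is not divisible by ``n_conditions``.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    pair = block_off + block_on
    if pair <= 0:
        raise ValueError("block_off + block_on must be positive")
    n_pairs_f = run_duration / pair
    n_pairs = int(round(n_pairs_f))
    if abs(n_pairs_f - n_pairs) > 1e-9 or n_pairs < 1:
        raise ValueError(
            f"run_duration={run_duration} s is not an integer multiple of the "
            f"{pair} s OFF+ON block pair"
        )
    if n_pairs % n_conditions != 0:
        raise ValueError(
            f"{n_conditions} conditions do not divide {n_pairs} ON blocks evenly"
        )
    conditions = CONDITIONS[:n_conditions]
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_conditions), n_pairs // n_conditions)
    labels = rng.permutation(labels)
    schedule = tuple(
        (k * pair + block_off, block_on, conditions[labels[k]])
        for k in range(n_pairs)
    )
    if microtime_dt is None:
        microtime_dt = tr / 16.0
    return Paradigm(
        tr=float(tr),
        run_duration=float(run_duration),
        n_volumes=floor(run_duration / tr),
        block_off=float(block_off),
        block_on=float(block_on),
        pace_interval=PACE_INTERVAL,
        conditions=conditions,
        block_schedule=schedule,
        microtime_dt=float(microtime_dt),
    )


def build_inputs(
    paradigm: Paradigm,
    encoding: str = "boxcar",
    event_duration: float = 1.0,
) -> tuple[InputTimeline, InputTimeline, InputTimeline]:
    """Derive the V, E, P input timelines from the condition schedule.

    ``boxcar`` marks the full ON block; ``event`` places unit pulses of
    ``event_duration`` seconds at the movement-pacing interval within each
    ON block.  Amplitude is 1 (dimensionless); scaling is absorbed by the
    driving/modulatory matrices of the connectivity model.
    """
    if encoding not in ("boxcar", "event"):
        raise ValueError(f"unknown encoding {encoding!r}")
    n = paradigm.n_bins
    dt = paradigm.microtime_dt
    values = {lab: np.zeros(n) for lab in INPUT_LABELS}
    for onset, duration, cond in paradigm.block_schedule:
        if encoding == "boxcar":
            spans = [(onset, duration)]
        else:
            n_events = int(floor(duration / paradigm.pace_interval))
            spans = [
                (onset + k * paradigm.pace_interval, event_duration)
                for k in range(n_events)
            ]
        for lab in INPUT_LABELS:
            if cond not in _INPUT_CONDITIONS[lab]:
                continue
            for t0, du in spans:
                i0 = int(round(t0 / dt))
                i1 = min(int(round((t0 + du) / dt)), n)
                values[lab][i0:i1] = 1.0
    return tuple(
        InputTimeline(lab, values[lab], dt) for lab in INPUT_LABELS
    )


def input_matrix(timelines) -> np.ndarray:
    """Stack timelines into an (n_bins, m) array ordered as (V, E, P)."""
    order = {t.label: t for t in timelines}
    return np.column_stack([order[lab].values for lab in INPUT_LABELS])
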