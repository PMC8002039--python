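"""Synthetic cohorts with the statistical structure the analysis assumes.

Generates ground-truth connectivity per subject-session as

    theta_i = group mean + CE_i * theta_CE + t_i * theta_t + CS_i * theta_CS
              + between-subject Gaussian noise,

then simulates BOLD through the generative model and adds white measurement
noise.  Defaults mirror the study conditions: 16 controls with one session,
8 patients with PRE and POST sessions, CE/nCE labels, capacity scores on
the clinical-table scale (~8-25 raw units), and the standard 10-minute
block paradigm (TR 3 s, 200 volumes).  Patients' PRE and POST sessions
share the subject-level random effect, so session differences are driven
only by the time regressor.

Effect sizes are keyed by parameter name (e.g. ``"B:SMA->M1"``).  True
magnitudes in vivo are unknowable from group-level figures; defaults are
chosen to be physiologically plausible and recoverable, and are documented
in the methods note.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .generative import (
    ConnectivityModel,
    HemodynamicParams,
    check_stability,
    pack_parameters,
    parameter_names,
    simulate_bold,
    unpack_parameters,
)
from .paradigm import Paradigm, build_inputs, build_paradigm
from .peb import SubjectRecord, normalize_capacity
from .roi import RoiSpec, VolumeSeries

CAPACITY_RANGE = (8.0, 25.0)  # raw clinical capacity-score spread


def default_control_model() -> ConnectivityModel:
    """Plausible 4-region ground truth for healthy controls.

    A contains the anatomically fixed connections (M1<->S1, SMA->M1,
    M1->SMA) plus the SMA<->S1, AG<->S1 and AG<->SMA pairs; the AG<->M1
    pair is absent.  E modulates four sensorimotor connections; V drives M1
    and SMA, P drives S1.
    """
    reg = ("M1", "S1", "SMA", "AG")
    n = len(reg)
    A = np.zeros((n, n))
    a_mask = np.eye(n, dtype=bool)
    np.fill_diagonal(A, -0.5)

    def setA(src, dst, w):
        A[reg.index(dst), reg.index(src)] = w
        a_mask[reg.index(dst), reg.index(src)] = True

    setA("S1", "M1", 0.30)
    setA("M1", "S1", -0.20)
    setA("SMA", "M1", -0.25)
    setA("M1", "SMA", -0.20)
    setA("SMA", "S1", 0.25)
    setA("S1", "SMA", 0.30)
    setA("AG", "S1", 0.20)
    setA("S1", "AG", 0.25)
    setA("AG", "SMA", 0.15)
    setA("SMA", "AG", 0.25)

    B = np.zeros((1, n, n))
    b_mask = np.zeros((1, n, n), bool)

    def setB(src, dst, w):
        B[0, reg.index(dst), reg.index(src)] = w
        b_mask[0, reg.index(dst), reg.index(src)] = True

    # SMA->M1 modulation averages ~0 at the group level (its session values
    # are dominated by the carryover/time contributions); the mask keeps the
    # connection modulated even where the base weight is zero.  At most one
    # modulated afferent per region: two modulated inputs converging on the
    # same target are nearly collinear at this paradigm's temporal
    # resolution, so only their combination would be identifiable.
    B[0, reg.index("M1"), reg.index("SMA")] = 0.0
    b_mask[0, reg.index("M1"), reg.index("SMA")] = True
    setB("M1", "S1", 0.30)
    setB("S1", "SMA", -0.20)

    C = np.zeros((n, 3))
    c_mask = np.zeros((n, 3), bool)
    inputs = ("V", "E", "P")

    def setC(inp, dst, w):
        C[reg.index(dst), inputs.index(inp)] = w
        c_mask[reg.index(dst), inputs.index(inp)] = True

    # driving weights sized so neural excursions stay within ~[-0.2, 0.7]:
    # the balloon model's inflow has no fixed point for sustained
    # deactivation below -gamma, so large drives are unphysiological
    setC("V", "M1", 0.10)
    setC("V", "SMA", 0.08)
    setC("P", "S1", 0.12)
    return ConnectivityModel(
        A=A, B=B, C=C, regions=reg, inputs=inputs,
        a_mask=a_mask, b_mask=b_mask, c_mask=c_mask,
    )


@dataclass
class CohortSpec:
    """Study conditions for cohort generation."""

    n_controls: int = 16
    n_patients: int = 8
    carryover_effects: dict = field(
        default_factory=lambda: {"B:SMA->M1": 0.5}
    )
    time_effects: dict = field(default_factory=lambda: {"B:M1->S1": 0.3})
    capacity_effects: dict = field(default_factory=lambda: {"C:V->SMA": -0.3})
    base_model: ConnectivityModel | None = None
    between_subject_sd: float = 0.1      # Hz, off-diagonal A/B/C entries
    self_sd: float = 0.025               # Hz, self-connections
    snr: float | None = 2.0              # per-region signal sd / noise sd
    noise_sd: float | None = None        # % signal; overrides snr if set
    seed: int = 0
    max_stability_retries: int = 200

    def resolved_base(self) -> ConnectivityModel:
        return self.base_model or default_control_model()


@dataclass
class SyntheticCohort:
    """Generated records, ground truths and ROI series for one cohort draw."""

    records: list
    truths: list                  # ConnectivityModel per subject-session
    series: list                  # (n_regions, n_volumes) arrays
    paradigm: Paradigm
    spec: CohortSpec
    hemo: HemodynamicParams
    seeds: list

    def __post_init__(self):
        for y in self.series:
            if y.shape[1] != self.paradigm.n_volumes:
                raise ValueError("series length does not match paradigm volumes")

    def control_indices(self):
        return [i for i, r in enumerate(self.records) if r.cohort == "control"]

    def patient_indices(self):
        return [i for i, r in enumerate(self.records) if r.cohort == "patient"]

    def series_frame(self, i: int) -> pd.DataFrame:
        truth = self.truths[i]
        return pd.DataFrame(self.series[i].T, columns=list(truth.regions))


def _effect_vector(names, effects) -> np.ndarray:
    v = np.zeros(len(names))
    for key, val in effects.items():
        if key not in names:
            raise KeyError(f"effect on unknown parameter {key!r}")
        v[names.index(key)] = val
    return v


def _noise_for(series_clean, spec: CohortSpec, rng) -> float:
    if spec.noise_sd is not None:
        return spec.noise_sd
    sd = float(np.mean(np.std(series_clean, axis=1)))
    return sd / spec.snr if spec.snr else 0.0


def generate_cohort(
    spec: CohortSpec | None = None,
    paradigm: Paradigm | None = None,
    hemo: HemodynamicParams | None = None,
) -> SyntheticCohort:
    """Draw a cohort and simulate every subject-session's ROI series."""
    spec = spec or CohortSpec()
    paradigm = paradigm or build_paradigm(seed=spec.seed)
    hemo = hemo or HemodynamicParams()
    base = spec.resolved_base()
    names = parameter_names(base)
    theta_group = pack_parameters(base)
    is_self = np.array(
        [nm.startswith("A:") and nm.split(":")[1].split("->")[0]
         == nm.split("->")[1] for nm in names]
    )
    sd_vec = np.where(is_self, spec.self_sd, spec.between_subject_sd)
    ce_vec = _effect_vector(names, spec.carryover_effects)
    t_vec = _effect_vector(names, spec.time_effects)
    cs_vec = _effect_vector(names, spec.capacity_effects)
    rng = np.random.default_rng(spec.seed)
    inputs = build_inputs(paradigm)

    def _ok(theta):
        """Stability of A and A+B plus a plausibility screen on the clean
        series: input switching can destabilize trajectories even when both
        matrices are individually stable, so the simulated response itself
        must stay within a physiological BOLD range."""
        model = unpack_parameters(theta, base)
        if not (
            check_stability(model.A)[0]
            and check_stability(model.A + model.B.sum(axis=0))[0]
        ):
            return False
        clean = simulate_bold(model, hemo, paradigm, inputs, noise_sd=0.0)
        # genuine switched-system explosions saturate the integrator's state
        # clamps and show up as responses of hundreds of percent; ordinary
        # strong modulations stay far below this bound
        return bool(np.all(np.isfinite(clean)) and np.max(np.abs(clean)) <= 50.0)

    def draw_subject_effect(extra=(0,)):
        """Between-subject deviation keeping every session admissible.

        ``extra`` lists the session-specific offsets (e.g. PRE and POST
        effect combinations) that must all stay admissible with this draw.
        """
        for _ in range(spec.max_stability_retries):
            eps = rng.normal(0.0, sd_vec)
            if all(_ok(theta_group + eps + off) for off in extra):
                return eps
        raise RuntimeError("stability resampling exhausted")

    records, truths, series, seeds = [], [], [], []

    def add_session(record, theta):
        model = unpack_parameters(theta, base)
        if not _ok(theta):
            raise RuntimeError("unstable session parameters")
        clean = simulate_bold(model, hemo, paradigm, inputs, noise_sd=0.0)
        nsd = _noise_for(clean, spec, rng)
        session_seed = int(rng.integers(0, 2**31 - 1))
        noisy = clean + np.random.default_rng(session_seed).normal(
            0.0, nsd, clean.shape
        )
        records.append(record)
        truths.append(model)
        series.append(noisy)
        seeds.append(session_seed)

    for i in range(spec.n_controls):
        eps = draw_subject_effect()
        add_session(
            SubjectRecord(subject_id=f"C{i + 1:02d}", cohort="control"),
            theta_group + eps,
        )

    raw_scores = rng.uniform(*CAPACITY_RANGE, size=spec.n_patients)
    cs_norm = normalize_capacity(raw_scores) if spec.n_patients else raw_scores
    carry = np.array(
        [1 if i < (spec.n_patients + 1) // 2 else -1
         for i in range(spec.n_patients)]
    )
    for i in range(spec.n_patients):
        offsets = [
            carry[i] * ce_vec + tp * t_vec + cs_norm[i] * cs_vec
            for tp in (1, -1)
        ]
        eps = draw_subject_effect(extra=offsets)  # shared across PRE and POST
        for tp, off in zip((1, -1), offsets):
            theta = theta_group + off + eps
            add_session(
                SubjectRecord(
                    subject_id=f"P{i + 1:02d}",
                    cohort="patient",
                    carryover=int(carry[i]),
                    timepoint=tp,
                    capacity_score=float(raw_scores[i]),
                ),
                theta,
            )
    return SyntheticCohort(
        records=records, truths=truths, series=series,
        paradigm=paradigm, spec=spec, hemo=hemo, seeds=seeds,
    )


def cohort_manifest(cohort: SyntheticCohort) -> pd.DataFrame:
    """One row per subject-session: labels, seed, true-parameter checksum."""
    rows = []
    for rec, truth, seed in zip(cohort.records, cohort.truths, cohort.seeds):
        digest = hashlib.sha256(
            np.round(pack_parameters(truth), 12).tobytes()
        ).hexdigest()[:16]
        rows.append(
            {
                "subject_id": rec.subject_id,
                "cohort": rec.cohort,
                "carryover": rec.carryover,
                "timepoint": rec.timepoint,
                "capacity_score": rec.capacity_score,
                "seed": seed,
                "truth_checksum": digest,
            }
        )
    return pd.DataFrame(rows)


def generate_volumes(
    series: np.ndarray,
    roi_layout: list[RoiSpec],
    grid_shape=(32, 32, 32),
    voxel_size=(2.0, 2.0, 2.0),
    origin=(0.0, 0.0, 0.0),
    noise_sd: float = 0.1,
    tr: float = 3.0,
    seed: int = 0,
) -> VolumeSeries:
    """Paint ROI time series into a noisy 4-D volume.

    Each ROI's voxels express its series with Gaussian spatial weighting
    (sd = radius/2, support out to 2x radius); the background is white
    noise.  ROI centers must be at least 2x radius apart.
    """
    series = np.asarray(series, float)
    if series.shape[0] != len(roi_layout):
        raise ValueError("one series per ROI required")
    centers = np.array([r.center for r in roi_layout])
    for a in range(len(roi_layout)):
        for b in range(a + 1, len(roi_layout)):
            d = np.linalg.norm(centers[a] - centers[b])
            need = 2.0 * max(roi_layout[a].radius, roi_layout[b].radius)
            if d < need:
                raise ValueError(
                    f"overlapping ROIs {roi_layout[a].label!r} and "
                    f"{roi_layout[b].label!r}: {d:.1f} mm < {need:.1f} mm"
                )
    rng = np.random.default_rng(seed)
    T = series.shape[1]
    data = rng.normal(0.0, noise_sd, (*grid_shape, T)) if noise_sd > 0 else (
        np.zeros((*grid_shape, T))
    )
    grid = np.indices(grid_shape).reshape(3, -1).T
    mm = grid * np.asarray(voxel_size) + np.asarray(origin)
    for k, roi in enumerate(roi_layout):
        d2 = np.sum((mm - np.asarray(roi.center)) ** 2, axis=1)
        sd = roi.radius / 2.0
        w = np.exp(-d2 / (2.0 * sd**2))
        w[d2 > (2.0 * roi.radius) ** 2] = 0.0
        inside = w > 0
        data.reshape(-1, T)[inside] += np.outer(w[inside], series[k])
    return VolumeSeries(data, tuple(voxel_size), tuple(origin), tr)
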