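"""Six-step model-structure identification over controls and patients.

Controls first: STEP 1 fixes the driving-input (C) structure by Bayesian
model selection among three candidates (V drives M1, SMA, or both; P always
drives S1); STEP 2 searches the endogenous (A) structure with anatomically
fixed connections (M1<->S1, SMA->M1, M1->SMA) and four switchable
bidirectional pairs; STEP 3 searches which connections the stimulation
input E modulates (B), E being the only modulatory input.  Patients then
inherit the controls' C structure with re-estimated weights (STEP 4), may
only discard -- never add -- endogenous connections relative to the
controls' winner (STEP 5), and get their own modulation search from the
STEP-5 structure (STEP 6).

Group-level searches run at the second level: a PEB model over the relevant
field, exhaustive Bayesian model reduction over on/off patterns, and a
Bayesian model average over the Occam window.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .generative import ConnectivityModel, HemodynamicParams, parameter_names
from .inversion import (
    InversionSettings,
    Posterior,
    PriorSpec,
    default_priors,
    invert,
)
from .model_space import (
    bayesian_model_reduction,
    model_posteriors,
    reduce_prior,
)
from .peb import GroupEstimates, build_design, fit_peb, peb_search
from .synthetic import default_control_model

REGIONS = ("M1", "S1", "SMA", "AG")

#: anatomically / functionally fixed endogenous connections (source->target)
FIXED_CONNECTIONS = ("A:M1->S1", "A:S1->M1", "A:SMA->M1", "A:M1->SMA")

#: bidirectional pairs tested in the structural search
SWITCHABLE_PAIRS = (
    ("A:SMA->S1", "A:S1->SMA"),
    ("A:AG->M1", "A:M1->AG"),
    ("A:AG->S1", "A:S1->AG"),
    ("A:AG->SMA", "A:SMA->AG"),
)

C_CANDIDATES = (
    ("V->M1", ("C:V->M1", "C:P->S1")),
    ("V->SMA", ("C:V->SMA", "C:P->S1")),
    ("V->both", ("C:V->M1", "C:V->SMA", "C:P->S1")),
)


@dataclass
class PipelineConfig:
    """Controls for the 6-step procedure."""

    settings: InversionSettings = field(default_factory=InversionSettings)
    cap: int = 4096
    occam_mass: float = 0.95
    inclusion_threshold: float = 0.5
    pairs_joint: bool = True          # switch A direction-pairs jointly
    encoding: str = "boxcar"
    expected_variance_fraction: float = 1.0 / 16.0
    patient_regressors: tuple | None = None   # default: all four


@dataclass
class StepConfig:
    step: int
    cohort: str
    fld: str
    candidates: list | None = None
    switchable: list | None = None
    fixed: tuple = ()
    inherited: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    steps: dict
    control_estimates: GroupEstimates | None = None
    patient_estimates: dict | None = None   # {"A": ..., "B": ..., "C": ...}
    control_posteriors: list | None = None
    patient_posteriors: list | None = None

    def winning_c(self) -> str:
        return self.steps["step1"]["winner"]

    def winning_a_connections(self) -> list:
        return self.steps["step2"]["winning_connections"]

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        serializable = {}
        for k, v in self.steps.items():
            serializable[k] = {
                kk: (vv.tolist() if isinstance(vv, np.ndarray) else vv)
                for kk, vv in v.items()
                if not isinstance(vv, (GroupEstimates, Posterior))
            }
        (out / "steps.json").write_text(json.dumps(serializable, indent=2))
        if self.control_estimates is not None:
            self.control_estimates.to_frame().to_csv(
                out / "control_estimates.csv", index=False
            )
        if self.patient_estimates:
            for fld, est in self.patient_estimates.items():
                est.to_frame().to_csv(
                    out / f"patient_estimates_{fld}.csv", index=False
                )


# ---------------------------------------------------------------------------
# model spaces
# ---------------------------------------------------------------------------

def full_search_model() -> ConnectivityModel:
    """Template with every searchable entry free: dense A, E-modulation of
    every connection, and the union of the C candidates."""
    base = default_control_model()
    n = base.n_regions
    a_mask = np.ones((n, n), bool)
    b_mask = np.ones((1, n, n), bool)
    c_mask = np.zeros((n, 3), bool)
    for _, conns in C_CANDIDATES:
        for c in conns:
            inp, dst = c.split(":")[1].split("->")
            c_mask[base.regions.index(dst), base.inputs.index(inp)] = True
    A = np.zeros((n, n))
    np.fill_diagonal(A, -0.5)
    return ConnectivityModel(
        A=A, B=np.zeros((1, n, n)), C=np.zeros((n, 3)),
        regions=base.regions, inputs=base.inputs,
        a_mask=a_mask, b_mask=b_mask, c_mask=c_mask,
    )


def step1_input_space() -> list[tuple[str, tuple]]:
    """Three driving-input candidates; each includes P->S1."""
    return [(label, conns) for label, conns in C_CANDIDATES]


def step2_structural_space(fixed=FIXED_CONNECTIONS) -> list[dict]:
    """All on/off combinations of the switchable bidirectional pairs.

    Self-connections and ``fixed`` are present in every candidate; B is
    assumed fully connected at this stage.
    """
    out = []
    for bits in itertools.product((True, False), repeat=len(SWITCHABLE_PAIRS)):
        conns = set(fixed) | {
            f"A:{r}->{r}" for r in REGIONS
        }
        for pair, on in zip(SWITCHABLE_PAIRS, bits):
            if on:
                conns.update(pair)
        out.append(
            {
                "pairs_on": [p for p, on in zip(SWITCHABLE_PAIRS, bits) if on],
                "connections": sorted(conns),
            }
        )
    return out


def step3_b_space(winning_a_connections) -> list[str]:
    """Modulatory candidates: E may modulate every surviving A connection
    (including self-connections); V and P modulate nothing."""
    return ["B:" + c.split(":")[1] for c in winning_a_connections]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _switch_for(names, on_names):
    on = set(on_names)
    return np.array([nm in on for nm in names], bool)


def _reduce_posterior_to(posterior, prior, keep_names):
    """BMR the posterior so parameters outside ``keep_names`` are pinned."""
    always = [nm for nm in posterior.names
              if not (nm.startswith(("A:", "B", "C:")))]
    switch = _switch_for(posterior.names, list(keep_names) + always)
    red_prior = reduce_prior(prior, switch)
    red, _ = bayesian_model_reduction(prior, posterior, red_prior)
    red.names = posterior.names
    red.prior = red_prior
    return red


def _self_connections():
    return [f"A:{r}->{r}" for r in REGIONS]


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    cohort,
    config: PipelineConfig | None = None,
    control_posteriors=None,
    patient_posteriors=None,
    out_dir=None,
) -> PipelineResult:
    """Run STEPs 1-6 on a cohort (e.g. a ``SyntheticCohort``).

    ``cohort`` must expose ``records``, ``series``, ``paradigm`` and
    (optionally) ``hemo``.  Pre-computed first-level posteriors may be
    passed to skip the inversion stage.  With no patients only STEPs 1-3
    run.
    """
    config = config or PipelineConfig()
    paradigm = cohort.paradigm
    hemo = getattr(cohort, "hemo", None) or HemodynamicParams()
    template = full_search_model()
    priors = default_priors(template)
    names = parameter_names(template)
    ctrl_idx = [i for i, r in enumerate(cohort.records) if r.cohort == "control"]
    pat_idx = [i for i, r in enumerate(cohort.records) if r.cohort == "patient"]
    steps: dict = {}

    # ---- first level: controls, full search model
    if control_posteriors is None:
        control_posteriors = [
            invert(cohort.series[i], paradigm, template, priors=priors,
                   hemo=hemo, settings=config.settings)
            for i in ctrl_idx
        ]

    # ---- STEP 1: driving-input structure (fixed-effects BMS over controls)
    candidates = step1_input_space()
    c_names = [nm for nm in names if nm.startswith("C:")]
    sumF = []
    for label, conns in candidates:
        keep = [nm for nm in names if not nm.startswith("C:")] + list(conns)
        switch = _switch_for(names, keep)
        red_prior = reduce_prior(priors, switch)
        total = 0.0
        for post in control_posteriors:
            _, dF = bayesian_model_reduction(priors, post, red_prior)
            total += dF
        sumF.append(total)
    probs = model_posteriors(np.array(sumF))
    win = int(np.argmax(probs))
    win_label, win_c = candidates[win]
    steps["step1"] = {
        "candidates": [label for label, _ in candidates],
        "sum_dF": np.array(sumF),
        "probabilities": {
            label: float(p) for (label, _), p in zip(candidates, probs)
        },
        "winner": win_label,
        "winning_connections": list(win_c),
    }
    # controls now carry the winning C structure (no BMA over C)
    keep_after_1 = [nm for nm in names if not nm.startswith("C:")] + list(win_c)
    control_posteriors = [
        _reduce_posterior_to(p, priors, keep_after_1) for p in control_posteriors
    ]

    # ---- STEP 2: endogenous structure for controls (PEB + pair search)
    ctrl_records = [cohort.records[i] for i in ctrl_idx]
    design_c = build_design(ctrl_records)
    peb_a = fit_peb(
        control_posteriors, design_c, "A",
        expected_variance_fraction=config.expected_variance_fraction,
        first_level_prior=priors,
    )
    switchable = (
        list(SWITCHABLE_PAIRS)
        if config.pairs_joint
        else [c for pair in SWITCHABLE_PAIRS for c in pair]
    )
    bma_a, incl_a, cmp_a = peb_search(
        peb_a, switchable, cap=config.cap, occam_mass=config.occam_mass
    )
    winning_a = set(FIXED_CONNECTIONS) | set(_self_connections())
    for el in switchable:
        key = "|".join(el) if isinstance(el, tuple) else el
        if incl_a[key] >= config.inclusion_threshold:
            winning_a.update(el if isinstance(el, tuple) else (el,))
    winning_a = sorted(winning_a)
    steps["step2"] = {
        "inclusion": incl_a,
        "winning_connections": winning_a,
        "map_model": cmp_a.identifiers[cmp_a.best()],
        "map_probability": float(cmp_a.probabilities[cmp_a.best()]),
        "estimates": bma_a,
    }

    # ---- STEP 3: modulatory structure for controls (E only; B restricted
    # to the surviving A connections via the PEB connection filter)
    b_space = [nm for nm in step3_b_space(winning_a) if nm in names]
    peb_b = fit_peb(
        control_posteriors, design_c, "B",
        expected_variance_fraction=config.expected_variance_fraction,
        first_level_prior=priors,
        connections=b_space,
    )
    bma_b, incl_b, cmp_b = peb_search(
        peb_b, list(b_space), cap=config.cap, occam_mass=config.occam_mass
    )
    winning_b = sorted(
        c for c in b_space if incl_b[c] >= config.inclusion_threshold
    )
    steps["step3"] = {
        "b_space": b_space,
        "inclusion": incl_b,
        "winning_connections": winning_b,
        "estimates": bma_b,
    }

    result = PipelineResult(
        steps=steps,
        control_estimates=bma_a,
        control_posteriors=control_posteriors,
    )
    if not pat_idx:
        if out_dir is not None:
            result.save(out_dir)
        return result

    # ---- STEP 4: patients inherit the C structure (weights re-estimated)
    pat_template = _patient_template(template, winning_a, win_c)
    pat_priors = default_priors(pat_template)
    if patient_posteriors is None:
        patient_posteriors = [
            invert(cohort.series[i], paradigm, pat_template, priors=pat_priors,
                   hemo=hemo, settings=config.settings)
            for i in pat_idx
        ]
    steps["step4"] = {"c_structure": list(win_c)}

    # ---- STEP 5: patients' A nested in the controls' winner
    pat_records = [cohort.records[i] for i in pat_idx]
    order = sorted(range(len(pat_records)),
                   key=lambda i: (pat_records[i].subject_id,
                                  -(pat_records[i].timepoint or 0)))
    pat_records = [pat_records[i] for i in order]
    patient_posteriors = [patient_posteriors[i] for i in order]
    design_p = build_design(pat_records, regressors=config.patient_regressors)
    peb_pa = fit_peb(
        patient_posteriors, design_p, "A",
        expected_variance_fraction=config.expected_variance_fraction,
        first_level_prior=pat_priors,
    )
    discardable = [
        c for c in winning_a
        if c not in FIXED_CONNECTIONS and c not in _self_connections()
    ]
    bma_pa, incl_pa, cmp_pa = peb_search(
        peb_pa, discardable, cap=config.cap, occam_mass=config.occam_mass
    )
    patient_a = sorted(
        set(FIXED_CONNECTIONS)
        | set(_self_connections())
        | {c for c in discardable if incl_pa[c] >= config.inclusion_threshold}
    )
    assert set(patient_a) <= set(winning_a), "patients' A must nest in controls'"
    steps["step5"] = {
        "inclusion": incl_pa,
        "winning_connections": patient_a,
        "estimates": bma_pa,
    }

    # ---- STEP 6: patients' modulation search from the STEP-5 structure
    pat_names = parameter_names(pat_template)
    b_space_p = [nm for nm in step3_b_space(patient_a) if nm in pat_names]
    peb_pb = fit_peb(
        patient_posteriors, design_p, "B",
        expected_variance_fraction=config.expected_variance_fraction,
        first_level_prior=pat_priors,
        connections=b_space_p,
    )
    bma_pb, incl_pb, cmp_pb = peb_search(
        peb_pb, list(b_space_p), cap=config.cap, occam_mass=config.occam_mass
    )
    patient_b = sorted(
        c for c in b_space_p if incl_pb[c] >= config.inclusion_threshold
    )
    steps["step6"] = {
        "b_space": b_space_p,
        "inclusion": incl_pb,
        "winning_connections": patient_b,
        "estimates": bma_pb,
    }
    peb_pc = fit_peb(
        patient_posteriors, design_p, "C",
        expected_variance_fraction=config.expected_variance_fraction,
        first_level_prior=pat_priors,
    )
    result.patient_estimates = {"A": bma_pa, "B": bma_pb, "C": peb_pc}
    result.patient_posteriors = patient_posteriors
    if out_dir is not None:
        result.save(out_dir)
    return result


def _patient_template(template: ConnectivityModel, winning_a, winning_c):
    """Masks restricted to the controls' winning structures."""
    n = template.n_regions
    reg = template.regions
    a_mask = np.zeros((n, n), bool)
    for c in winning_a:
        src, dst = c.split(":")[1].split("->")
        a_mask[reg.index(dst), reg.index(src)] = True
    b_mask = np.zeros((1, n, n), bool)
    b_mask[0] = a_mask  # E may modulate any surviving connection
    c_mask = np.zeros_like(template.c_mask)
    for c in winning_c:
        inp, dst = c.split(":")[1].split("->")
        c_mask[reg.index(dst), template.inputs.index(inp)] = True
    A = np.zeros((n, n))
    np.fill_diagonal(A, -0.5)
    return ConnectivityModel(
        A=A, B=np.zeros((1, n, n)), C=np.zeros_like(template.C),
        regions=reg, inputs=template.inputs,
        a_mask=a_mask, b_mask=b_mask, c_mask=c_mask,
    )
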