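# fesdcm

Effective-connectivity analysis of a four-region cortical motor network
(M1, S1, SMA, AG) under a 2×2 volitional × functional-electrical-
stimulation (FES) paradigm: bilinear dynamic causal modeling (DCM) of
BOLD time series, variational-Laplace inversion, evidence-based model
comparison (Bayesian model reduction and averaging), and hierarchical
empirical-Bayes (PEB) group inference with carryover, time and
capacity-score regressors.

The package is aimed at researchers studying FES-induced motor recovery
("carryover effect") after stroke, and more generally at anyone who wants
a self-contained, testable implementation of the DCM → BMR → PEB analysis
chain with a synthetic-data generator for end-to-end validation.

## The model

Neural dynamics per region follow the bilinear state equation

    dx/dt = (A + Σ_j u_j B_j) x + C u

where `A` (Hz) is endogenous coupling, `B_j` the modulation of coupling by
experimental input j, and `C` the direct driving influence of the inputs.
Three inputs are derived from the block paradigm (TR 3 s, 10-minute run,
20 alternating 9 s OFF / 21 s ON blocks, four conditions): volitional
drive `V`, electrical stimulation `E` (the only modulatory input), and
proprioception `P`.  Neural activity is mapped to percent BOLD change by
the standard balloon–windkessel model.  Inversion maximizes the
variational free energy `F` (the log-evidence bound used for all model
comparison); group effects are estimated by placing a general linear
model (mean, carryover CE=±1, time PRE/POST=±1, normalized capacity
score) over the first-level posteriors.  The overall magnitude of a
connection for a given group and time point is the signed sum of its
regressor contributions.  See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
import fesdcm as fd

# a synthetic patient cohort with a planted +0.5 Hz carryover effect on
# the SMA->M1 modulation (8 patients, PRE and POST sessions each)
spec = fd.CohortSpec(n_controls=0, n_patients=8, seed=1)
cohort = fd.generate_cohort(spec)

# first level: fit each session's connectivity model
posts = [
    fd.invert(cohort.series[i], cohort.paradigm, spec.resolved_base())
    for i in cohort.patient_indices()
]

# second level: hierarchical model over the modulatory (B) parameters
records = [cohort.records[i] for i in cohort.patient_indices()]
est = fd.fit_peb(posts, fd.build_design(records), "B")
co = est.coefficient("carryover", "B:SMA->M1")
sd = est.coefficient_sd("carryover", "B:SMA->M1")
print(f"carryover coefficient on B:SMA->M1: {co:+.3f} +/- {sd:.3f} Hz")

# overall connection magnitude for the responder group before treatment
print(f"CE, PRE: {fd.combine_contributions(est, 'B:SMA->M1', +1, +1):+.3f} Hz")
```

Running this prints (exact numbers vary with the seed):

```
carryover coefficient on B:SMA->M1: +0.205 +/- 0.070 Hz
CE, PRE: +0.554 Hz
```

i.e. the hierarchical model attributes about +0.2 Hz of the SMA→M1
modulation difference to the carryover classification (responders minus
non-responders, per unit of the ±1 coding), and the summed contributions
give the responders' pre-treatment connection strength.  The coefficient
sits below the planted +0.5 Hz: at this noise level a minority of
sessions' modulation signs are genuinely unidentifiable, which attenuates
the group contrast (discussed in `docs/methods.md`).

The full six-step structure identification (controls' C → A → B, then
patients nested within the controls' winner) runs as

```python
cohort = fd.generate_cohort(fd.CohortSpec(seed=1))   # 16 controls + 8 patients
result = fd.run_pipeline(cohort, fd.PipelineConfig(), out_dir="results/run1")
print(result.steps["step1"]["probabilities"])
print(result.steps["step2"]["inclusion"])
```

A thin CLI covers the same flows: `fesdcm simulate-cohort`,
`fesdcm invert`, `fesdcm pipeline` (see `--help`).

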