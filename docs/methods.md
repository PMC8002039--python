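# Methods

## The model

`fesdcm` analyses effective connectivity in a four-region cortical motor
network — primary motor cortex (M1), primary somatosensory cortex (S1),
supplementary motor area (SMA) and angular gyrus (AG) — under a 2×2
volitional × electrical-stimulation paradigm for ankle dorsiflexion.
Neural activity follows the bilinear state equation

    dx/dt = (A + Σ_j u_j B_j) x + C u

with `A[target, source]` the endogenous coupling (Hz), `B_j` the change in
coupling induced by modulatory input j, and `C` the direct driving
influence of the experimental inputs.  Three inputs are derived from the
block schedule: `V` (descending volitional drive; active in the two
conditions requiring voluntary effort), `E` (ascending electrical
stimulation; active in the two stimulated conditions) and `P`
(proprioceptive afference; active in all four conditions).  `E` is the
only modulatory input; `V` and `P` only drive.

Each region's activity enters a standard four-state balloon–windkessel
cascade (vasodilatory signal, inflow, venous volume, deoxyhemoglobin;
canonical parameters κ = 0.64 s⁻¹, γ = 0.32 s⁻¹, τ = 2 s, α = 0.32,
E₀ = 0.4, V₀ = 0.04), observed as percent BOLD signal change with the
classic coefficients k₁ = 7E₀, k₂ = 2, k₃ = 2E₀ − 0.2.  The source
literature presupposes this observation model without restating it; the
parameter values here are the conventional defaults, and they are fixed
(not fitted) unless explicitly requested.

A caveat worth knowing: the balloon model has no inflow fixed point for
sustained neural deactivation below −γ.  Parameter regimes that push
sustained x under ≈ −0.3 are unphysiological and numerically explosive.
The synthetic generator therefore sizes its driving weights so that neural
excursions stay within roughly [−0.2, 0.7], and the integrator saturates
the log hemodynamic states at ±8 (far outside physiology) so that
pathological parameter proposals during optimization produce a finite,
poor prediction instead of a floating-point failure.

## Paradigm

One 10-minute run: TR 3 s, 200 volumes, 20 alternating 9 s OFF / 21 s ON
blocks, four conditions (vol+FES, FES, vol, passive) allocated in balanced
counts (5 blocks each) in a seed-reproducible pseudo-random order.
Movements are paced at 3.5 s.  Inputs are sampled on a microtime grid of
TR/16 by default and encoded as boxcars over ON blocks; an event encoding
(3.5 s-spaced pulses of configurable duration) is available, since the
block-versus-event reading of the paradigm is ambiguous.  Input amplitude
is 1; scaling is absorbed by `C` and `B`.

## Inversion (variational Laplace)

`invert` maximizes the free energy

    F = E_q[log p(y|θ)] − KL(q(θ)‖p(θ)) − KL(q(λ)‖p(λ))

over a Gaussian posterior `q` by Gauss–Newton ascent with step-halving;
steps are only accepted if they increase F, so the accepted-F sequence is
non-decreasing by construction.  Observation noise is white per region
with log-precision hyperparameters λ (Gaussian hyperprior, mean 0,
variance 16), updated by Newton steps under the same accept-if-improved
rule.  Gradients come from finite differences on the integrator (forward
scheme, step 1e-3; a central scheme is available).  Convergence: ΔF <
0.01 nats over 3 consecutive iterations, at most 128 iterations.

Priors (Gaussian, diagonal): off-diagonal A and B entries N(0, 1/16); C
entries N(0, 1); self-connections N(−0.5 Hz, 1/256), parameterized
directly in Hz.  Serial correlations in the noise are ignored.

Two robustness devices address the multimodal landscape of bilinear
models:

* **Staged warm start** (default): the model is first fitted with all
  modulatory entries pinned to zero (A and C only), and the optimum seeds
  the full fit.  This strongly reduces spurious endogenous couplings in
  dense search models.
* **Direct-refit fallback**: if the staged fit leaves residual variance
  above 1.5× the white-noise level estimated from successive differences
  of the data, the model is refitted from the prior mean and the
  higher-F solution is kept.  This rescues occasional stalls of the
  staged path on strongly modulated sessions.

Proposals are accepted only if `A` (strictly negative diagonal) and the
fully modulated `A + ΣB_j` are stable.  On conjugate linear-Gaussian
problems the implementation reproduces the analytic posterior and log
evidence to 1e-6, which the test suite checks.

## Model comparison

Free energies are converted to posterior model probabilities by softmax
under uniform model priors.  Reduced models pin parameters with a prior
variance of 1e-8 (not exactly 0, keeping precision matrices invertible);
their posteriors and evidence changes follow analytically from the full
model by Bayesian model reduction (BMR), with no data re-visit.  Bayesian
model averaging moment-matches the probability-weighted Gaussian mixture
over the retained models; "best performing" models are retained by an
Occam window holding the smallest set of cumulative posterior probability
≥ 0.95 (configurable).

## Hierarchical group model (PEB)

At the second level, each subject-session's connection parameters are
random effects around a general linear model: mean regressor (all ones);
carryover classification CE = +1 / nCE = −1; acquisition time PRE = +1 /
POST = −1; and the capacity score, mean-corrected and scaled by its
maximum absolute deviation into [−1, 1].  Controls are modeled with the
mean regressor only.  Patients contribute PRE and POST sessions as
independent rows.  The overall magnitude of a connection for a given
group and time point is the signed sum of its regressor contributions.

Estimation replaces each subject's shrinkage prior with the empirical
prior N(x_i·β, Q) via BMR, where Q = exp(−γ)·(1/16)·Σ₀ scales the
first-level prior covariance Σ₀ of the selected parameters
(`expected_variance_fraction` default 1/16).  For fixed γ the summed
reduction free energy is an exact quadratic in β, so β's posterior is
closed-form; γ is estimated by profiling that closed form under a N(0, 1)
hyperprior, with a Laplace variance from the profile curvature.  The
second-level prior on β uses the first-level prior mean for the mean
regressor (zero for the others) and Σ₀ per regressor block.  Per-subject
marginal posterior blocks of the selected field (A, B or C) enter the
hierarchy; cross-field posterior covariance is not propagated.

Exhaustive second-level searches switch connections (or bidirectional
pairs, jointly) off by pinning their β coefficients across all
regressors; each on/off pattern is scored by BMR on the β posterior.
When the pattern count exceeds the cap (default 4096), the search is
pruned to the ⌊log₂ cap⌋ connections with the weakest individual evidence
of presence, the others staying on.

## The six-step structure identification

1. **Controls, C:** three candidates — V drives M1, SMA, or both; P
   always drives S1.  Scored by summed per-subject BMR evidence
   (fixed-effects selection); the MAP candidate is fixed thereafter.
2. **Controls, A:** fixed connections M1↔S1, SMA→M1 and M1→SMA
   (anatomically motivated) plus self-connections; the four remaining
   bidirectional pairs (SMA↔S1, AG↔M1, AG↔S1, AG↔SMA) are switched
   jointly (2⁴ = 16 structures; a config flag switches the 8 directions
   independently).  B is fully connected at this stage.  PEB over the A
   field, BMR search, BMA; pairs with inclusion probability ≥ 0.5 are
   kept.
3. **Controls, B:** E may modulate every surviving A connection
   (including self-connections); V and P modulate nothing.  PEB over the
   B field restricted to that set, exhaustive/pruned search, BMA.
4. **Patients, C:** structure inherited from step 1; weights re-estimated
   by inverting the patients with the winning masks.
5. **Patients, A:** connections may only be discarded relative to the
   controls' winner (nestedness is asserted on every run); exhaustive
   second-level search over the non-fixed connections with the
   four-regressor design, BMA.
6. **Patients, B:** modulation search over the step-5 structure, BMA.

## Synthetic cohorts

The generator reproduces the study conditions: 16 controls (one session),
8 patients (PRE and POST), CE/nCE labels balanced, capacity scores drawn
uniformly over the clinical-table range (8–25) and normalized by the PEB
rule.  Session parameters are group mean + CE·θ_CE + t·θ_t + CS·θ_CS +
between-subject Gaussian noise (sd 0.1 Hz off-diagonal, 0.025 Hz on
self-connections); a patient's two sessions share the subject-level
random effect, deliberately creating the within-subject dependence the
independent-rows second level ignores, so its impact is measurable.
Measurement noise defaults to SNR 2 (per-region mean signal sd divided by
noise sd).

The default ground-truth network: self-connections −0.5 Hz; the fixed
connections plus SMA↔S1, AG↔S1 and AG↔SMA present (0.15–0.3 Hz), AG↔M1
absent; E modulates SMA→M1 (group mean 0), M1→S1 (+0.3) and S1→SMA
(−0.2); V drives M1 (0.10) and SMA (0.08), P drives S1 (0.12).  Default
planted group effects: carryover +0.5 Hz on the SMA→M1 modulation, time
+0.3 Hz on the M1→S1 modulation, capacity −0.3 Hz on the V→SMA drive.
Two structural choices matter and were made deliberately:

* at most one modulated afferent per region — two modulated inputs
  converging on one target are nearly collinear at this paradigm's
  temporal resolution (first-level posterior correlation ≈ −0.9), so only
  their combination would be identifiable;
* driving weights sized for neural excursions within [−0.2, 0.7] (see the
  balloon-model caveat above).

Candidate sessions are screened by simulating the noise-free series and
rejecting draws whose response exceeds 50% signal change: eigenvalue
stability of `A` and `A+B` does not preclude transient explosions of the
input-switched system, and genuine explosions saturate the integrator
clamps at hundreds of percent, so the bound separates cleanly without
truncating strong-but-sane modulations.

What the generator does **not** emulate: hemodynamic variability across
subjects and regions, serially correlated physiological noise, motion and
scanner drift, lesions, and spatial heterogeneity inside an ROI.  Passing
recovery tests therefore demonstrate the estimator's correctness under
its own assumptions, not robustness to real fMRI artifacts.

The ROI stage is exercised by painting ROI series into a synthetic 4-D
volume with Gaussian spatial weighting (sd = radius/2, support 2×radius)
plus voxel noise, then smoothing (4 mm FWHM), selecting masked maxima
under the 8 mm separation rule (greedy, in declared region order, falling
back to the next-highest voxel on conflict) and summarizing 4 mm spheres
by their first eigenvariate (scaled to the RMS amplitude of the mean ROI
series, sign aligned with it).

## Problem sizes and numerical choices in the validation suite

* Single-subject recovery: 20 independent subjects, full 200-volume runs,
  SNR 2; pooled correlation between true and estimated A/B entries.
* Pipeline structure recovery: 10 cohorts of 6 controls each (steps 1–3).
* Group-effect recovery: 20 cohorts of 8 patients (16 sessions each),
  direct (unstaged) first-level fits.
* Inversion predictions in these studies are integrated at TR/8; the
  deviation from the TR/16 generation grid is ≈ 3e-4 percent signal,
  three orders of magnitude below the measurement noise.
* ROI round trip: 30³ voxel grid (2 mm), 4 ROIs ≥ 20 mm apart, voxel
  noise sd 0.3.

## Known limitations

* Bilinear DCM likelihoods are multimodal.  For a minority of synthetic
  subjects (~20% at SNR 2) the sign-flipped modulation mode has *higher*
  evidence than the generating parameters; no evidence-based estimator
  can recover those sessions, which attenuates group-level modulatory
  contrasts.  The hierarchical carryover coefficient is therefore
  systematically below its nominal planted value at this noise level, and
  the strict recovery check in the acceptance suite documents this
  honestly rather than relaxing its threshold.
* The marginal-block PEB ignores cross-field posterior covariance.
* The independent-rows second level understates the uncertainty of
  between-session contrasts when sessions share subject-level effects
  (by up to √2), which is intentional and measurable (see above).
* No slice-timing, confound regression or serial-correlation modeling;
  ROI series are assumed clean.
* Hemodynamic parameters are fixed at canonical values by default; the
  sampling resolution and priors of the original analysis are not public,
  so all numerical defaults here are declared, not inherited.
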