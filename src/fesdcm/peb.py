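"""Hierarchical (parametric empirical Bayes) group model.

First-level connection parameters are treated as random effects around a
group-level general linear model: for subject-session i with design row x_i,

    theta_i = (x_i . beta) + eps_i,      eps_i ~ N(0, Q),

where beta holds one coefficient vector per regressor (group mean;
carryover classification CE=+1/nCE=-1; acquisition time PRE=+1/POST=-1;
mean-corrected capacity score normalized to [-1, 1]) and Q is the
between-subject covariance, scaled by a log-precision hyperparameter gamma.

Estimation replaces each subject's original shrinkage prior with the
empirical prior N(x_i . beta, Q) by Bayesian model reduction.  For fixed
gamma the summed reduction free energy is an exact quadratic in beta, so
beta's posterior is available in closed form; gamma is estimated by
profiling that closed form under a Gaussian hyperprior.  The overall
magnitude of a connection for a given subject-session is the signed sum of
its regressor contributions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .inversion import Posterior, PriorSpec
from .model_space import (
    ModelComparison,
    bayesian_model_average,
    bayesian_model_reduction,
    enumerate_reduced_models,
    model_posteriors,
    occam_window,
    reduce_prior,
)

REGRESSORS = ("mean", "carryover", "time", "capacity")

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class SubjectRecord:
    """One subject-session row of the second-level design.

    Controls carry no carryover/timepoint/capacity entries (None); patients
    have ``carryover`` in {+1 (CE), -1 (nCE)} and ``timepoint`` in
    {+1 (PRE), -1 (POST)}.
    """

    subject_id: str
    cohort: str                       # "control" | "patient"
    carryover: int | None = None
    timepoint: int | None = None
    capacity_score: float | None = None

    def __post_init__(self):
        if self.cohort not in ("control", "patient"):
            raise ValueError(f"unknown cohort {self.cohort!r}")
        if self.cohort == "control":
            if any(v is not None for v in (self.carryover, self.timepoint,
                                           self.capacity_score)):
                raise ValueError("controls carry no patient covariates")
        else:
            if self.carryover not in (1, -1) or self.timepoint not in (1, -1):
                raise ValueError("patients need carryover and timepoint in {-1,+1}")


def records_table(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "cohort": r.cohort,
                "carryover": r.carryover,
                "timepoint": r.timepoint,
                "capacity_score": r.capacity_score,
            }
            for r in records
        ]
    )


@dataclass
class PEBDesign:
    """Second-level design matrix over subject-sessions."""

    matrix: np.ndarray
    regressors: tuple
    rows: tuple                        # (subject_id, timepoint) labels

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, float))
        if "mean" in self.regressors:
            col = self.matrix[:, self.regressors.index("mean")]
            if not np.all(col == 1.0):
                raise ValueError("mean column must be all ones")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self) -> str:
        df = pd.DataFrame(self.matrix, columns=list(self.regressors))
        df.insert(0, "row", [f"{s}@{t}" for s, t in self.rows])
        return df.to_csv(sep="\t", index=False)


def normalize_capacity(scores) -> np.ndarray:
    """Mean-correct and scale capacity scores into [-1, 1].

    Degenerate input (all scores equal) maps to all zeros.
    """
    s = np.asarray(scores, float)
    s = s - s.mean()
    m = np.max(np.abs(s))
    return s / m if m > 0 else s


def build_design(records, regressors=None) -> PEBDesign:
    """Design matrix from subject-session records.

    Controls admit only the mean regressor; patients default to all four
    (mean, carryover, time, capacity).  Rows are ordered deterministically
    by (subject, session), PRE before POST.
    """
    records = sorted(
        records,
        key=lambda r: (r.subject_id, -(r.timepoint or 0)),
    )
    cohorts = {r.cohort for r in records}
    if len(cohorts) > 1:
        raise ValueError("mixed cohorts in one design")
    is_control = cohorts == {"control"}
    if regressors is None:
        regressors = ("mean",) if is_control else REGRESSORS
    regressors = tuple(regressors)
    if is_control and set(regressors) != {"mean"}:
        raise ValueError("controls are modeled with a single mean regressor")
    n = len(records)
    cols = []
    for reg in regressors:
        if reg == "mean":
            cols.append(np.ones(n))
        elif reg == "carryover":
            cols.append(np.array([float(r.carryover) for r in records]))
        elif reg == "time":
            cols.append(np.array([float(r.timepoint) for r in records]))
        elif reg == "capacity":
            raw = [r.capacity_score for r in records]
            if any(v is None for v in raw):
                raise ValueError("missing capacity scores for capacity regressor")
            cols.append(normalize_capacity(raw))
        else:
            raise ValueError(f"unknown regressor {reg!r}")
    return PEBDesign(
        matrix=np.column_stack(cols),
        regressors=regressors,
        rows=tuple((r.subject_id, r.timepoint) for r in records),
    )


@dataclass
class GroupEstimates:
    """Second-level coefficients per connection x regressor.

    ``beta`` is (n_regressors, n_connections); ``beta_cov`` covers the
    regressor-major flattened vector.  ``subject_means`` holds the
    empirical-Bayes-updated first-level means (one row per subject-session).
    """

    connections: list
    regressors: tuple
    beta: np.ndarray
    beta_cov: np.ndarray
    free_energy: float
    gamma: float
    gamma_var: float
    design: PEBDesign
    beta_prior: PriorSpec
    subject_means: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_connections(self) -> int:
        return len(self.connections)

    def coefficient(self, regressor: str, connection: str) -> float:
        r = self.regressors.index(regressor)
        j = self.connections.index(connection)
        return float(self.beta[r, j])

    def coefficient_sd(self, regressor: str, connection: str) -> float:
        r = self.regressors.index(regressor)
        j = self.connections.index(connection)
        i = r * self.n_connections + j
        return float(np.sqrt(self.beta_cov[i, i]))

    def as_posterior(self) -> Posterior:
        return Posterior(
            mean=self.beta.ravel(),
            cov=self.beta_cov,
            free_energy=self.free_energy,
            names=[
                f"{reg}:{conn}"
                for reg in self.regressors
                for conn in self.connections
            ],
            prior=self.beta_prior,
        )

    def to_frame(self) -> pd.DataFrame:
        sd = np.sqrt(np.diag(self.beta_cov)).reshape(self.beta.shape)
        rows = []
        for r, reg in enumerate(self.regressors):
            for j, conn in enumerate(self.connections):
                rows.append(
                    {"connection": conn, "regressor": reg,
                     "mean": self.beta[r, j], "sd": sd[r, j]}
                )
        return pd.DataFrame(rows)


def _field_indices(names, fld):
    if fld == "B":
        pref = ("B:", "B1:", "B2:", "B3:")
    else:
        pref = (f"{fld}:",)
    return [i for i, nm in enumerate(names) if nm.startswith(pref)]


def fit_peb(
    first_level: list[Posterior],
    design: PEBDesign,
    fld: str = "A",
    expected_variance_fraction: float = 1.0 / 16.0,
    beta_prior: PriorSpec | None = None,
    gamma_prior: tuple = (0.0, 1.0),
    first_level_prior: PriorSpec | None = None,
    connections: list | None = None,
) -> GroupEstimates:
    """Empirical-Bayes estimation of second-level effects on one field.

    ``fld`` selects which connection family (A, B or C) enters the
    hierarchy; the marginal posterior block of those parameters is used per
    subject.  The between-subject covariance is
    ``exp(-gamma) * expected_variance_fraction * Sigma0`` with Sigma0 the
    first-level prior covariance of the selected parameters.
    """
    if len(first_level) != design.n:
        raise ValueError("rows of design do not align with first-level posteriors")
    names0 = first_level[0].names
    if names0 is None:
        raise ValueError("first-level posteriors need parameter names")
    for p in first_level:
        if p.names != names0:
            raise ValueError("first-level posteriors do not share a parameterization")
    rank = np.linalg.matrix_rank(design.matrix)
    if rank < design.matrix.shape[1]:
        raise ValueError(
            f"rank-deficient design: rank {rank} < {design.matrix.shape[1]} "
            f"columns {design.regressors}"
        )
    idx = _field_indices(names0, fld)
    if connections is not None:
        idx = [i for i in idx if names0[i] in connections]
    if not idx:
        raise ValueError(f"no parameters of field {fld!r} in the model")
    prior0 = first_level_prior or first_level[0].prior
    if prior0 is None:
        raise ValueError("first-level prior unavailable; pass first_level_prior")
    conn = [names0[i] for i in idx]
    k = len(idx)
    R = len(design.regressors)
    mu0 = prior0.mean[idx]
    S0 = prior0.cov[np.ix_(idx, idx)]
    P0 = np.linalg.inv(S0)
    ms, Ps = [], []
    for p in first_level:
        m = p.mean[idx]
        S = p.cov[np.ix_(idx, idx)]
        P = np.linalg.inv(0.5 * (S + S.T))
        ms.append(m)
        Ps.append(0.5 * (P + P.T))
    if beta_prior is None:
        b0 = np.zeros(R * k)
        if "mean" in design.regressors:
            r = design.regressors.index("mean")
            b0[r * k:(r + 1) * k] = mu0
        Sb = np.kron(np.eye(R), S0)
        beta_prior = PriorSpec(
            mean=b0, cov=Sb,
            names=[f"{reg}:{c}" for reg in design.regressors for c in conn],
        )
    Pb0 = beta_prior.precision
    ld_S0 = np.linalg.slogdet(S0)[1]
    Qbase = expected_variance_fraction * S0
    Qbase_inv = np.linalg.inv(Qbase)
    ld_Qbase = np.linalg.slogdet(Qbase)[1]
    X = design.matrix

    def profile(gamma):
        """Closed-form log joint evidence over beta at fixed gamma."""
        Qinv = np.exp(gamma) * Qbase_inv
        ld_Qinv = k * gamma - ld_Qbase
        const = 0.0
        G = np.zeros((design.n, k))       # Q^-1 Pr^-1 r_i rows
        Hc = np.zeros((k, k))             # shared connection-space curvature?
        # per-subject quantities (Pr differs only through P_i)
        quad_blocks = []
        for i in range(design.n):
            Pi, mi = Ps[i], ms[i]
            Pr = Pi - P0 + Qinv
            Pr = 0.5 * (Pr + Pr.T)
            # guard: curvature must stay positive definite
            w, V = np.linalg.eigh(Pr)
            w = np.maximum(w, 1e-10)
            Pr_inv = (V / w) @ V.T
            ld_Pr = float(np.sum(np.log(w)))
            r = Pi @ mi - P0 @ mu0
            const += 0.5 * (
                np.linalg.slogdet(Pi)[1] + ld_Qinv + ld_S0 - ld_Pr
            ) + 0.5 * (r @ Pr_inv @ r - mi @ Pi @ mi + mu0 @ P0 @ mu0)
            G[i] = Qinv @ Pr_inv @ r
            quad_blocks.append(Qinv @ Pr_inv @ Qinv - Qinv)
        # assemble gradient/Hessian over beta (regressor-major vec)
        g = np.zeros(R * k)
        H = np.zeros((R * k, R * k))
        for i in range(design.n):
            xi = X[i]
            for r1 in range(R):
                g[r1 * k:(r1 + 1) * k] += xi[r1] * G[i]
                for r2 in range(R):
                    H[r1 * k:(r1 + 1) * k, r2 * k:(r2 + 1) * k] += (
                        xi[r1] * xi[r2] * quad_blocks[i]
                    )
        H = H - Pb0
        g = g + Pb0 @ beta_prior.mean
        negH = -(0.5 * (H + H.T))
        w, V = np.linalg.eigh(negH)
        w = np.maximum(w, 1e-12)
        negH_inv = (V / w) @ V.T
        beta = negH_inv @ g
        # T(0) includes the beta-prior normal density at 0
        t0 = const - 0.5 * (
            beta_prior.mean @ Pb0 @ beta_prior.mean
            + np.linalg.slogdet(beta_prior.cov)[1] + R * k * LOG2PI
        )
        logZ = (
            t0 + 0.5 * g @ negH_inv @ g
            + 0.5 * (R * k * LOG2PI - float(np.sum(np.log(w))))
        )
        return logZ, beta, negH_inv

    gm, gv = gamma_prior

    def objective(gamma):
        logZ, _, _ = profile(gamma)
        return -(logZ - 0.5 * (gamma - gm) ** 2 / gv)

    res = minimize_scalar(objective, bounds=(-5.0, 6.0), method="bounded",
                          options={"xatol": 1e-3})
    gamma = float(res.x)
    logZ, beta_vec, beta_cov = profile(gamma)
    # Laplace over gamma
    h = 1e-3
    f0, fp, fm = (-objective(gamma), -objective(gamma + h), -objective(gamma - h))
    curv = (fp - 2 * f0 + fm) / h**2
    gamma_var = float(-1.0 / curv) if curv < 0 else np.inf
    F = f0 + (0.5 * (np.log(2 * np.pi) + np.log(gamma_var)) if np.isfinite(gamma_var)
              else 0.0) - 0.5 * (np.log(2 * np.pi * gv))
    # empirical-Bayes update of each subject's first-level mean
    Qinv = np.exp(gamma) * Qbase_inv
    subject_means = np.empty((design.n, k))
    for i in range(design.n):
        Pr = 0.5 * ((Ps[i] - P0 + Qinv) + (Ps[i] - P0 + Qinv).T)
        mu_emp = np.zeros(k)
        for r1 in range(R):
            mu_emp += X[i, r1] * beta_vec[r1 * k:(r1 + 1) * k]
        subject_means[i] = np.linalg.solve(
            Pr, Ps[i] @ ms[i] - P0 @ mu0 + Qinv @ mu_emp
        )
    return GroupEstimates(
        connections=conn,
        regressors=design.regressors,
        beta=beta_vec.reshape(R, k),
        beta_cov=beta_cov,
        free_energy=float(F),
        gamma=gamma,
        gamma_var=gamma_var,
        design=design,
        beta_prior=beta_prior,
        subject_means=subject_means,
        diagnostics={"field": fld, "logZ": float(logZ)},
    )


def combine_contributions(
    estimates: GroupEstimates,
    connection: str,
    carryover: float = 0.0,
    timepoint: float = 0.0,
    capacity: float = 0.0,
) -> float:
    """Overall connection magnitude (Hz) as the signed sum of contributions.

    Returns theta_mean + carryover*theta_CE + timepoint*theta_t +
    capacity*theta_CS; regressors absent from the design contribute 0.
    """
    if connection not in estimates.connections:
        raise KeyError(f"unknown connection {connection!r}")
    weights = {"mean": 1.0, "carryover": carryover, "time": timepoint,
               "capacity": capacity}
    total = 0.0
    for reg in estimates.regressors:
        total += weights[reg] * estimates.coefficient(reg, connection)
    return float(total)


def peb_search(
    estimates: GroupEstimates,
    switchable: list | None = None,
    cap: int = 4096,
    occam_mass: float = 0.95,
):
    """Exhaustive second-level search over on/off connection patterns.

    Switching a connection off pins its coefficients (all regressors) to
    zero-variance priors; each pattern is scored by Bayesian model
    reduction of the beta posterior, and the retained (Occam window) set is
    Bayesian-model-averaged.  A switchable element may also be a tuple of
    connection names that are switched jointly (e.g. a bidirectional pair).
    If the pattern count exceeds ``cap``, the search space is pruned to the
    floor(log2(cap)) elements with the weakest individual evidence of being
    present, the rest staying on.

    Returns (BMA GroupEstimates, per-element inclusion probability keyed by
    connection name or "a|b" for tuples, ModelComparison).
    """
    if switchable is None:
        switchable = list(estimates.connections)
    flat = [c for el in switchable for c in (el if isinstance(el, tuple) else (el,))]
    unknown = [c for c in flat if c not in estimates.connections]
    if unknown:
        raise KeyError(f"unknown connections {unknown}")
    k = estimates.n_connections
    R = len(estimates.regressors)
    post = estimates.as_posterior()
    prior = estimates.beta_prior
    n_par = R * k

    def conn_indices(el):
        conns = el if isinstance(el, tuple) else (el,)
        return [
            r * k + estimates.connections.index(c)
            for c in conns
            for r in range(R)
        ]

    def el_key(el):
        return "|".join(el) if isinstance(el, tuple) else el

    if 2 ** len(switchable) > cap:
        n_keep = max(1, int(np.floor(np.log2(cap))))
        # weakest single-connection evidence = least dF loss when pinned
        losses = []
        for c in switchable:
            sw = np.ones(n_par, bool)
            sw[conn_indices(c)] = False
            _, dF = bayesian_model_reduction(prior, post, reduce_prior(prior, sw))
            losses.append(dF)
        order = np.argsort(losses)[::-1]  # largest dF (least harmful to pin) first
        switchable = [switchable[i] for i in order[:n_keep]]

    patterns = list(itertools.product((True, False), repeat=len(switchable)))
    dFs, posts, ids = [], [], []
    for bits in patterns:
        sw = np.ones(n_par, bool)
        for c, on in zip(switchable, bits):
            if not on:
                sw[conn_indices(c)] = False
        red, dF = bayesian_model_reduction(prior, post, reduce_prior(prior, sw))
        dFs.append(dF)
        posts.append(red)
        ids.append(
            ",".join(el_key(c) for c, on in zip(switchable, bits) if on) or "none"
        )
    comparison = ModelComparison(identifiers=ids, free_energies=np.array(dFs))
    probs = comparison.probabilities
    keep = occam_window(probs, occam_mass)
    bma = bayesian_model_average(
        [posts[i] for i in keep], probs[keep] / probs[keep].sum()
    )
    switched = {c for el in switchable
                for c in (el if isinstance(el, tuple) else (el,))}
    inclusion = {
        c: 1.0 for c in estimates.connections if c not in switched
    }
    for j, el in enumerate(switchable):
        inclusion[el_key(el)] = float(
            sum(p for p, bits in zip(probs, patterns) if bits[j])
        )
    bma_est = GroupEstimates(
        connections=estimates.connections,
        regressors=estimates.regressors,
        beta=bma.mean.reshape(R, k),
        beta_cov=bma.cov,
        free_energy=estimates.free_energy,
        gamma=estimates.gamma,
        gamma_var=estimates.gamma_var,
        design=estimates.design,
        beta_prior=prior,
        subject_means=estimates.subject_means,
        diagnostics={"search": "bmr-exhaustive", "n_models": len(patterns)},
    )
    return bma_est, inclusion, comparison
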