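"""Evidence-based model comparison: BMS, Bayesian model reduction, BMA.

Reduced models switch parameters off by pinning their prior variance to a
tiny value (1e-8), so every model shares one parameterization and the
evidence of any reduced model follows analytically from the full model's
prior and posterior -- no re-inversion of the data.  Posterior model
probabilities are the softmax of free energies under uniform model priors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .inversion import Posterior, PriorSpec

PINNED_VARIANCE = 1e-8


@dataclass
class ReducedModel:
    """An on/off pattern over switchable parameters."""

    identifier: str
    switch: np.ndarray                 # bool, length = parameter count
    reduced_prior: PriorSpec | None = None
    free_energy: float | None = None
    posterior: Posterior | None = None

    def __post_init__(self):
        self.switch = np.asarray(self.switch, bool)


@dataclass
class ModelComparison:
    identifiers: list[str]
    free_energies: np.ndarray
    probabilities: np.ndarray = field(init=False)

    def __post_init__(self):
        self.free_energies = np.asarray(self.free_energies, float)
        self.probabilities = model_posteriors(self.free_energies)

    def best(self) -> int:
        return int(np.argmax(self.probabilities))


def model_posteriors(F) -> np.ndarray:
    """Posterior model probabilities from free energies (uniform priors)."""
    F = np.asarray(F, float)
    if F.size == 0:
        raise ValueError("empty free-energy vector")
    if not np.all(np.isfinite(F)):
        raise ValueError("free energies must be finite")
    z = F - F.max()
    p = np.exp(z)
    return p / p.sum()


def reduce_prior(prior: PriorSpec, switch, pinned_mean=None) -> PriorSpec:
    """Pin switched-off parameters to (near) zero prior variance."""
    switch = np.asarray(switch, bool)
    cov = prior.cov.copy()
    mean = prior.mean.copy()
    off = ~switch
    cov[off, :] = 0.0
    cov[:, off] = 0.0
    cov[off, off] = PINNED_VARIANCE
    if pinned_mean is not None:
        mean[off] = pinned_mean
    else:
        mean[off] = 0.0
    return PriorSpec(mean=mean, cov=cov, names=prior.names)


def bayesian_model_reduction(
    full_prior: PriorSpec,
    full_posterior: Posterior,
    reduced_prior: PriorSpec,
) -> tuple[Posterior, float]:
    """Analytic posterior and evidence change under a new (reduced) prior.

    Returns ``(reduced posterior, dF)`` where dF = log evidence(reduced) -
    log evidence(full).  Derivation: the evidence ratio equals the
    expectation of the prior ratio under the full posterior, a Gaussian
    integral with precision  Pr = P + P0r - P0.
    """
    P = np.linalg.inv(full_posterior.cov)
    P0 = full_prior.precision
    P0r = reduced_prior.precision
    Pr = P + P0r - P0
    Pr = 0.5 * (Pr + Pr.T)
    sign, ld_Pr = np.linalg.slogdet(Pr)
    if sign <= 0:
        raise np.linalg.LinAlgError(
            "reduced posterior precision is not positive definite "
            f"(slogdet sign {sign}); conditioning: |P|~{np.linalg.cond(P):.2e}"
        )
    mu, mu0, mu0r = full_posterior.mean, full_prior.mean, reduced_prior.mean
    b = P @ mu + P0r @ mu0r - P0 @ mu0
    Sr = np.linalg.inv(Pr)
    Sr = 0.5 * (Sr + Sr.T)
    mr = Sr @ b
    ld_P = np.linalg.slogdet(P)[1]
    ld_P0 = np.linalg.slogdet(P0)[1]
    ld_P0r = np.linalg.slogdet(P0r)[1]
    c = mu @ P @ mu + mu0r @ P0r @ mu0r - mu0 @ P0 @ mu0
    dF = 0.5 * (ld_P + ld_P0r - ld_P0 - ld_Pr) + 0.5 * (b @ Sr @ b - c)
    reduced = Posterior(
        mean=mr,
        cov=Sr,
        free_energy=full_posterior.free_energy + float(dF),
        names=full_posterior.names,
        lam=full_posterior.lam,
        prior=reduced_prior,
    )
    return reduced, float(dF)


def bayesian_model_average(
    posteriors: list[Posterior],
    probabilities,
    occam_min_prob: float = 0.0,
) -> Posterior:
    """Moment-matched Gaussian mixture over retained models.

    Models with probability below ``occam_min_prob`` are dropped and the
    rest renormalized; the returned covariance is the within- plus
    between-model covariance of the truncated mixture.
    """
    p = np.asarray(probabilities, float)
    if len(posteriors) != p.size:
        raise ValueError("probabilities do not match posterior list")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("probabilities must sum to 1")
    keep = p >= occam_min_prob
    if not np.any(keep):
        raise ValueError("all models fall below the Occam threshold")
    p = p[keep] / p[keep].sum()
    kept = [q for q, k in zip(posteriors, keep) if k]
    mean = sum(w * q.mean for w, q in zip(p, kept))
    cov = sum(
        w * (q.cov + np.outer(q.mean - mean, q.mean - mean))
        for w, q in zip(p, kept)
    )
    F = float(sum(w * q.free_energy for w, q in zip(p, kept)))
    return Posterior(
        mean=mean, cov=cov, free_energy=F, names=kept[0].names,
        diagnostics={"n_models": int(keep.sum())},
    )


def occam_window(probabilities, mass: float = 0.95) -> np.ndarray:
    """Indices of the smallest model set with cumulative probability >= mass."""
    p = np.asarray(probabilities, float)
    order = np.argsort(p)[::-1]
    cum = np.cumsum(p[order])
    k = int(np.searchsorted(cum, mass) + 1)
    return np.sort(order[:min(k, p.size)])


def enumerate_reduced_models(
    switchable: np.ndarray | list,
    cap: int = 4096,
    n_params: int | None = None,
) -> list[ReducedModel]:
    """All on/off combinations of the switchable parameters.

    ``switchable`` holds indices into the parameter vector (length
    ``n_params``; defaults to max index + 1).  Non-switchable parameters are
    always on.
    """
    idx = np.asarray(switchable, int)
    if 2 ** idx.size > cap:
        raise ValueError(
            f"2^{idx.size} models exceed cap={cap}; use a greedy/pruned search"
        )
    if n_params is None:
        n_params = int(idx.max()) + 1 if idx.size else 1
    out = []
    for bits in itertools.product((True, False), repeat=idx.size):
        switch = np.ones(n_params, bool)
        switch[idx] = bits
        name = "full" if all(bits) else "off:" + ",".join(
            str(i) for i, b in zip(idx, bits) if not b
        )
        out.append(ReducedModel(identifier=name, switch=switch))
    return out
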