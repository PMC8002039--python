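"""Forward model: bilinear neural dynamics, hemodynamics, BOLD observation.

Neural activity x (one state per region) evolves as

    dx/dt = (A + sum_j u_j B_j) x + C u

where A (Hz) is endogenous coupling, B_j (Hz) the modulation of coupling by
experimental input j, and C (Hz per unit input) the direct driving input.
Convention: ``A[target, source]`` throughout, including serialization.

Each region's neural activity drives a standard 4-state balloon-windkessel
hemodynamic cascade (vasodilatory signal s, blood inflow f, venous volume v,
deoxyhemoglobin content q; the last three are log-transformed internally to
enforce positivity), observed as percent BOLD signal change

    y = 100 V0 [k1 (1-q) + k2 (1-q/v) + k3 (1-v)].

Integration is fixed-step RK4 at the paradigm's microtime resolution with
inputs held piecewise-constant per bin; the hot loop is JIT-compiled with
numba, with a pure-NumPy reference path used for unit-level checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

REGIONS = ("M1", "S1", "SMA", "AG")
INPUTS = ("V", "E", "P")
MODULATORY = ("E",)  # only stimulation modulates coupling


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityModel:
    """A/B/C matrices with structure masks.

    ``B`` is stacked (n_modulatory, n, n), one slice per modulatory input in
    the order of ``modulatory``.  Masked-out entries must be exactly zero.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    regions: tuple = REGIONS
    inputs: tuple = INPUTS
    modulatory: tuple = MODULATORY
    a_mask: np.ndarray | None = None
    b_mask: np.ndarray | None = None
    c_mask: np.ndarray | None = None

    def __post_init__(self):
        self.A = np.asarray(self.A, float)
        self.B = np.asarray(self.B, float)
        self.C = np.asarray(self.C, float)
        n = len(self.regions)
        if self.B.ndim == 2:
            self.B = self.B[None, :, :]
        if self.a_mask is None:
            self.a_mask = np.ones((n, n), bool)
        if self.b_mask is None:
            self.b_mask = self.B != 0
        if self.c_mask is None:
            self.c_mask = self.C != 0
        self.a_mask = np.asarray(self.a_mask, bool)
        self.b_mask = np.asarray(self.b_mask, bool)
        self.c_mask = np.asarray(self.c_mask, bool)
        if self.b_mask.ndim == 2:
            self.b_mask = self.b_mask[None, :, :]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def validate(self, require_stable: bool = True) -> None:
        if np.any(self.A[~self.a_mask] != 0):
            raise ValueError("A has nonzero entries outside its structure mask")
        if np.any(self.B[~self.b_mask] != 0):
            raise ValueError("B has nonzero entries outside its structure mask")
        if np.any(self.C[~self.c_mask] != 0):
            raise ValueError("C has nonzero entries outside its structure mask")
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("diagonal of A (self-decay) must be strictly negative")
        if require_stable:
            ok, report = check_stability(self.A)
            if not ok:
                raise ValueError(f"A is unstable: {report}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "regions": list(self.regions),
                "inputs": list(self.inputs),
                "modulatory": list(self.modulatory),
                "A": self.A.tolist(),
                "B": self.B.tolist(),
                "C": self.C.tolist(),
                "a_mask": self.a_mask.astype(int).tolist(),
                "b_mask": self.b_mask.astype(int).tolist(),
                "c_mask": self.c_mask.astype(int).tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ConnectivityModel":
        d = json.loads(text)
        return cls(
            A=np.array(d["A"]),
            B=np.array(d["B"]),
            C=np.array(d["C"]),
            regions=tuple(d["regions"]),
            inputs=tuple(d["inputs"]),
            modulatory=tuple(d["modulatory"]),
            a_mask=np.array(d["a_mask"], bool),
            b_mask=np.array(d["b_mask"], bool),
            c_mask=np.array(d["c_mask"], bool),
        )


@dataclass
class HemodynamicParams:
    """Balloon-windkessel parameters, one value per region unless scalar.

    kappa: vasodilatory signal decay rate (1/s); gamma: flow autoregulation
    rate (1/s); tau: mean transit time (s); alpha: vessel stiffness exponent;
    E0: resting oxygen extraction fraction; V0: resting venous volume
    fraction entering the BOLD scaling.
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    E0: float = 0.4
    V0: float = 0.04

    def validate(self) -> None:
        for name in ("kappa", "gamma", "tau"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive")
        if not np.all((0 < np.asarray(self.E0)) & (np.asarray(self.E0) < 1)):
            raise ValueError("E0 must lie in (0, 1)")
        if not np.all((0 < np.asarray(self.alpha)) & (np.asarray(self.alpha) <= 1)):
            raise ValueError("alpha must lie in (0, 1]")

    def arrays(self, n: int) -> tuple:
        out = []
        for name in ("kappa", "gamma", "tau", "alpha", "E0"):
            v = np.asarray(getattr(self, name), float)
            out.append(np.full(n, v) if v.ndim == 0 else v.astype(float))
        return tuple(out)

    def bold_constants(self) -> tuple:
        E0 = float(np.mean(np.asarray(self.E0)))
        return 7.0 * E0, 2.0, 2.0 * E0 - 0.2


@dataclass
class SystemState:
    """Neural + hemodynamic state of all regions at one time point.

    ``log_f/log_v/log_q`` hold inflow, volume, and deoxyhemoglobin on the
    log scale (rest = 0); ``s`` is the vasodilatory signal.
    """

    x: np.ndarray
    s: np.ndarray
    log_f: np.ndarray
    log_v: np.ndarray
    log_q: np.ndarray

    @classmethod
    def rest(cls, n: int) -> "SystemState":
        z = np.zeros(n)
        return cls(z.copy(), z.copy(), z.copy(), z.copy(), z.copy())


# ---------------------------------------------------------------------------
# derivatives (reference implementations)
# ---------------------------------------------------------------------------

def neural_derivative(x, u, model: ConnectivityModel) -> np.ndarray:
    """dx/dt = (A + sum_j u_j B_j) x + C u, evaluated exactly."""
    x = np.asarray(x, float)
    u = np.asarray(u, float)
    n, m = model.C.shape
    if x.shape != (n,) or u.shape != (m,):
        raise ValueError(
            f"dimension mismatch: x{x.shape}, u{u.shape} vs model ({n} regions,"
            f" {m} inputs)"
        )
    A_eff = model.A.copy()
    mod_idx = [model.inputs.index(lab) for lab in model.modulatory]
    for j, idx in enumerate(mod_idx):
        A_eff += u[idx] * model.B[j]
    return A_eff @ x + model.C @ u


def hemodynamic_derivative(state: SystemState, params: HemodynamicParams):
    """Time derivative of (s, log f, log v, log q) given neural drive x."""
    clip = lambda a: np.clip(a, -8.0, 8.0)
    f, v, q = (np.exp(clip(state.log_f)), np.exp(clip(state.log_v)),
               np.exp(clip(state.log_q)))
    if np.any(f <= 0) or np.any(v <= 0) or np.any(q <= 0):
        raise ValueError("natural-scale hemodynamic states must be positive")
    n = state.x.size
    kappa, gamma, tau, alpha, E0 = params.arrays(n)
    ds = state.x - kappa * state.s - gamma * (f - 1.0)
    dlf = state.s / f
    outflow = v ** (1.0 / alpha)
    dlv = (f - outflow) / (tau * v)
    Ef = 1.0 - (1.0 - E0) ** (1.0 / f)
    dlq = (f * Ef / E0 - outflow * q / v) / (tau * q)
    return ds, dlf, dlv, dlq


def bold_observe(state: SystemState, params: HemodynamicParams) -> np.ndarray:
    """Percent BOLD signal change; depends only on volume and deoxyhemoglobin."""
    v, q = np.exp(state.log_v), np.exp(state.log_q)
    k1, k2, k3 = params.bold_constants()
    return 100.0 * params.V0 * (
        k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v)
    )


def check_stability(A: np.ndarray) -> tuple[bool, str]:
    """True iff every eigenvalue of A has negative real part."""
    A = np.asarray(A, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be a square matrix")
    eig = np.linalg.eigvals(A)
    worst = eig[np.argmax(eig.real)]
    ok = bool(np.all(eig.real < 0))
    return ok, f"max-real-part eigenvalue {worst:.4f}"


# ---------------------------------------------------------------------------
# fast integrator
# ---------------------------------------------------------------------------

@njit(cache=True)
def _integrate_kernel(A, B, C, U, mod_idx, dt, bins_per_vol, n_vols,
                      kappa, gamma, tau, alpha, E0, V0, k1, k2, k3):
    n = A.shape[0]
    d = 5 * n  # state layout: [x, s, lf, lv, lq]
    y = np.zeros(d)
    Y = np.empty((n, n_vols))
    n_mod = B.shape[0]
    m = U.shape[1]
    Aeff = np.empty((n, n))
    Cu = np.empty(n)
    k1v = np.empty(d); k2v = np.empty(d); k3v = np.empty(d); k4v = np.empty(d)
    yt = np.empty(d)
    ia = 1.0 / alpha
    ib = 0
    for vol in range(n_vols):
        for i in range(n):
            v = np.exp(y[3 * n + i])
            q = np.exp(y[4 * n + i])
            Y[i, vol] = 100.0 * V0 * (
                k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v)
            )
        if vol == n_vols - 1:
            break
        for _ in range(bins_per_vol):
            u = U[ib]
            for r in range(n):
                acc = 0.0
                for c in range(m):
                    acc += C[r, c] * u[c]
                Cu[r] = acc
                for c in range(n):
                    a = A[r, c]
                    for j in range(n_mod):
                        uj = u[mod_idx[j]]
                        if uj != 0.0:
                            a += uj * B[j, r, c]
                    Aeff[r, c] = a
            _deriv(y, Aeff, Cu, kappa, gamma, tau, ia, E0, n, k1v)
            for i in range(d):
                yt[i] = y[i] + 0.5 * dt * k1v[i]
            _deriv(yt, Aeff, Cu, kappa, gamma, tau, ia, E0, n, k2v)
            for i in range(d):
                yt[i] = y[i] + 0.5 * dt * k2v[i]
            _deriv(yt, Aeff, Cu, kappa, gamma, tau, ia, E0, n, k3v)
            for i in range(d):
                yt[i] = y[i] + dt * k3v[i]
            _deriv(yt, Aeff, Cu, kappa, gamma, tau, ia, E0, n, k4v)
            c6 = dt / 6.0
            for i in range(d):
                y[i] += c6 * (k1v[i] + 2.0 * k2v[i] + 2.0 * k3v[i] + k4v[i])
            # numerical guard: saturate states far outside physiology so
            # badly conditioned parameter proposals yield a finite (poor)
            # prediction instead of a floating-point failure
            for i in range(2 * n):
                if y[i] > 50.0:
                    y[i] = 50.0
                elif y[i] < -50.0:
                    y[i] = -50.0
            for i in range(2 * n, d):
                if y[i] > 8.0:
                    y[i] = 8.0
                elif y[i] < -8.0:
                    y[i] = -8.0
            ib += 1
    return Y


@njit(cache=True, inline="always")
def _deriv(y, Aeff, Cu, kappa, gamma, tau, inv_alpha, E0, n, out):
    for i in range(n):
        acc = Cu[i]
        for c in range(n):
            acc += Aeff[i, c] * y[c]
        out[i] = acc
    for i in range(n):
        s = y[n + i]
        # clamp log-states at the point of use: RK4 stage points can
        # overshoot for pathological parameters, and exp underflow to an
        # exact 0 would poison the division below
        lf = min(max(y[2 * n + i], -8.0), 8.0)
        lv = min(max(y[3 * n + i], -8.0), 8.0)
        lq = min(max(y[4 * n + i], -8.0), 8.0)
        f = np.exp(lf)
        v = np.exp(lv)
        q = np.exp(lq)
        out[n + i] = y[i] - kappa[i] * s - gamma[i] * (f - 1.0)
        out[2 * n + i] = s / f
        outflow = v ** inv_alpha[i]
        out[3 * n + i] = (f - outflow) / (tau[i] * v)
        Ef = 1.0 - (1.0 - E0[i]) ** (1.0 / f)
        out[4 * n + i] = (f * Ef / E0[i] - outflow * q / v) / (tau[i] * q)


def simulate_bold(
    model: ConnectivityModel,
    hemo: HemodynamicParams,
    paradigm,
    inputs,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate BOLD series (% signal change), shape (n_regions, n_volumes).

    Volume k is sampled at t = k*tr; additive white Gaussian noise of the
    requested standard deviation is applied per region.  Deterministic given
    ``seed``.
    """
    model.validate(require_stable=True)
    hemo.validate()
    from .paradigm import input_matrix

    U = input_matrix(inputs) if not isinstance(inputs, np.ndarray) else inputs
    n = model.n_regions
    kappa, gamma, tau, alpha, E0 = hemo.arrays(n)
    k1, k2, k3 = hemo.bold_constants()
    mod_idx = np.array(
        [model.inputs.index(lab) for lab in model.modulatory], np.int64
    )
    Y = _integrate_kernel(
        np.ascontiguousarray(model.A),
        np.ascontiguousarray(model.B),
        np.ascontiguousarray(model.C),
        np.ascontiguousarray(U, dtype=np.float64),
        mod_idx,
        float(paradigm.microtime_dt),
        paradigm.bins_per_volume,
        paradigm.n_volumes,
        kappa, gamma, tau, alpha, E0,
        float(hemo.V0), k1, k2, k3,
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        Y = Y + rng.normal(0.0, noise_sd, Y.shape)
    return Y


def simulate_bold_reference(model, hemo, paradigm, inputs) -> np.ndarray:
    """Pure-NumPy RK4 integration, used to validate the compiled kernel."""
    from .paradigm import input_matrix

    U = input_matrix(inputs) if not isinstance(inputs, np.ndarray) else inputs
    n = model.n_regions
    dt = paradigm.microtime_dt
    state = SystemState.rest(n)
    Y = np.empty((n, paradigm.n_volumes))
    mod_idx = [model.inputs.index(lab) for lab in model.modulatory]
    ib = 0

    def deriv(vec, u):
        st = SystemState(*np.split(vec, 5))
        dx = neural_derivative(st.x, u, model)
        ds, dlf, dlv, dlq = hemodynamic_derivative(st, hemo)
        return np.concatenate([dx, ds, dlf, dlv, dlq])

    vec = np.zeros(5 * n)
    for vol in range(paradigm.n_volumes):
        Y[:, vol] = bold_observe(SystemState(*np.split(vec, 5)), hemo)
        if vol == paradigm.n_volumes - 1:
            break
        for _ in range(paradigm.bins_per_volume):
            u = U[ib]
            r1 = deriv(vec, u)
            r2 = deriv(vec + 0.5 * dt * r1, u)
            r3 = deriv(vec + 0.5 * dt * r2, u)
            r4 = deriv(vec + dt * r3, u)
            vec = vec + dt / 6.0 * (r1 + 2 * r2 + 2 * r3 + r4)
            vec[: 2 * n] = np.clip(vec[: 2 * n], -50.0, 50.0)
            vec[2 * n:] = np.clip(vec[2 * n:], -8.0, 8.0)
            ib += 1
    return Y


# ---------------------------------------------------------------------------
# parameter vector <-> matrices
# ---------------------------------------------------------------------------

def parameter_names(model: ConnectivityModel) -> list[str]:
    """Names of free parameters in pack order, e.g. ``A:SMA->M1``.

    Order: A entries (row-major over the mask), then B per modulatory input,
    then C.  ``A[target, source]`` maps to ``A:source->target``.
    """
    names = []
    reg, inp = model.regions, model.inputs
    for t in range(len(reg)):
        for s_ in range(len(reg)):
            if model.a_mask[t, s_]:
                names.append(f"A:{reg[s_]}->{reg[t]}")
    for j, lab in enumerate(model.modulatory):
        prefix = "B" if len(model.modulatory) == 1 else f"B{j + 1}"
        for t in range(len(reg)):
            for s_ in range(len(reg)):
                if model.b_mask[j, t, s_]:
                    names.append(f"{prefix}:{reg[s_]}->{reg[t]}")
    for t in range(len(reg)):
        for m in range(len(inp)):
            if model.c_mask[t, m]:
                names.append(f"C:{inp[m]}->{reg[t]}")
    return names


def pack_parameters(model: ConnectivityModel) -> np.ndarray:
    parts = [model.A[model.a_mask]]
    for j in range(model.B.shape[0]):
        parts.append(model.B[j][model.b_mask[j]])
    parts.append(model.C[model.c_mask])
    return np.concatenate(parts)


def unpack_parameters(theta: np.ndarray, template: ConnectivityModel) -> ConnectivityModel:
    theta = np.asarray(theta, float)
    A = np.zeros_like(template.A)
    B = np.zeros_like(template.B)
    C = np.zeros_like(template.C)
    i = int(template.a_mask.sum())
    A[template.a_mask] = theta[:i]
    for j in range(B.shape[0]):
        k = int(template.b_mask[j].sum())
        B[j][template.b_mask[j]] = theta[i:i + k]
        i += k
    k = int(template.c_mask.sum())
    C[template.c_mask] = theta[i:i + k]
    return replace(
        template, A=A, B=B, C=C,
        a_mask=template.a_mask.copy(),
        b_mask=template.b_mask.copy(),
        c_mask=template.c_mask.copy(),
    )
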