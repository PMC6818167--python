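"""Free-energy estimators over λ states: MBAR and thermodynamic integration.

MBAR solves the self-consistent equations

    f_i = −ln Σ_n exp(−u_i(x_n)) / Σ_k N_k exp(f_k − u_k(x_n)),

gauge-fixed at f_0 = 0, where u_k are reduced potentials (energy/RT) and
N_k the number of samples drawn from state k. Uncertainties come from the
asymptotic covariance of the estimator. All log-sums are max-shifted; the
solver iterates self-consistently and switches to Newton–Raphson once the
residual drops below 1e-2.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .errors import ConfigurationError, ConvergenceError, InputError
from .units import kt

__all__ = [
    "FreeEnergyResult",
    "LambdaSchedule",
    "ReducedPotentialMatrix",
    "MBARResult",
    "build_lambda_schedule",
    "mbar_free_energies",
    "zwanzig",
    "ti_integrate",
    "propagate_cycle_error",
]


@dataclass(frozen=True)
class FreeEnergyResult:
    """A ΔG (kcal/mol) with 1-SD uncertainty and provenance."""

    dg: float
    sigma: float
    method: str = ""
    leg: str = ""
    temperature: float = 310.0
    units: str = "kcal/mol"

    def __post_init__(self):
        if self.sigma < 0:
            raise InputError("uncertainty must be ≥ 0")


@dataclass(frozen=True)
class LambdaSchedule:
    """Named legs of λ values, each tagged with the interaction it switches."""

    name: str
    legs: tuple  # of (leg_name, component, tuple_of_lambdas)

    def __post_init__(self):
        for leg_name, component, lams in self.legs:
            arr = np.asarray(lams, dtype=float)
            if arr.size < 2 or np.any(np.diff(arr) <= 0):
                raise ConfigurationError(f"leg {leg_name!r} must be strictly increasing")
            if np.any((arr < 0) | (arr > 1)):
                raise ConfigurationError(f"leg {leg_name!r} values must lie in [0, 1]")
            if component == "coulomb" and (arr[0] != 0.0 or arr[-1] != 1.0):
                raise ConfigurationError(f"charge leg {leg_name!r} must span 0..1")
            if arr[-1] != 1.0:
                raise ConfigurationError(f"leg {leg_name!r} must end at λ=1")

    @property
    def n_windows(self) -> int:
        return sum(len(lams) for _, _, lams in self.legs)

    def leg_lambdas(self, leg_name: str) -> tuple:
        for name, _, lams in self.legs:
            if name == leg_name:
                return tuple(lams)
        raise KeyError(leg_name)


_COULOMB_11 = tuple(round(0.1 * i, 10) for i in range(11))
_VDW_15 = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 1.0)
_RESTRAINT_10 = (0.01, 0.025, 0.05, 0.075, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0)
_BONDED_VDW_5 = (0.0, 0.25, 0.5, 0.75, 1.0)

# λ=0 of the vdw/restraint legs coincides with the endpoint of the previous
# leg and is not a separately sampled window, so those legs start above 0.
_PROTOCOLS = {
    "abfe_complex": (
        ("restrain", "restraint", _RESTRAINT_10),
        ("discharge", "coulomb", _COULOMB_11),
        ("decouple", "vdw", _VDW_15),
    ),
    "abfe_water": (
        ("discharge", "coulomb", _COULOMB_11),
        ("decouple", "vdw", _VDW_15),
    ),
    "protonation": (
        ("charge", "coulomb", _COULOMB_11),
        ("bonded_vdw", "bonded+vdw", _BONDED_VDW_5),
    ),
}


def uniform_lambdas(dlam: float) -> tuple:
    """Uniform λ grid 0..1 inclusive; dlam must divide 1 exactly."""
    n = 1.0 / dlam
    if abs(n - round(n)) > 1e-9:
        raise ConfigurationError(f"Δλ={dlam} does not divide [0, 1]")
    return tuple(round(i * dlam, 12) for i in range(int(round(n)) + 1))


def build_lambda_schedule(protocol: str) -> LambdaSchedule:
    """The λ-window registry: ``abfe_complex`` (36 windows: 10 restraint +
    11 coulomb + 15 vdw), ``abfe_water`` (26), ``protonation`` (16: 11
    charge + 5 bonded+vdw)."""
    if protocol not in _PROTOCOLS:
        raise ConfigurationError(
            f"unknown λ protocol {protocol!r}; choose from {sorted(_PROTOCOLS)}"
        )
    return LambdaSchedule(name=protocol, legs=_PROTOCOLS[protocol])


@dataclass
class ReducedPotentialMatrix:
    """u_kn: reduced potential of every sample evaluated in every state."""

    u_kn: np.ndarray  # (K states, N samples), dimensionless
    n_k: np.ndarray  # samples drawn from each state; Σ n_k = N
    temperature: float = 310.0
    exact_f: np.ndarray | None = None  # ground truth (synthetic ensembles)

    def __post_init__(self):
        self.u_kn = np.asarray(self.u_kn, dtype=float)
        self.n_k = np.asarray(self.n_k, dtype=int)
        if self.u_kn.ndim != 2:
            raise InputError("u_kn must be a 2D (states × samples) matrix")
        if self.n_k.size != self.u_kn.shape[0]:
            raise InputError("N_k length must equal number of states")
        if int(self.n_k.sum()) != self.u_kn.shape[1]:
            raise InputError("Σ N_k must equal the number of sample columns")
        if np.any(self.n_k < 0):
            raise InputError("N_k must be nonnegative")
        if not np.all(np.isfinite(self.u_kn)):
            raise InputError("u_kn contains non-finite entries")

    @property
    def n_states(self) -> int:
        return self.u_kn.shape[0]


@dataclass
class MBARResult:
    f_k: np.ndarray  # reduced free energies, f_0 = 0
    delta_g: np.ndarray  # (K, K) pairwise ΔG_ij = G_j − G_i, kcal/mol
    d_delta_g: np.ndarray  # (K, K) 1-SD uncertainties, kcal/mol
    theta: np.ndarray  # asymptotic covariance of f_k
    temperature: float
    n_iter: int

    def result(self, i: int = 0, j: int = -1, leg: str = "") -> FreeEnergyResult:
        return FreeEnergyResult(
            dg=float(self.delta_g[i, j]),
            sigma=float(self.d_delta_g[i, j]),
            method="mbar",
            leg=leg,
            temperature=self.temperature,
        )


def _mbar_log_denom(f_s, u_s, log_n_s):
    # log Σ_k N_k exp(f_k − u_kn), over sampled states only
    return logsumexp(log_n_s[:, None] + f_s[:, None] - u_s, axis=0)


def mbar_free_energies(
    matrix: ReducedPotentialMatrix,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> MBARResult:
    """Solve MBAR; returns reduced free energies, pairwise ΔG (kcal/mol),
    and uncertainties from the asymptotic covariance.

    States with N_k = 0 are treated as perturbation targets: they receive
    free energies and uncertainties but do not enter the mixture
    distribution.
    """
    u = matrix.u_kn
    n_k = matrix.n_k
    K, N = u.shape
    if K < 2:
        raise InputError("MBAR needs at least two states")
    if N < 1 or n_k.sum() == 0:
        raise InputError("MBAR needs at least one sample")
    rt = kt(matrix.temperature)

    sampled = np.flatnonzero(n_k > 0)
    u_s = u[sampled]
    n_s = n_k[sampled].astype(float)
    log_n_s = np.log(n_s)
    f_s = np.zeros(sampled.size)

    newton = False
    resid = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        log_denom = _mbar_log_denom(f_s, u_s, log_n_s)
        if not newton:
            f_new = -logsumexp(-u_s - log_denom[None, :], axis=1)
            f_new -= f_new[0]
            resid = float(np.max(np.abs(f_new - f_s)))
            f_s = f_new
            if resid < 1e-2:
                newton = True  # polish with Newton–Raphson
        else:
            # p_in = exp(f_i − u_in)/D_n; stationarity: Σ_n p_in = 1
            logp = f_s[:, None] - u_s - log_denom[None, :]
            p = np.exp(logp)
            row = p.sum(axis=1)
            grad = n_s * (row - 1.0)
            # hessian of Σ_n ln D_n − Σ_k N_k f_k:
            # H_ij = δ_ij N_i Σ_n p_in − Σ_n (N_i p_in)(N_j p_jn)
            np_in = n_s[:, None] * p
            hess = np.diag(n_s * row) - np_in @ np_in.T
            # gauge-fix f_0: solve on the reduced system
            g_r = grad[1:]
            h_r = hess[1:, 1:]
            try:
                step = np.linalg.solve(h_r, g_r)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(h_r, g_r, rcond=None)[0]
            f_new = f_s.copy()
            f_new[1:] -= step
            resid = float(np.max(np.abs(f_new - f_s)))
            f_s = f_new
        if resid < tol:
            break
    else:
        raise ConvergenceError(
            f"MBAR did not converge in {max_iter} iterations (residual {resid:.3e})"
        )

    # free energies of all states, including unsampled perturbation states
    log_denom = _mbar_log_denom(f_s, u_s, log_n_s)
    f_all = -logsumexp(-u - log_denom[None, :], axis=1)
    f_all -= f_all[0]

    # asymptotic covariance via the weight matrix W_ni = exp(f_i − u_in)/D_n
    logw = f_all[:, None] - u - log_denom[None, :]
    w = np.exp(logw).T  # (N, K)
    svd_u, s, vt = np.linalg.svd(w, full_matrices=False)
    ndiag = np.diag(n_k.astype(float))
    inner = np.eye(K) - (s[:, None] * vt) @ ndiag @ (vt.T * s[None, :])
    theta = (vt.T * s[None, :]) @ np.linalg.pinv(inner, rcond=1e-12) @ (s[:, None] * vt)

    dvar = theta.diagonal()[:, None] + theta.diagonal()[None, :] - 2.0 * theta
    dvar = np.clip(dvar, 0.0, None)
    delta_f = f_all[None, :] - f_all[:, None]
    return MBARResult(
        f_k=f_all,
        delta_g=rt * delta_f,
        d_delta_g=rt * np.sqrt(dvar),
        theta=theta,
        temperature=matrix.temperature,
        n_iter=it,
    )


def zwanzig(matrix: ReducedPotentialMatrix, i: int, j: int) -> float:
    """One-sided exponential averaging: reduced Δf(i→j) from samples of i."""
    n_k = matrix.n_k
    if n_k[i] == 0:
        raise InputError(f"state {i} has no samples for exponential averaging")
    start = int(n_k[:i].sum())
    sl = slice(start, start + int(n_k[i]))
    du = matrix.u_kn[j, sl] - matrix.u_kn[i, sl]
    return float(-(logsumexp(-du) - np.log(n_k[i])))


def ti_integrate(lambdas, dhdl_means, dhdl_ses=None, leg: str = "", temperature: float = 310.0) -> FreeEnergyResult:
    """Trapezoidal thermodynamic integration of ⟨dH/dλ⟩ (kcal/mol).

    Uncertainty is the quadrature sum of the per-point SEs under the
    trapezoid weights.
    """
    lam = np.asarray(lambdas, dtype=float)
    means = np.asarray(dhdl_means, dtype=float)
    if lam.size != means.size:
        raise InputError("λ grid and ⟨dH/dλ⟩ lengths differ")
    if lam.size < 2:
        raise InputError("TI needs at least two λ points")
    if np.any(np.diff(lam) == 0):
        raise InputError("duplicate λ values")
    if np.any(np.diff(lam) < 0):
        raise InputError("λ values must be strictly increasing")
    dg = float(np.trapezoid(means, lam))
    weights = np.zeros_like(lam)
    weights[0] = (lam[1] - lam[0]) / 2.0
    weights[-1] = (lam[-1] - lam[-2]) / 2.0
    if lam.size > 2:
        weights[1:-1] = (lam[2:] - lam[:-2]) / 2.0
    if dhdl_ses is None:
        sigma = 0.0
    else:
        ses = np.asarray(dhdl_ses, dtype=float)
        sigma = float(np.sqrt(np.sum((weights * ses) ** 2)))
    return FreeEnergyResult(dg=dg, sigma=sigma, method="ti", leg=leg, temperature=temperature)


def propagate_cycle_error(legs, signs=None) -> FreeEnergyResult:
    """Signed sum of legs with uncertainties combined in quadrature."""
    legs = list(legs)
    if not legs:
        raise InputError("need at least one leg")
    if signs is None:
        signs = [1.0] * len(legs)
    if len(signs) != len(legs):
        raise InputError("one sign per leg required")
    temps = {leg.temperature for leg in legs}
    units = {leg.units for leg in legs}
    if len(units) > 1:
        raise InputError(f"mixed units in cycle: {units}")
    dg = float(sum(s * leg.dg for s, leg in zip(signs, legs)))
    sigma = float(np.sqrt(sum(leg.sigma**2 for leg in legs)))
    return FreeEnergyResult(
        dg=dg,
        sigma=sigma,
        method="cycle",
        leg="+".join(leg.leg or leg.method for leg in legs),
        temperature=legs[0].temperature if len(temps) == 1 else float("nan"),
        units=legs[0].units,
    )
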