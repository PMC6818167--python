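"""Refit of a carboxyl-rotation dihedral to a Ryckaert-Bellemans series.

The protonated-glutamate C-C-O-H rotation profile is averaged over
replicate scan energies and fitted (linear weighted least squares) with a
truncated Ryckaert-Bellemans potential

    V(φ) = Σ_{n<n_terms} C_n (cos ψ)ⁿ,   ψ = φ − 180°,

the common MD convention. "Three-term" means C₀, C₁, C₂ free. The refit's
purpose is the syn/anti carboxyl balance, exposed via
:func:`syn_anti_gap` = V(0°) − V(180°).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError

__all__ = [
    "DihedralScan",
    "RBCoefficients",
    "average_scan",
    "fit_rb",
    "rb_eval",
    "rescan_check",
    "syn_anti_gap",
    "rb_to_cosine_series",
    "cosine_series_to_rb",
]


@dataclass
class DihedralScan:
    """Uniform angle grid over [0°, 360°) with per-angle mean energies
    (kcal/mol), standard errors, and optionally the raw replicates."""

    angles: np.ndarray  # deg
    means: np.ndarray
    ses: np.ndarray | None = None
    replicates: list | None = None

    def __post_init__(self):
        self.angles = np.asarray(self.angles, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        if self.angles.size != self.means.size:
            raise InputError("angles and means differ in length")
        if self.angles.size < 2:
            raise InputError("scan needs at least two angles")
        steps = np.diff(self.angles)
        if not np.allclose(steps, steps[0], atol=1e-9):
            raise InputError("angle grid must be uniform")
        if not np.all(np.isfinite(self.means)):
            raise InputError("non-finite scan energies")
        if self.ses is not None:
            self.ses = np.asarray(self.ses, dtype=float)
            if self.ses.size != self.angles.size:
                raise InputError("SE length mismatch")

    @property
    def step(self) -> float:
        return float(self.angles[1] - self.angles[0])

    @property
    def n_angles(self) -> int:
        return int(self.angles.size)


@dataclass(frozen=True)
class RBCoefficients:
    """C₀..C₅ (kcal/mol); coefficients beyond ``n_terms`` are fixed at 0."""

    c: tuple  # always length 6
    n_terms: int = 3

    def __post_init__(self):
        if len(self.c) != 6:
            raise InputError("RB coefficient vector must have length 6")
        if not (1 <= self.n_terms <= 6):
            raise InputError("n_terms must be in 1..6")
        if any(abs(ci) > 0 for ci in self.c[self.n_terms:]):
            raise InputError(f"coefficients beyond the first {self.n_terms} must be zero")


def rb_eval(coeffs: RBCoefficients, phi) -> np.ndarray | float:
    """V(φ) = Σ C_n (cos ψ)ⁿ with ψ = φ − 180°; periodic in 360°."""
    phi = np.asarray(phi, dtype=float)
    cospsi = np.cos(np.deg2rad(phi - 180.0))
    out = np.zeros_like(cospsi)
    for n in range(5, -1, -1):
        out = out * cospsi + coeffs.c[n]
    return out if out.ndim else float(out)


def average_scan(angles, replicate_energies) -> DihedralScan:
    """Per-angle arithmetic mean and standard error over replicates, with
    the global minimum shifted to zero (the fit is offset-invariant via C₀)."""
    angles = np.asarray(angles, dtype=float)
    if len(replicate_energies) != angles.size:
        raise InputError("one replicate list per angle required")
    means, ses = [], []
    for reps in replicate_energies:
        arr = np.asarray(reps, dtype=float)
        if arr.size < 1:
            raise InputError("every angle needs at least one replicate")
        means.append(arr.mean())
        ses.append(arr.std(ddof=1) / np.sqrt(arr.size) if arr.size > 1 else 0.0)
    means = np.array(means)
    means -= means.min()
    return DihedralScan(angles=angles, means=means, ses=np.array(ses),
                        replicates=[np.asarray(r, dtype=float) for r in replicate_energies])


def fit_rb(scan: DihedralScan, n_terms: int = 3):
    """Weighted linear least-squares RB fit.

    Weights are 1/SE² where SEs are available and positive, else uniform.
    Returns ``(RBCoefficients, rms_residual, covariance)``; the covariance
    is the standard (XᵀWX)⁻¹ scaled by the residual variance when weights
    are uniform, or the unscaled (XᵀWX)⁻¹ for 1/SE² weights.
    """
    if not (1 <= n_terms <= 6):
        raise ConfigurationError("n_terms must be in 1..6")
    if scan.n_angles < n_terms:
        raise InputError("fewer angles than free coefficients")
    cospsi = np.cos(np.deg2rad(scan.angles - 180.0))
    design = np.vander(cospsi, N=n_terms, increasing=True)
    if np.linalg.matrix_rank(design) < n_terms:
        raise InputError("rank-deficient design: too few distinct cos ψ values")
    y = scan.means
    if scan.ses is not None and np.all(scan.ses > 0):
        w = 1.0 / scan.ses**2
        weighted = True
    else:
        w = np.ones_like(y)
        weighted = False
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    resid = y - design @ coef
    rms = float(np.sqrt(np.mean(resid**2)))
    xtwx_inv = np.linalg.inv((design * w[:, None]).T @ design)
    if weighted:
        cov = xtwx_inv
    else:
        dof = max(scan.n_angles - n_terms, 1)
        cov = xtwx_inv * float(resid @ resid) / dof
    c = tuple(coef) + (0.0,) * (6 - n_terms)
    return RBCoefficients(c=c, n_terms=n_terms), rms, cov


def rescan_check(coeffs: RBCoefficients, target: DihedralScan, tolerance: float):
    """Compare the fitted potential against a target scan on the same grid.

    The least-squares optimal constant shift is removed first. Returns a
    dict with ``passed``, ``max_deviation`` and the worst angle. The target
    grid must cover one full period, matching the grid the fit used.
    """
    if abs(target.n_angles * target.step - 360.0) > 1e-9:
        raise InputError("target grid does not span a full 360° period")
    model = rb_eval(coeffs, target.angles)
    d = np.asarray(model) - target.means
    d -= d.mean()
    k = int(np.argmax(np.abs(d)))
    return {
        "passed": bool(np.abs(d[k]) <= tolerance),
        "max_deviation": float(np.abs(d[k])),
        "worst_angle": float(target.angles[k]),
    }


def syn_anti_gap(coeffs: RBCoefficients) -> float:
    """V(0°) − V(180°) = Σ C_n(−1)ⁿ − Σ C_n = −2(C₁ + C₃ + C₅): the
    syn/anti carboxyl-orientation energy gap the refit corrects."""
    return float(sum(c * ((-1.0) ** n - 1.0) for n, c in enumerate(coeffs.c)))


def rb_to_cosine_series(coeffs: RBCoefficients) -> np.ndarray:
    """Coefficients a_n of V(φ) = Σ a_n (cos φ)ⁿ (plain-cosine convention).

    cos ψ = cos(φ−180°) = −cos φ, so a_n = (−1)ⁿ C_n.
    """
    return np.array([((-1.0) ** n) * c for n, c in enumerate(coeffs.c)])


def cosine_series_to_rb(a, n_terms: int | None = None) -> RBCoefficients:
    a = np.asarray(a, dtype=float)
    if a.size > 6:
        raise InputError("at most six cosine-series coefficients")
    c = np.zeros(6)
    c[: a.size] = [((-1.0) ** n) * an for n, an in enumerate(a)]
    if n_terms is None:
        nz = np.flatnonzero(c)
        n_terms = int(nz[-1]) + 1 if nz.size else 1
    return RBCoefficients(c=tuple(c), n_terms=n_terms)
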