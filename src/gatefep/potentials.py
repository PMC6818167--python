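"""One-dimensional model free-energy surfaces with analytic ground truth.

These play the role of the unknown PMF along the gate CV: samplers draw
Boltzmann-biased configurations from them, and recovery tests compare
estimates against their exact shape. The calibrated double well mimics the
deprotonated, substrate-bound gate landscape — an inward-occluded basin
near 14.2 Å metastable against an inward-open basin near 17.5 Å, with a
configurable depth offset between the two minima.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .errors import ConfigurationError
from .units import kt

__all__ = [
    "ModelPotential1D",
    "flat",
    "harmonic",
    "double_well",
    "piecewise_polynomial",
]


@dataclass
class ModelPotential1D:
    """A scalar potential U(ξ) (kcal/mol) on a finite Å domain.

    ``minima`` (if set) are the exact locations of local minima;
    ``min_offset`` is the exact U difference between the second and first
    minimum (negative: second well deeper).
    """

    kind: str
    fn: callable
    domain: tuple
    params: dict = field(default_factory=dict)
    minima: tuple | None = None
    min_offset: float | None = None

    def __call__(self, x):
        u = self.fn(np.asarray(x, dtype=float))
        if not np.all(np.isfinite(u)):
            raise ConfigurationError(f"{self.kind} potential non-finite on evaluation points")
        return u

    def basin_free_energy_difference(self, temperature: float, split: float | None = None) -> float:
        """Exact Boltzmann basin free-energy difference (kcal/mol).

        ΔG = −RT ln(Z_B/Z_A) with each Z a quadrature of exp(−U/RT) over
        its basin; the basins are separated at ``split`` (defaults to the
        barrier top between the two minima). Distinct from ``min_offset``,
        which compares raw well depths.
        """
        rt = kt(temperature)
        if split is None:
            if self.minima is None or len(self.minima) < 2:
                raise ConfigurationError("need two minima or an explicit split point")
            xs = np.linspace(self.minima[0], self.minima[1], 2001)
            split = float(xs[np.argmax(self(xs))])
        lo, hi = self.domain
        u0 = float(np.min(self(np.linspace(lo, hi, 2001))))  # stabilize the exponentials
        za, _ = quad(lambda x: np.exp(-(self.fn(x) - u0) / rt), lo, split, limit=200)
        zb, _ = quad(lambda x: np.exp(-(self.fn(x) - u0) / rt), split, hi, limit=200)
        return float(-rt * np.log(zb / za))


def flat(domain=(13.0, 19.0)) -> ModelPotential1D:
    return ModelPotential1D("flat", lambda x: np.zeros_like(np.asarray(x, dtype=float)), tuple(domain))


def harmonic(center: float, curvature: float, domain=(13.0, 19.0)) -> ModelPotential1D:
    """U(ξ) = a·(ξ−ξ₀)², a in kcal/mol/Å²."""
    if curvature <= 0:
        raise ConfigurationError("harmonic curvature must be positive")
    return ModelPotential1D(
        "harmonic",
        lambda x: curvature * (np.asarray(x, dtype=float) - center) ** 2,
        tuple(domain),
        params={"center": center, "curvature": curvature},
        minima=(center,),
    )


def piecewise_polynomial(breakpoints, coeff_sets, domain) -> ModelPotential1D:
    """Piecewise polynomial in ξ; ``coeff_sets[i]`` (np.polyval order) applies
    on [breakpoints[i], breakpoints[i+1])."""
    bp = np.asarray(breakpoints, dtype=float)
    if len(coeff_sets) != len(bp) - 1:
        raise ConfigurationError("need one coefficient set per interval")

    def fn(x):
        x = np.asarray(x, dtype=float)
        idx = np.clip(np.searchsorted(bp, x, side="right") - 1, 0, len(coeff_sets) - 1)
        out = np.empty_like(x)
        for i, c in enumerate(coeff_sets):
            m = idx == i
            out[m] = np.polyval(c, x[m])
        return out

    return ModelPotential1D("piecewise_polynomial", fn, tuple(domain))


def _quartic_linear(h, m, w, tilt):
    def fn(x):
        z = (np.asarray(x, dtype=float) - m) / w
        return h * (z * z - 1.0) ** 2 + tilt * (np.asarray(x, dtype=float) - m)

    return fn


def _stationary_points(h, m, w, tilt):
    # U' = (4h/w)(z³ − z) + tilt, z = (x−m)/w  →  cubic in z
    roots = np.roots([4.0 * h / w, 0.0, -4.0 * h / w, tilt])
    real = np.sort(roots[np.abs(roots.imag) < 1e-10].real)
    return m + w * real


def double_well(
    offset: float = 2.2,
    barrier: float = 1.5,
    minima_guess=(14.2, 17.5),
    domain=(12.0, 20.0),
    max_outer_slope: float = 2.0,
) -> ModelPotential1D:
    """Quartic-plus-linear double well calibrated to an exact well-depth offset.

    The linear tilt is solved (Brent root find) so that
    U(right minimum) − U(left minimum) = −``offset`` exactly: the
    inward-open well (right) is deeper by ``offset`` kcal/mol. ``barrier``
    sets the quartic hump height (kcal/mol) before tilting; the default is
    gentle, matching the shallow, rather flat landscape between the
    occluded and open basins. Outside the wells the quartic walls are
    continued linearly (C¹) once their slope reaches ``max_outer_slope``
    (kcal/mol/Å), so that umbrella windows of ordinary stiffness can hold
    position on the flanks.
    """
    if offset < 0:
        raise ConfigurationError("offset must be ≥ 0 (right well deeper)")
    m = 0.5 * (minima_guess[0] + minima_guess[1])
    w = 0.5 * (minima_guess[1] - minima_guess[0])
    if barrier <= 0 or w <= 0:
        raise ConfigurationError("barrier and well separation must be positive")

    def depth_diff(tilt):
        sp = _stationary_points(barrier, m, w, tilt)
        if len(sp) < 3:  # tilt so strong the barrier vanished
            return np.inf
        fn = _quartic_linear(barrier, m, w, tilt)
        return fn(sp[2]) - fn(sp[0])

    if offset == 0:
        tilt = 0.0
    else:
        # bracket: tilt < 0 deepens the right well
        t_max = -1e-9
        t_min = -0.95 * 8.0 * barrier / (3.0 * np.sqrt(3.0) * w)  # near barrier loss
        tilt = brentq(lambda t: depth_diff(t) + offset, t_min, t_max, xtol=1e-14)
    sp = _stationary_points(barrier, m, w, tilt)
    core = _quartic_linear(barrier, m, w, tilt)

    def dcore(x):
        z = (np.asarray(x, dtype=float) - m) / w
        return (4.0 * barrier / w) * (z**3 - z) + tilt

    # junctions where the outer walls reach the slope cap (C¹ continuation)
    lo, hi = domain
    xl = brentq(lambda x: dcore(x) + max_outer_slope, lo - 20.0, sp[0], xtol=1e-12)
    xr = brentq(lambda x: dcore(x) - max_outer_slope, sp[2], hi + 20.0, xtol=1e-12)
    ul, ur = float(core(xl)), float(core(xr))

    def fn(x):
        x = np.asarray(x, dtype=float)
        out = core(x)
        out = np.where(x < xl, ul - max_outer_slope * (x - xl), out)
        out = np.where(x > xr, ur + max_outer_slope * (x - xr), out)
        return out

    return ModelPotential1D(
        "double_well",
        fn,
        tuple(domain),
        params={
            "barrier": barrier, "center": m, "half_sep": w, "tilt": tilt,
            "wall_junctions": (float(xl), float(xr)), "max_outer_slope": max_outer_slope,
        },
        minima=(float(sp[0]), float(sp[2])),
        min_offset=float(core(sp[2]) - core(sp[0])),
    )
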