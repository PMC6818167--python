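"""Absolute binding free-energy cycle with Boresch orientational restraints.

The ligand is annihilated once in water and once in the complex while held
by a six-degree-of-freedom restraint (one distance, two angles, three
dihedrals between three protein and three ligand anchor atoms). The
restraint's standard-state release free energy has the closed rigid-rotor
form and the cycle closes as

    ΔG_bind = ΔG_annihilate,water − (ΔG_restrain + ΔG_annihilate,complex)
              − ΔG_release.

More negative ΔG_bind means tighter binding.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, InputError
from .estimators import FreeEnergyResult, propagate_cycle_error
from .io import TimeSeries
from .units import STANDARD_VOLUME_A3, kt

__all__ = [
    "BoreschRestraint",
    "BindingFreeEnergyResult",
    "boresch_analytic_dG",
    "restraint_equilibrium_from_series",
    "assemble_abfe",
]

#: anchor atoms used in the transporter–alanine restraint
DEFAULT_PROTEIN_ANCHORS = ("T43:CA", "T43:C", "G44:N")
DEFAULT_LIGAND_ANCHORS = ("A:C", "A:CA", "A:N")


@dataclass
class BoreschRestraint:
    """Six-DOF orientational restraint: r(G44:N–A:C), two bend angles and
    three dihedrals across the protein/ligand anchor triplets.

    Equilibrium angles are in degrees; force constants in kcal/mol/Å²
    (distance) and kcal/mol/rad² (angles, dihedrals).
    """

    r0: float  # Å
    theta_a0: float  # deg
    theta_b0: float  # deg
    phi1_0: float = 0.0  # deg
    phi2_0: float = 0.0
    phi3_0: float = 0.0
    k_r: float = 10.0
    k_theta_a: float = 100.0
    k_theta_b: float = 100.0
    k_phi1: float = 100.0
    k_phi2: float = 100.0
    k_phi3: float = 100.0
    temperature: float = 310.0
    protein_anchors: tuple = DEFAULT_PROTEIN_ANCHORS
    ligand_anchors: tuple = DEFAULT_LIGAND_ANCHORS

    def __post_init__(self):
        if not (0.0 < self.theta_a0 < 180.0) or not (0.0 < self.theta_b0 < 180.0):
            raise InputError("equilibrium angles must lie strictly between 0° and 180°")
        if self.r0 <= 0:
            raise InputError("equilibrium distance must be positive")
        for name in ("k_r", "k_theta_a", "k_theta_b", "k_phi1", "k_phi2", "k_phi3"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive for the analytic formula")

    @property
    def force_constants(self):
        return (self.k_r, self.k_theta_a, self.k_theta_b, self.k_phi1, self.k_phi2, self.k_phi3)


@dataclass
class BindingFreeEnergyResult:
    dg_bind: float  # kcal/mol
    sigma: float
    breakdown: dict = field(default_factory=dict)  # leg name → (signed ΔG, σ)

    def __post_init__(self):
        total = sum(v[0] for v in self.breakdown.values())
        if abs(total - self.dg_bind) > 1e-12 * max(1.0, abs(self.dg_bind)):
            raise InputError("breakdown does not sum to ΔG_bind")


def boresch_analytic_dG(
    restraint: BoreschRestraint,
    standard_volume: float = STANDARD_VOLUME_A3,
) -> FreeEnergyResult:
    """Rigid-rotor release free energy of the six-DOF restraint:

        ΔG_release = RT ln[ 8π² V° √(K_r K_θA K_θB K_φ1 K_φ2 K_φ3)
                            / (r₀² sinθ_A0 sinθ_B0 (2πRT)³) ]

    This is the free energy of releasing the restrained, non-interacting
    ligand to 1 M standard concentration (V° = 1660 Å³); it enters the
    binding cycle with a +1 sign. Dihedral equilibrium values do not enter.
    """
    rt = kt(restraint.temperature)
    tha = np.deg2rad(restraint.theta_a0)
    thb = np.deg2rad(restraint.theta_b0)
    if np.sin(tha) <= 0 or np.sin(thb) <= 0:
        raise InputError("sin θ₀ must be positive")
    ks = restraint.force_constants
    # stiff-restraint sanity: fluctuations small vs geometric scales
    if np.sqrt(rt / ks[0]) > 0.25 * restraint.r0 or any(
        np.sqrt(rt / k) > 0.5 for k in ks[1:]
    ):
        warnings.warn("restraint is soft; the rigid-rotor formula may be inaccurate")
    arg = (
        8.0
        * np.pi**2
        * standard_volume
        * np.sqrt(np.prod(ks))
        / (restraint.r0**2 * np.sin(tha) * np.sin(thb) * (2.0 * np.pi * rt) ** 3)
    )
    return FreeEnergyResult(
        dg=float(rt * np.log(arg)),
        sigma=0.0,
        method="boresch-analytic",
        leg="release",
        temperature=restraint.temperature,
    )


def _circular_mean_deg(values: np.ndarray) -> float:
    rad = np.deg2rad(values)
    s, c = np.mean(np.sin(rad)), np.mean(np.cos(rad))
    if np.hypot(s, c) < 1e-6:
        raise AnalysisError("circular mean undefined: resultant length ~ 0")
    mean = np.rad2deg(np.arctan2(s, c))
    if mean <= -180.0:  # map to (−180°, 180°]
        mean += 360.0
    return float(mean)


def restraint_equilibrium_from_series(traces: dict) -> dict:
    """Equilibrium restraint values from unbiased traces.

    ``traces`` maps DOF name → :class:`TimeSeries`; the name decides the
    averaging rule: ``r``/``distance`` → arithmetic mean, anything else
    (angles, dihedrals, degrees) → circular mean mapped to (−180°, 180°].
    """
    out = {}
    for name, trace in traces.items():
        if not isinstance(trace, TimeSeries):
            raise InputError(f"trace {name!r} must be a TimeSeries")
        vals = trace.values()
        if name.lower() in ("r", "r0", "distance") or name.lower().startswith("dist"):
            out[name] = float(np.mean(vals))
        else:
            out[name] = _circular_mean_deg(vals)
    return out


def assemble_abfe(
    water_leg: FreeEnergyResult,
    complex_legs,
    release: FreeEnergyResult,
) -> BindingFreeEnergyResult:
    """Close the binding cycle from forward-leg free energies.

    All inputs are forward (λ 0→1) ΔG values — restrain-and-annihilate in
    the complex, annihilate in water, analytic release — and the sign
    bookkeeping lives entirely here.
    """
    complex_legs = list(complex_legs)
    legs = [water_leg, *complex_legs, release]
    units = {leg.units for leg in legs}
    if len(units) > 1:
        raise InputError(f"mixed units across legs: {units}")
    temps = {round(leg.temperature, 9) for leg in legs}
    if len(temps) > 1:
        raise InputError(f"legs computed at different temperatures: {temps}")
    signs = [1.0] + [-1.0] * len(complex_legs) + [-1.0]
    total = propagate_cycle_error(legs, signs)
    breakdown = {"water": (water_leg.dg, water_leg.sigma)}
    for i, leg in enumerate(complex_legs):
        breakdown[leg.leg or f"complex_{i}"] = (-leg.dg, leg.sigma)
    breakdown["release"] = (-release.dg, release.sigma)
    return BindingFreeEnergyResult(dg_bind=total.dg, sigma=total.sigma, breakdown=breakdown)
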