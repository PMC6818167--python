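"""Intracellular-gate collective variable and umbrella window machinery.

The gate CV is the distance between the unweighted geometric centers of the
Cα atoms of two residue stretches — by default 113–117 on TM3 (around E115)
and 235–239 on TM6 (around D237). Its increase tracks the opening of the
intracellular gate of the transporter.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, SelectionError
from .io import StructureModel, TimeSeries

__all__ = [
    "GateCVDefinition",
    "WindowGrid",
    "compute_gate_cv",
    "build_window_grid",
    "assign_initial_frames",
]


@dataclass(frozen=True)
class GateCVDefinition:
    """Two inclusive residue ranges whose Cα geometric centers define the CV."""

    group_a: tuple = (113, 117)
    group_b: tuple = (235, 239)

    def __post_init__(self):
        a = set(range(self.group_a[0], self.group_a[1] + 1))
        b = set(range(self.group_b[0], self.group_b[1] + 1))
        if not a or not b:
            raise ConfigurationError("CV residue ranges must be non-empty")
        if a & b:
            raise ConfigurationError("CV residue ranges must be disjoint")

    @property
    def residues_a(self):
        return list(range(self.group_a[0], self.group_a[1] + 1))

    @property
    def residues_b(self):
        return list(range(self.group_b[0], self.group_b[1] + 1))


@dataclass(frozen=True)
class WindowGrid:
    """Uniformly spaced umbrella window centers with a shared bias constant.

    ``kappa`` is kept in the unit it is supplied in (kJ/mol/nm², matching
    MD-engine conventions); estimators convert internally.
    """

    centers: tuple  # Å, strictly increasing, uniform
    spacing: float  # Å
    kappa: float  # kJ/mol/nm²

    @property
    def n_windows(self) -> int:
        return len(self.centers)


def _group_center(structure: StructureModel, resids) -> np.ndarray:
    pos = structure.ca_positions(resids)
    missing = [r for r in resids if r not in pos]
    if missing:
        raise SelectionError(f"missing Cα for residues {missing}")
    return np.mean([pos[r] for r in resids], axis=0)


def compute_gate_cv(structure: StructureModel, cvdef: GateCVDefinition | None = None) -> float:
    """Distance (Å) between the Cα geometric centers of the two gate groups."""
    cvdef = cvdef or GateCVDefinition()
    ca = _group_center(structure, cvdef.residues_a)
    cb = _group_center(structure, cvdef.residues_b)
    return float(np.linalg.norm(ca - cb))


def build_window_grid(lo: float, hi: float, spacing: float, kappa: float = 1000.0) -> WindowGrid:
    """Uniform window centers over [lo, hi] inclusive of both endpoints.

    Raises :class:`ConfigurationError` if ``spacing`` does not divide the
    range (no silent truncation).
    """
    if hi <= lo:
        raise ConfigurationError("grid max must exceed min")
    if spacing <= 0:
        raise ConfigurationError("spacing must be positive")
    n_intervals = (hi - lo) / spacing
    if abs(n_intervals - round(n_intervals)) > 1e-9:
        raise ConfigurationError(
            f"spacing {spacing} does not divide range [{lo}, {hi}]"
        )
    n = int(round(n_intervals)) + 1
    centers = tuple(lo + i * spacing for i in range(n))
    return WindowGrid(centers=centers, spacing=float(spacing), kappa=float(kappa))


def assign_initial_frames(cv_trace: TimeSeries, grid: WindowGrid, column: str | None = None) -> dict[int, int]:
    """For each window, the index of the trace frame whose CV value is
    closest to the window center; ties go to the earliest frame."""
    vals = cv_trace.values(column)
    centers = np.asarray(grid.centers)
    # argmin returns the first minimizer, which is the earliest-frame tie-break
    return {
        j: int(np.argmin(np.abs(vals - c))) for j, c in enumerate(centers)
    }
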