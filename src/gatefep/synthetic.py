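"""Synthetic test inputs with known ground truth.

Every generator here emulates the *shape* of the data the pipeline
consumes — biased CV samples, per-λ reduced potentials, noisy dihedral
scans, box-size series of charging free energies — while planting an
exactly known answer alongside, so estimator recovery can be tested
without any molecular dynamics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cv import WindowGrid
from .dihedral import DihedralScan, RBCoefficients, rb_eval
from .errors import ConfigurationError
from .estimators import ReducedPotentialMatrix
from .potentials import ModelPotential1D
from .protonation import (
    DEFAULT_EPS_S,
    DEFAULT_GAMMA_S,
    DEFAULT_N_SOLVENT,
    DEFAULT_RADIUS,
    ChargingLeg,
    finite_size_correction,
)
from .units import kj_nm2_to_kcal_A2, kt
from .wham import UmbrellaDataset, UmbrellaWindow

__all__ = [
    "HarmonicAlchemicalSpec",
    "sample_biased",
    "generate_umbrella_dataset",
    "generate_alchemical_ensemble",
    "generate_dihedral_scan",
    "generate_finite_size_series",
]


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_biased(
    potential: ModelPotential1D,
    bias_center: float,
    kappa: float,
    temperature: float,
    n: int,
    seed,
    n_chains: int = 32,
    burn_in: int | None = None,
    step: float = 0.5,
) -> np.ndarray:
    """Metropolis Monte Carlo samples from exp(−[U(ξ) + ½K(ξ−c)²]/RT).

    ``kappa`` is in kcal/mol/Å². Runs ``n_chains`` independent walkers;
    the proposal width is tuned during burn-in toward 30–50% acceptance.
    Burn-in defaults to 10% of n (at least 1000 steps per chain).
    Bit-reproducible for a fixed seed.
    """
    if n < 1:
        raise ConfigurationError("n must be ≥ 1")
    if kappa < 0:
        raise ConfigurationError("bias force constant must be ≥ 0")
    rt = kt(temperature)
    lo, hi = potential.domain
    rng = _rng(seed)

    def energy(x):
        return potential(x) + 0.5 * kappa * (x - bias_center) ** 2

    # start all chains near the minimum of the biased potential
    grid = np.linspace(lo, hi, 512)
    x0 = grid[int(np.argmin(energy(grid)))]
    x = np.clip(x0 + 0.05 * rng.standard_normal(n_chains), lo, hi)
    e = energy(x)

    n_steps = int(np.ceil(n / n_chains))
    if burn_in is None:
        burn_in = max(1000, int(np.ceil(0.1 * n / n_chains)))

    accepted = 0
    proposed = 0
    for t in range(burn_in + n_steps):
        prop = x + step * rng.standard_normal(n_chains)
        inside = (prop >= lo) & (prop <= hi)
        e_prop = np.where(inside, energy(np.clip(prop, lo, hi)), np.inf)
        logu = np.log(rng.random(n_chains))
        acc = inside & (logu < -(e_prop - e) / rt)
        x = np.where(acc, prop, x)
        e = np.where(acc, e_prop, e)
        if t < burn_in:
            accepted += int(acc.sum())
            proposed += n_chains
            if proposed >= 50 * n_chains:
                rate = accepted / proposed
                if rate > 0.5:
                    step = min(step * 1.25, hi - lo)
                elif rate < 0.3:
                    step = max(step * 0.8, 1e-4)
                accepted = proposed = 0
        else:
            if t == burn_in:
                out = np.empty((n_steps, n_chains))
            out[t - burn_in] = x
    return out.ravel()[:n]


def generate_umbrella_dataset(
    potential: ModelPotential1D,
    grid: WindowGrid,
    temperature: float,
    n_per_window: int,
    seed: int,
    **sampler_kwargs,
) -> UmbrellaDataset:
    """One biased sample set per window of ``grid``; window order preserved.

    ``grid.kappa`` (kJ/mol/nm²) is converted to kcal/mol/Å² for the
    sampler and stored converted on each window. The generating potential
    rides along as ``dataset.truth``.
    """
    kappa = kj_nm2_to_kcal_A2(grid.kappa)
    children = np.random.SeedSequence(seed).spawn(grid.n_windows)
    windows = [
        UmbrellaWindow(
            center=c,
            kappa=kappa,
            samples=sample_biased(
                potential, c, kappa, temperature, n_per_window,
                np.random.default_rng(child), **sampler_kwargs,
            ),
        )
        for c, child in zip(grid.centers, children)
    ]
    return UmbrellaDataset(
        windows=windows,
        temperature=temperature,
        truth=potential,
        meta={"seed": seed, "kappa_kj_nm2": grid.kappa, "n_per_window": n_per_window},
    )


@dataclass
class HarmonicAlchemicalSpec:
    """Multi-state harmonic ensemble with closed-form free energies.

    State i is a 1D harmonic well with spring constant ``k[i]``
    (kcal/mol/Å²) and center ``c[i]`` (Å). The exact reduced free energy
    of state i relative to state 0 is ½·ln(k_i/k_0) — centers do not
    affect ΔG.
    """

    k: tuple  # kcal/mol/Å² per state
    c: tuple  # Å per state
    n_samples: tuple  # N_k per state (0 allowed: perturbation state)
    temperature: float = 310.0

    def __post_init__(self):
        if len(self.k) != len(self.c) or len(self.k) != len(self.n_samples):
            raise ConfigurationError("k, c, n_samples must have equal lengths")
        if len(self.k) < 2:
            raise ConfigurationError("need at least two λ states")
        if any(ki <= 0 for ki in self.k):
            raise ConfigurationError("spring constants must be positive")
        if any(n < 0 for n in self.n_samples):
            raise ConfigurationError("sample counts must be ≥ 0")

    def exact_reduced_f(self) -> np.ndarray:
        k = np.asarray(self.k, dtype=float)
        return 0.5 * np.log(k / k[0])

    def exact_dg(self, i: int, j: int) -> float:
        """Closed-form ΔG(i→j) in kcal/mol: (RT/2)·ln(k_j/k_i)."""
        return float(kt(self.temperature) * 0.5 * np.log(self.k[j] / self.k[i]))


def generate_alchemical_ensemble(spec: HarmonicAlchemicalSpec, seed) -> ReducedPotentialMatrix:
    """Exact Gaussian draws from each sampled state, with u_kn filled by
    evaluating every sample in every state. Ground truth is attached as
    ``matrix.exact_f``."""
    rng = _rng(seed)
    rt = kt(spec.temperature)
    xs = []
    for ki, ci, ni in zip(spec.k, spec.c, spec.n_samples):
        if ni > 0:
            xs.append(ci + np.sqrt(rt / ki) * rng.standard_normal(ni))
    x = np.concatenate(xs) if xs else np.empty(0)
    k = np.asarray(spec.k, dtype=float)[:, None]
    c = np.asarray(spec.c, dtype=float)[:, None]
    u_kn = 0.5 * k * (x[None, :] - c) ** 2 / rt
    return ReducedPotentialMatrix(
        u_kn=u_kn,
        n_k=np.asarray(spec.n_samples, dtype=int),
        temperature=spec.temperature,
        exact_f=spec.exact_reduced_f(),
    )


def generate_dihedral_scan(
    coeffs: RBCoefficients,
    step: float = 5.0,
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed=0,
) -> DihedralScan:
    """Noisy scan of an RB potential on the half-open grid [0°, 360°).

    A 5° step gives the standard 72-point scan. Per-angle replicate
    energies are RB(φ) + Gaussian noise; the scan stores means and SEs.
    """
    if step <= 0 or abs(360.0 / step - round(360.0 / step)) > 1e-9:
        raise ConfigurationError(f"step {step}° must divide 360°")
    if replicates < 1:
        raise ConfigurationError("need at least one replicate")
    rng = _rng(seed)
    angles = np.arange(0.0, 360.0, step)
    truth = np.asarray(rb_eval(coeffs, angles))
    reps = truth[:, None] + noise_sd * rng.standard_normal((angles.size, replicates))
    means = reps.mean(axis=1)
    ses = (
        reps.std(axis=1, ddof=1) / np.sqrt(replicates)
        if replicates > 1
        else np.zeros(angles.size)
    )
    return DihedralScan(angles=angles, means=means, ses=ses, replicates=list(reps))


def generate_finite_size_series(
    dg_inf: float,
    q: float,
    box_edges=tuple(range(30, 101, 10)),
    eps_s: float = DEFAULT_EPS_S,
    gamma_s: float = DEFAULT_GAMMA_S,
    radius: float = DEFAULT_RADIUS,
    n_solvent: int = DEFAULT_N_SOLVENT,
    replicates: int = 1,
    noise_sd: float = 0.0,
    seed=0,
) -> list[ChargingLeg]:
    """Box-size series of *uncorrected* charging free energies with the
    planted finite-size artifact:

        ΔG_raw(L) = ΔG_∞ − ΔG_cor(q, L, ...) + noise

    using exactly the correction model of
    :func:`gatefep.protonation.finite_size_correction`, so applying the
    correction recovers ΔG_∞ at every L (to 1e-9 noiseless).
    """
    rng = _rng(seed)
    legs = []
    for L in box_edges:
        for _ in range(replicates):
            template = ChargingLeg(
                dg=0.0, box_edge=float(L), charge=q,
                eps_s=eps_s, gamma_s=gamma_s, radius=radius, n_solvent=n_solvent,
            )
            raw = dg_inf - finite_size_correction(template) + noise_sd * rng.standard_normal()
            legs.append(
                ChargingLeg(
                    dg=float(raw), sigma=noise_sd, box_edge=float(L), charge=q,
                    eps_s=eps_s, gamma_s=gamma_s, radius=radius, n_solvent=n_solvent,
                )
            )
    return legs
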