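import numpy as np
import pytest

import gatefep as g


def make_pdb(path, residues, missing_ca=()):
    """Write a minimal PDB with one Cα per (resid, xyz) entry."""
    with open(path, "w") as fh:
        serial = 1
        for resid, (x, y, z) in residues.items():
            if resid in missing_ca:
                name, pad = "CB", " CB "
            else:
                pad = " CA "
            fh.write(
                f"ATOM  {serial:>5} {pad}ALA A{resid:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
            )
            serial += 1
        fh.write("END\n")
    return path


def make_gro(path, residues):
    """Same coordinates as make_pdb but in GRO format (nm)."""
    with open(path, "w") as fh:
        fh.write("synthetic fixture\n")
        fh.write(f"{len(residues)}\n")
        for serial, (resid, (x, y, z)) in enumerate(residues.items(), start=1):
            fh.write(f"{resid:>5}{'ALA':<5}{'CA':>5}{serial:>5}{x / 10:8.3f}{y / 10:8.3f}{z / 10:8.3f}\n")
        fh.write("  10.00000  10.00000  10.00000\n")
    return path


@pytest.fixture
def gate_residues():
    """Group A Cα's centered at the origin, group B at (0, 0, 15 Å)."""
    res = {}
    for i, rid in enumerate(range(113, 118)):
        res[rid] = (0.0, float(i) - 2.0, 0.0)
    for i, rid in enumerate(range(235, 240)):
        res[rid] = (0.0, float(i) - 2.0, 15.0)
    return res


@pytest.fixture(scope="session")
def harmonic_umbrella():
    """Moderate-size umbrella dataset on a known harmonic surface."""
    pot = g.harmonic(center=16.0, curvature=0.5, domain=(13.0, 19.0))
    grid = g.build_window_grid(13.0, 19.0, 0.5, kappa=1000.0)
    ds = g.generate_umbrella_dataset(pot, grid, 310.0, 5000, seed=11)
    return ds, pot


@pytest.fixture(scope="session")
def harmonic_pair_ensemble():
    """Two-state harmonic alchemical ensemble (k vs 2k) with exact ΔG."""
    spec = g.HarmonicAlchemicalSpec(k=(1.0, 2.0), c=(0.0, 0.2), n_samples=(50_000, 50_000))
    return g.generate_alchemical_ensemble(spec, seed=21), spec
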