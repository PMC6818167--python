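import numpy as np
import pytest
from scipy.integrate import quad

import gatefep as g
from gatefep.errors import AnalysisError, InputError
from gatefep.units import STANDARD_VOLUME_A3, kt

RT = kt(310.0)


def stiff_restraint(scale=1.0):
    return g.BoreschRestraint(
        r0=5.0, theta_a0=80.0, theta_b0=100.0,
        phi1_0=30.0, phi2_0=-60.0, phi3_0=170.0,
        k_r=10.0 * scale, k_theta_a=100.0 * scale, k_theta_b=100.0 * scale,
        k_phi1=100.0 * scale, k_phi2=100.0 * scale, k_phi3=100.0 * scale,
    )


def quadrature_release_dg(r: g.BoreschRestraint) -> float:
    """Brute-force configurational integral of the restrained ligand
    (separable 6D quadrature) vs the 8π²V° free-ligand volume."""
    zr = quad(lambda x: x * x * np.exp(-r.k_r * (x - r.r0) ** 2 / (2 * RT)), 0.0, r.r0 + 12.0, limit=300)[0]
    za = quad(lambda t: np.sin(t) * np.exp(-r.k_theta_a * (t - np.deg2rad(r.theta_a0)) ** 2 / (2 * RT)), 0.0, np.pi, limit=300)[0]
    zb = quad(lambda t: np.sin(t) * np.exp(-r.k_theta_b * (t - np.deg2rad(r.theta_b0)) ** 2 / (2 * RT)), 0.0, np.pi, limit=300)[0]
    zphi = 1.0
    for k in (r.k_phi1, r.k_phi2, r.k_phi3):
        zphi *= quad(lambda p: np.exp(-k * p * p / (2 * RT)), -np.pi, np.pi, limit=300)[0]
    return RT * np.log(8 * np.pi**2 * STANDARD_VOLUME_A3 / (zr * za * zb * zphi))


class TestBoreschAnalytic:
    def test_matches_brute_force_quadrature_in_stiff_regime(self):
        r = stiff_restraint()
        assert g.boresch_analytic_dG(r).dg == pytest.approx(quadrature_release_dg(r), abs=0.05)

    def test_doubling_all_force_constants_shifts_by_3RTln2(self):
        base = g.boresch_analytic_dG(stiff_restraint()).dg
        doubled = g.boresch_analytic_dG(stiff_restraint(scale=2.0)).dg
        assert doubled - base == pytest.approx(3 * RT * np.log(2), abs=1e-12)

    def test_doubling_standard_volume_shifts_by_RTln2(self):
        r = stiff_restraint()
        a = g.boresch_analytic_dG(r).dg
        b = g.boresch_analytic_dG(r, standard_volume=2 * STANDARD_VOLUME_A3).dg
        assert b - a == pytest.approx(RT * np.log(2), abs=1e-12)

    def test_independent_of_dihedral_equilibrium_values(self):
        a = stiff_restraint()
        b = g.BoreschRestraint(
            r0=a.r0, theta_a0=a.theta_a0, theta_b0=a.theta_b0,
            phi1_0=111.0, phi2_0=22.0, phi3_0=-99.0,
            k_r=a.k_r, k_theta_a=a.k_theta_a, k_theta_b=a.k_theta_b,
            k_phi1=a.k_phi1, k_phi2=a.k_phi2, k_phi3=a.k_phi3,
        )
        assert g.boresch_analytic_dG(a).dg == g.boresch_analytic_dG(b).dg

    def test_soft_restraint_warns(self):
        soft = g.BoreschRestraint(r0=2.0, theta_a0=90.0, theta_b0=90.0, k_r=0.5)
        with pytest.warns(UserWarning, match="soft"):
            g.boresch_analytic_dG(soft)

    @pytest.mark.parametrize("kwargs", [dict(theta_a0=0.0), dict(theta_b0=180.0), dict(k_r=-1.0)])
    def test_domain_errors(self, kwargs):
        base = dict(r0=5.0, theta_a0=80.0, theta_b0=100.0)
        base.update(kwargs)
        with pytest.raises(InputError):
            g.BoreschRestraint(**base)


class TestRestraintEquilibrium:
    def _ts(self, values):
        return g.TimeSeries(time=np.arange(len(values), dtype=float), columns={"v": np.asarray(values, dtype=float)})

    def test_constant_traces_return_the_constants(self):
        traces = {"r": self._ts([5.2] * 10), "theta_a": self._ts([85.0] * 10), "phi1": self._ts([-120.0] * 10)}
        eq = g.restraint_equilibrium_from_series(traces)
        assert eq == {"r": pytest.approx(5.2), "theta_a": pytest.approx(85.0), "phi1": pytest.approx(-120.0)}

    def test_wraparound_dihedral_averages_to_180(self):
        eq = g.restraint_equilibrium_from_series({"phi1": self._ts([179.0, -179.0])})
        assert eq["phi1"] == pytest.approx(180.0, abs=1e-9)

    def test_circular_mean_matches_grid_likelihood_maximizer(self):
        rng = np.random.default_rng(41)
        true_mu = 150.0
        samples = np.rad2deg(rng.vonmises(np.deg2rad(true_mu), kappa=8.0, size=5000))
        eq = g.restraint_equilibrium_from_series({"phi2": self._ts(samples)})
        # brute-force: μ maximizing Σ cos(θ−μ) on a fine grid
        grid = np.arange(-180.0, 180.0, 0.01)
        ll = np.array([np.sum(np.cos(np.deg2rad(samples - mu))) for mu in grid[::10]])
        coarse = grid[::10][np.argmax(ll)]
        fine = grid[np.abs(grid - coarse) <= 0.2]
        llf = np.array([np.sum(np.cos(np.deg2rad(samples - mu))) for mu in fine])
        brute = fine[np.argmax(llf)]
        assert abs(eq["phi2"] - brute) < 0.5

    def test_degenerate_circular_mean_is_analysis_error(self):
        with pytest.raises(AnalysisError):
            g.restraint_equilibrium_from_series({"phi1": self._ts([0.0, 180.0])})


class TestAssembleAbfe:
    def test_null_cycle(self):
        zero = g.FreeEnergyResult(0.0, 0.0)
        res = g.assemble_abfe(zero, [zero, zero], zero)
        assert res.dg_bind == 0.0

    def test_recovers_planted_binding_free_energy(self):
        """Every leg built from a harmonic ensemble whose ΔG is closed-form."""
        legs = {}
        for name, (k0, k1), seed in [
            ("water", (1.0, 2.2), 51),
            ("complex", (1.0, 3.1), 52),
        ]:
            spec = g.HarmonicAlchemicalSpec(k=(k0, k1), c=(0.0, 0.0), n_samples=(20_000, 20_000))
            m = g.generate_alchemical_ensemble(spec, seed=seed)
            legs[name] = (g.mbar_free_energies(m).result(0, 1, leg=name), spec.exact_dg(0, 1))
        release = g.boresch_analytic_dG(stiff_restraint())
        res = g.assemble_abfe(legs["water"][0], [legs["complex"][0]], release)
        planted = legs["water"][1] - legs["complex"][1] - release.dg
        assert abs(res.dg_bind - planted) < 3 * res.sigma

    def test_complex_sub_leg_order_irrelevant(self):
        w = g.FreeEnergyResult(-10.0, 0.1)
        c1 = g.FreeEnergyResult(3.0, 0.2, leg="restrain")
        c2 = g.FreeEnergyResult(5.0, 0.3, leg="annihilate")
        rel = g.FreeEnergyResult(1.0, 0.0, leg="release")
        a = g.assemble_abfe(w, [c1, c2], rel)
        b = g.assemble_abfe(w, [c2, c1], rel)
        assert a.dg_bind == b.dg_bind and a.sigma == b.sigma

    def test_breakdown_sums_to_total_exactly(self):
        w = g.FreeEnergyResult(-47.73, 0.01, leg="water")
        c = g.FreeEnergyResult(-41.0, 0.04, leg="complex")
        rel = g.FreeEnergyResult(0.84, 0.0, leg="release")
        res = g.assemble_abfe(w, [c], rel)
        assert sum(v[0] for v in res.breakdown.values()) == pytest.approx(res.dg_bind, abs=1e-12)

    def test_opposite_sign_assembly_cancels(self):
        leg = g.FreeEnergyResult(2.5, 0.3, leg="x")
        res = g.propagate_cycle_error([leg, leg], signs=[1.0, -1.0])
        assert res.dg == 0.0
        assert res.sigma == pytest.approx(np.sqrt(2) * 0.3)

    def test_temperature_mismatch_rejected(self):
        a = g.FreeEnergyResult(1.0, 0.1, temperature=310.0)
        b = g.FreeEnergyResult(1.0, 0.1, temperature=298.0)
        with pytest.raises(InputError):
            g.assemble_abfe(a, [b], g.FreeEnergyResult(0.0, 0.0))
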