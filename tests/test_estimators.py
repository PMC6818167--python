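import numpy as np
import pytest

import gatefep as g
from gatefep.errors import ConfigurationError, InputError
from gatefep.estimators import uniform_lambdas
from gatefep.units import kt

RT = kt(310.0)


class TestLambdaSchedules:
    def test_abfe_complex_has_36_windows(self):
        s = g.build_lambda_schedule("abfe_complex")
        assert s.n_windows == 36
        assert len(s.leg_lambdas("restrain")) == 10
        assert len(s.leg_lambdas("discharge")) == 11
        assert len(s.leg_lambdas("decouple")) == 15

    def test_printed_lambda_values_exact(self):
        s = g.build_lambda_schedule("abfe_complex")
        assert s.leg_lambdas("restrain") == (0.01, 0.025, 0.05, 0.075, 0.1, 0.2, 0.35, 0.5, 0.75, 1.0)
        assert s.leg_lambdas("decouple") == (
            0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9, 0.95, 1.0
        )
        assert s.leg_lambdas("discharge") == tuple(round(0.1 * i, 10) for i in range(11))

    def test_protonation_has_16_windows(self):
        s = g.build_lambda_schedule("protonation")
        assert s.n_windows == 16
        assert s.leg_lambdas("bonded_vdw") == (0.0, 0.25, 0.5, 0.75, 1.0)

    def test_water_protocol_drops_restraint_leg(self):
        s = g.build_lambda_schedule("abfe_water")
        assert s.n_windows == 26
        with pytest.raises(KeyError):
            s.leg_lambdas("restrain")

    def test_unknown_protocol_rejected(self):
        with pytest.raises(ConfigurationError):
            g.build_lambda_schedule("nonsense")

    def test_custom_uniform_charge_leg(self):
        assert uniform_lambdas(0.5) == (0.0, 0.5, 1.0)
        with pytest.raises(ConfigurationError):
            uniform_lambdas(0.3)


class TestMbar:
    def test_identical_states_give_zero(self):
        spec = g.HarmonicAlchemicalSpec(k=(1.0, 1.0), c=(0.3, 0.3), n_samples=(2000, 2000))
        res = g.mbar_free_energies(g.generate_alchemical_ensemble(spec, seed=31))
        assert res.delta_g[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert res.d_delta_g[0, 1] < 1e-6

    def test_harmonic_pair_matches_closed_form(self, harmonic_pair_ensemble):
        matrix, spec = harmonic_pair_ensemble
        res = g.mbar_free_energies(matrix)
        exact = spec.exact_dg(0, 1)
        assert abs(res.delta_g[0, 1] - exact) < 3 * res.d_delta_g[0, 1]
        assert res.d_delta_g[0, 1] < 0.01  # tight at n = 5e4/state

    def test_reduced_potential_shift_invariance(self, harmonic_pair_ensemble):
        matrix, _ = harmonic_pair_ensemble
        a = g.mbar_free_energies(matrix)
        shifted = g.ReducedPotentialMatrix(matrix.u_kn + 500.0, matrix.n_k, matrix.temperature)
        b = g.mbar_free_energies(shifted)
        assert np.allclose(a.delta_g, b.delta_g, atol=1e-10)

    def test_cycle_closure_over_three_states(self):
        spec = g.HarmonicAlchemicalSpec(
            k=(1.0, 1.7, 2.9), c=(0.0, 0.1, 0.3), n_samples=(5000, 5000, 5000)
        )
        res = g.mbar_free_energies(g.generate_alchemical_ensemble(spec, seed=32))
        closure = res.delta_g[0, 1] + res.delta_g[1, 2] + res.delta_g[2, 0]
        assert abs(closure) < 1e-9

    def test_reduces_to_zwanzig_with_single_sampled_state(self):
        spec = g.HarmonicAlchemicalSpec(k=(1.0, 1.6), c=(0.0, 0.2), n_samples=(5000, 0))
        m = g.generate_alchemical_ensemble(spec, seed=33)
        res = g.mbar_free_energies(m)
        assert res.f_k[1] == pytest.approx(g.zwanzig(m, 0, 1), abs=1e-8)

    def test_sample_reordering_invariance(self, harmonic_pair_ensemble):
        matrix, _ = harmonic_pair_ensemble
        a = g.mbar_free_energies(matrix)
        rng = np.random.default_rng(34)
        n0 = int(matrix.n_k[0])
        perm = np.concatenate([rng.permutation(n0), n0 + rng.permutation(int(matrix.n_k[1]))])
        shuffled = g.ReducedPotentialMatrix(matrix.u_kn[:, perm], matrix.n_k, matrix.temperature)
        b = g.mbar_free_energies(shuffled)
        assert np.allclose(a.delta_g, b.delta_g, atol=1e-10)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(InputError):
            g.ReducedPotentialMatrix(np.zeros((2, 10)), np.array([4, 4]))


class TestTi:
    def test_constant_integrand(self):
        res = g.ti_integrate([0.0, 0.5, 1.0], [3.0, 3.0, 3.0])
        assert res.dg == pytest.approx(3.0)

    def test_linear_integrand_exact(self):
        res = g.ti_integrate([0.0, 0.5, 1.0], [0.0, 0.5, 1.0])
        assert res.dg == pytest.approx(0.5, abs=1e-15)

    def test_harmonic_path_against_analytic(self):
        # k(λ) = k0(1+3λ): ⟨dH/dλ⟩ = (RT/2)·3/(1+3λ); ∫ = (RT/2)·ln4
        lam = np.linspace(0, 1, 11)
        means = (RT / 2) * 3.0 / (1.0 + 3.0 * lam)
        res = g.ti_integrate(lam, means)
        assert res.dg == pytest.approx(RT / 2 * np.log(4.0), rel=0.01)

    def test_uncertainty_uses_trapezoid_weights(self):
        res = g.ti_integrate([0.0, 0.5, 1.0], [1.0, 1.0, 1.0], [0.4, 0.4, 0.4])
        expected = 0.4 * np.sqrt(0.25**2 + 0.5**2 + 0.25**2)
        assert res.sigma == pytest.approx(expected)

    def test_duplicate_lambda_rejected(self):
        with pytest.raises(InputError):
            g.ti_integrate([0.0, 0.5, 0.5, 1.0], [1, 2, 3, 4])

    def test_mbar_and_ti_agree_on_dense_harmonic_path(self):
        lam = np.linspace(0.0, 1.0, 21)
        ks = 1.0 * (1.0 + 3.0 * lam)
        spec = g.HarmonicAlchemicalSpec(
            k=tuple(ks), c=(0.0,) * 21, n_samples=(2000,) * 21
        )
        mbar = g.mbar_free_energies(g.generate_alchemical_ensemble(spec, seed=35))
        means = (RT / 2) * 3.0 / (1.0 + 3.0 * lam)
        ti = g.ti_integrate(lam, means)
        exact = RT / 2 * np.log(4.0)
        assert abs(mbar.delta_g[0, -1] - exact) < 3 * mbar.d_delta_g[0, -1]
        assert abs(ti.dg - exact) < 0.01  # quadrature bias on the dense grid
        assert abs(mbar.delta_g[0, -1] - ti.dg) < 3 * mbar.d_delta_g[0, -1] + 0.01


class TestCyclePropagation:
    def test_three_four_five_quadrature(self):
        a = g.FreeEnergyResult(1.0, 0.3, leg="a")
        b = g.FreeEnergyResult(-1.0, 0.4, leg="b")
        res = g.propagate_cycle_error([a, b], signs=[1, 1])
        assert res.dg == pytest.approx(0.0)
        assert res.sigma == pytest.approx(0.5)

    def test_single_leg_unchanged(self):
        a = g.FreeEnergyResult(-5.89, 0.04, leg="complex")
        res = g.propagate_cycle_error([a])
        assert (res.dg, res.sigma) == (a.dg, a.sigma)

    def test_quadrature_matches_monte_carlo_propagation(self):
        # assembly shaped like a binding-cycle sum of independent legs
        legs = [
            g.FreeEnergyResult(-47.73, 0.01, leg="water"),
            g.FreeEnergyResult(41.0, 0.04, leg="complex"),
            g.FreeEnergyResult(0.84, 0.02, leg="release"),
        ]
        signs = [1.0, -1.0, -1.0]
        res = g.propagate_cycle_error(legs, signs)
        rng = np.random.default_rng(36)
        draws = sum(
            s * rng.normal(l.dg, l.sigma, 1_000_000) for s, l in zip(signs, legs)
        )
        assert res.sigma == pytest.approx(draws.std(), rel=0.02)
        assert res.dg == pytest.approx(-47.73 - 41.0 - 0.84, abs=1e-12)
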