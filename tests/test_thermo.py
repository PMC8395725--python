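"""Swelling-pressure decomposition, Donnan partitioning, equilibrium roots."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from gelswell import thermo as th


# frozen arbitrary-precision evaluation (sympy, 30 digits) of the mixing law
# at phi=0.05, chi0=0.448, chi1=0.21, T=298.15 K, V1=1.8e-5 m^3/mol
MIXING_ORACLE = 20250.9287875141411176536939566


class TestMixingPressure:
    def test_zero_phi_is_exactly_zero(self, reference_chi, solvent):
        assert th.mixing_pressure(0.0, reference_chi, solvent) == 0.0

    def test_matches_arbitrary_precision_oracle(self, reference_chi, solvent):
        val = th.mixing_pressure(0.05, reference_chi, solvent)
        assert val == pytest.approx(MIXING_ORACLE, rel=1e-13)

    def test_theta_solvent_cubic_limit(self, solvent):
        # at chi0 = 1/2, chi1 = 0 the quadratic term cancels and
        # Pi_mix = (RT/V1)(phi^3/3 + O(phi^4)) from above
        fh = th.FloryHugginsParams(chi0=0.5, chi1=0.0)
        pref = solvent.rt / solvent.molar_volume
        for phi in (1e-3, 1e-4):
            val = th.mixing_pressure(phi, fh, solvent)
            assert val > 0
            assert val / (pref * phi**3) == pytest.approx(1.0 / 3.0, rel=5e-3)

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_domain_error_names_value(self, bad, reference_chi, solvent):
        with pytest.raises(ValueError, match="volume fraction"):
            th.mixing_pressure(bad, reference_chi, solvent)


class TestElasticPressure:
    def test_phi_one_returns_minus_g0(self):
        el = th.ElasticParams(g0=1000.0)
        assert th.elastic_pressure(1.0 - 1e-15, el) == pytest.approx(-1000.0, rel=1e-12)

    def test_equals_minus_shear_modulus(self, rng):
        el = th.ElasticParams(g0=12.3e3)
        phi = rng.uniform(1e-4, 0.99, size=50)
        np.testing.assert_allclose(
            th.elastic_pressure(phi, el), -el.shear_modulus(phi), rtol=0, atol=0
        )

    def test_log_domain_oracle(self):
        # 0.008^(1/3) = 0.2 exactly, so -g0 * 0.2 = -8000 Pa
        el = th.ElasticParams(g0=40e3)
        assert th.elastic_pressure(0.008, el) == pytest.approx(-8000.0, rel=1e-14)

    def test_nonpositive_phi_rejected(self):
        with pytest.raises(ValueError):
            th.elastic_pressure(0.0, th.ElasticParams(g0=1.0))

    def test_inconsistent_prefactor_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            th.ElasticParams(g0=1000.0, a_factor=1.0, nu=1.0)

    def test_from_chain_density(self):
        el = th.ElasticParams.from_chain_density(nu=4.0, a_factor=1.0)
        assert el.g0 == pytest.approx(4.0 * th.GAS_CONSTANT * 298.15, rel=1e-15)


class TestDonnan:
    def test_zero_fixed_charge_reproduces_bath(self, pa_params, nacl_bath):
        neutral = th.GelThermoParams(
            fh=pa_params.fh, elastic=pa_params.elastic, fixed_charge_per_monomer=0.0
        )
        internal = th.donnan_partition(0.05, neutral, nacl_bath)
        np.testing.assert_allclose(internal, nacl_bath.concentrations, rtol=1e-12)

    def test_univalent_closed_form(self, pa_params, nacl_bath):
        phi = 0.01
        cf = pa_params.fixed_charge_concentration(phi)
        cs = 40.0
        cation = 0.5 * (cf + np.sqrt(cf**2 + 4 * cs**2))
        internal = th.donnan_partition(phi, pa_params, nacl_bath)
        assert internal[0] == pytest.approx(cation, rel=1e-12)
        assert internal[1] == pytest.approx(cs**2 / cation, rel=1e-12)

    def test_mixed_valence_against_bisection_oracle(self, pa_params):
        bath = th.IonicBath.with_divalent(40.0, 2.0)
        phi = 0.02
        cf = pa_params.fixed_charge_concentration(phi)
        z, c = bath.valences, bath.concentrations

        def resid(lam):
            return float(np.sum(z * c * lam ** (-z)) - cf)

        lam_oracle = optimize.brentq(resid, 1e-6, 1e6, xtol=1e-15, rtol=8.9e-16)
        internal = th.donnan_partition(phi, pa_params, bath)
        np.testing.assert_allclose(internal, c * lam_oracle ** (-z), rtol=1e-10)

    def test_empty_bath_with_fixed_charge_errors(self, pa_params):
        bath = th.IonicBath([th.IonSpecies("Na+", 1, 0.0), th.IonSpecies("Cl-", -1, 0.0)])
        with pytest.raises(ValueError, match="no Donnan equilibrium"):
            th.donnan_partition(0.01, pa_params, bath)

    def test_bath_must_be_electroneutral(self):
        with pytest.raises(ValueError, match="electroneutral"):
            th.IonicBath([th.IonSpecies("Na+", 1, 10.0), th.IonSpecies("Cl-", -1, 5.0)])


class TestIonicPressure:
    def test_zero_for_neutral_gel(self, pa_params, nacl_bath):
        neutral = th.GelThermoParams(
            fh=pa_params.fh, elastic=pa_params.elastic, fixed_charge_per_monomer=0.0
        )
        assert th.ionic_pressure(0.05, neutral, nacl_bath) == pytest.approx(0.0, abs=1e-9)

    def test_nonnegative_and_monotone_in_salt(self, pa_params):
        salts = np.geomspace(1.0, 1000.0, 25)
        vals = [
            th.ionic_pressure(0.02, pa_params, th.IonicBath.monovalent(cs))
            for cs in salts
        ]
        assert all(v >= 0 for v in vals)
        assert all(a > b for a, b in zip(vals, vals[1:]))
        # vanishes in the high-salt limit (the added-salt regime where the
        # Donnan term is negligible)
        # asymptotically ~ RT c_f^2/(4 c_s): two decades of suppression here
        assert vals[-1] < 3e-3 * vals[0]


class TestSwellingPressure:
    @settings(deadline=None, max_examples=30)
    @given(
        phi=st.floats(1e-4, 0.4),
        chi1=st.floats(-0.5, 1.5),
        g0=st.floats(100.0, 1e5),
    )
    def test_components_sum_exactly(self, phi, chi1, g0):
        params = th.GelThermoParams(
            fh=th.FloryHugginsParams(0.45, chi1),
            elastic=th.ElasticParams(g0=g0),
            fixed_charge_per_monomer=0.05,
        )
        bath = th.IonicBath.monovalent(50.0)
        b = th.swelling_pressure(phi, params, bath)
        assert b.pi_tot == b.pi_mix + b.pi_el + b.pi_ion  # exact by construction
        assert b.pi_el <= 0
        assert b.pi_ion >= 0

    def test_neutral_reduction(self, reference_chi, solvent):
        params = th.GelThermoParams(
            fh=reference_chi,
            elastic=th.ElasticParams(g0=5e3),
            fixed_charge_per_monomer=0.0,
        )
        b = th.swelling_pressure(0.05, params, bath=None)
        assert b.pi_ion == 0.0
        assert b.pi_tot == pytest.approx(
            th.mixing_pressure(0.05, reference_chi, solvent)
            + th.elastic_pressure(0.05, params.elastic),
            rel=1e-15,
        )

    def test_breakdown_matches_component_ops(self, pa_params, nacl_bath):
        b = th.swelling_pressure(0.05, pa_params, nacl_bath)
        assert b.pi_mix == pytest.approx(
            th.mixing_pressure(0.05, pa_params.fh, pa_params.solvent), rel=1e-14
        )
        assert b.pi_el == pytest.approx(
            th.elastic_pressure(0.05, pa_params.elastic), rel=1e-14
        )
        assert b.pi_ion == pytest.approx(
            th.ionic_pressure(0.05, pa_params, nacl_bath), rel=1e-12
        )


class TestMixingFromTotal:
    def test_free_swelling_returns_modulus(self):
        assert th.mixing_from_total(0.0, 4200.0) == 4200.0

    def test_round_trip_with_decomposition(self, pa_params, nacl_bath):
        b = th.swelling_pressure(0.03, pa_params, nacl_bath)
        g = -b.pi_el
        assert th.mixing_from_total(b.pi_tot - b.pi_ion, g) == pytest.approx(
            b.pi_mix, rel=1e-12
        )

    def test_negative_modulus_rejected(self):
        with pytest.raises(ValueError):
            th.mixing_from_total(0.0, -1.0)


class TestEquilibrium:
    def test_inverse_consistency(self, pa_params, nacl_bath):
        phi_star = 0.02
        p_ext = th.swelling_pressure(phi_star, pa_params, nacl_bath).pi_tot
        assert p_ext > 0
        roots = th.equilibrium_phi(pa_params, nacl_bath, p_ext)
        best = min(roots, key=lambda r: abs(r.phi - phi_star))
        assert best.phi == pytest.approx(phi_star, rel=1e-9)
        assert abs(best.residual) < 1e-6

    def test_neutral_gel_against_grid_scan(self, reference_chi):
        params = th.GelThermoParams(
            fh=th.FloryHugginsParams(0.448, 0.0),
            elastic=th.ElasticParams(g0=2e3),
            fixed_charge_per_monomer=0.0,
        )
        grid = np.geomspace(1e-5, 0.5, 1_000_000)
        pi = th.total_pressure_profile(grid, params, None)
        sign_changes = np.nonzero(np.sign(pi[:-1]) * np.sign(pi[1:]) < 0)[0]
        roots = th.equilibrium_phi(params, None, 0.0)
        assert len(roots) == len(sign_changes)
        for er, i in zip(roots, sign_changes):
            assert grid[i] <= er.phi <= grid[i + 1]

    def test_no_root_raises(self, reference_chi):
        params = th.GelThermoParams(
            fh=th.FloryHugginsParams(0.0, 0.0),  # good solvent, gel swells hard
            elastic=th.ElasticParams(g0=1.0),
            fixed_charge_per_monomer=0.0,
        )
        with pytest.raises(th.NoEquilibriumError):
            th.equilibrium_phi(params, None, 1e9)

    def test_stability_labels(self, pa_params, nacl_bath):
        roots = th.equilibrium_phi(pa_params, nacl_bath, 0.0)
        assert sum(r.globally_stable for r in roots) == 1
        assert all(r.stable for r in roots if r.globally_stable)


class TestTransitionScan:
    def test_constant_chi_reports_no_transition(self, pa_params):
        from gelswell.presets import divalent_bath

        scan = th.transition_scan(
            pa_params,
            lambda c: pa_params.fh,
            divalent_bath,
            np.linspace(0.0, 1.0, 11),
        )
        assert not scan.has_transition
        assert scan.transition_salt is None

    def test_ramp_jump_matches_dense_grid_oracle(self, pa_params):
        from gelswell.presets import divalent_bath, divalent_chi_ramp

        coarse = np.linspace(0.0, 1.0, 21)
        scan = th.transition_scan(pa_params, divalent_chi_ramp, divalent_bath, coarse)
        assert scan.has_transition
        # independent dense brute-force scan of the stable branch
        dense = np.linspace(0.0, 1.0, 81)
        phis = np.array(
            [
                th.stable_phi(
                    pa_params.with_chi(divalent_chi_ramp(c)), divalent_bath(c)
                )
                for c in dense
            ]
        )
        jump = np.nonzero(phis[1:] / phis[:-1] > 3.0)[0]
        assert len(jump) > 0
        c_dense = dense[jump[0] + 1]
        # coarse-grid estimate brackets the dense one within one coarse step
        assert abs(scan.transition_salt - c_dense) <= (coarse[1] - coarse[0])

    def test_scan_direction_does_not_matter(self, pa_params):
        # the stable branch is an equilibrium property: scanning the grid
        # upward or downward yields the same curve (reversible transition)
        from gelswell.presets import divalent_bath, divalent_chi_ramp

        grid = np.linspace(0.0, 1.0, 11)
        up = th.transition_scan(pa_params, divalent_chi_ramp, divalent_bath, grid)
        down_phis = [
            th.stable_phi(pa_params.with_chi(divalent_chi_ramp(c)), divalent_bath(c))
            for c in grid[::-1]
        ]
        np.testing.assert_allclose(up.phi_stable, down_phis[::-1], rtol=1e-9)

    def test_non_monotone_grid_rejected(self, pa_params):
        with pytest.raises(ValueError, match="strictly increasing"):
            th.transition_scan(
                pa_params, lambda c: pa_params.fh, lambda c: None, [0.0, 2.0, 1.0]
            )


class TestChiFit:
    def test_exact_recovery_on_noiseless_data(self, reference_chi, solvent):
        phi = np.linspace(0.01, 0.1, 25)
        pi = th.mixing_pressure(phi, reference_chi, solvent)
        fit = th.fit_chi(phi, pi, solvent)
        assert fit.params.chi0 == pytest.approx(0.448, rel=1e-10)
        assert fit.params.chi1 == pytest.approx(0.21, rel=1e-10)
        assert fit.residual_norm < 1e-6

    def test_chi1_zero_data_recovers_zero_within_stderr(self, solvent, rng):
        fh = th.FloryHugginsParams(0.46, 0.0)
        phi = np.linspace(0.02, 0.2, 30)
        pi = th.mixing_pressure(phi, fh, solvent)
        pi_noisy = pi * (1 + 0.001 * rng.standard_normal(phi.shape))
        fit = th.fit_chi(phi, pi_noisy, solvent)
        assert abs(fit.params.chi1) < 3 * fit.stderr_chi1

    def test_unbiased_under_relative_noise(self, reference_chi, solvent):
        # 200 replicates at 2% noise, n=25: chi0 bias below 3x its MC error
        phi = np.linspace(0.01, 0.1, 25)
        pi = th.mixing_pressure(phi, reference_chi, solvent)
        rng = np.random.default_rng(7)
        est = []
        for _ in range(200):
            noisy = pi * (1 + 0.02 * rng.standard_normal(phi.shape))
            est.append(th.fit_chi(phi, noisy, solvent).params.chi0)
        est = np.asarray(est)
        mc_err = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - reference_chi.chi0) < 3 * mc_err

    def test_constrained_chi0_fit(self, reference_chi, solvent):
        phi = np.linspace(0.01, 0.1, 25)
        pi = th.mixing_pressure(phi, reference_chi, solvent)
        fit = th.fit_chi(phi, pi, solvent, fix_chi0=0.448)
        assert fit.params.chi0 == 0.448
        assert fit.params.chi1 == pytest.approx(0.21, rel=1e-10)

    def test_too_few_records_rejected(self, solvent):
        with pytest.raises(ValueError, match=">= 3"):
            th.fit_chi([0.01, 0.02], [1.0, 2.0], solvent)

    def test_degenerate_design_rejected(self, solvent):
        with pytest.raises(ValueError, match="degenerate"):
            th.fit_chi([0.05, 0.05, 0.05], [1.0, 1.1, 0.9], solvent)
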