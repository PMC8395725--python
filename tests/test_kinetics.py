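"""Sphere mode relation, first-mode fits, D_c extraction, master curve."""

import numpy as np
import pytest

from gelswell import kinetics as kn
from gelswell.sphere_modes import PURE_DIFFUSION_B1, SphereModeRelation
from gelswell.synthetic import NoiseSpec, gen_swelling_curves

REL = SphereModeRelation()


class TestSphereModes:
    def test_pure_diffusion_limit(self):
        assert REL.b1(0.0) == pytest.approx(6 / np.pi**2, rel=1e-15)
        assert REL.beta1(0.0) == np.pi

    def test_mode_weights_sum_to_one(self):
        # sum 6/(n pi)^2 = (6/pi^2) * (pi^2/6) = 1
        betas, amps = REL.spectrum(0.0, 10_000)
        partial = np.cumsum(amps)
        assert np.all(np.diff(partial) > 0)
        assert np.all(partial <= 1.0 + 1e-12)
        assert partial[-1] == pytest.approx(1.0, abs=1e-4)

    def test_shear_corrected_weights_also_sum_to_one(self):
        _, amps = REL.spectrum(0.3, 400)
        assert amps.sum() == pytest.approx(1.0, abs=5e-3)

    def test_b1_monotone_increasing_in_modulus_ratio(self):
        rs = np.linspace(0.0, 0.7499, 1000)
        b1 = np.array([REL.b1(r) for r in rs])
        assert np.all(np.diff(b1) > 0)

    def test_round_trip_inverse(self):
        for r in np.linspace(0.0, 0.74, 25):
            beta, r_back = REL.invert_b1(REL.b1(r))
            assert abs(r_back - r) < 1e-8
            assert beta == pytest.approx(REL.beta1(r) if r else np.pi, rel=1e-10)

    def test_out_of_range_reports_interval(self):
        with pytest.raises(ValueError, match="attainable range"):
            REL.invert_b1(0.3)


class TestModelDiameter:
    def test_initial_and_final_values(self):
        modes = kn.pure_diffusion_modes(120.0, 2000)
        d = kn.model_diameter(np.array([0.0]), 1e-3, 1.6e-3, modes)
        # sum B_n -> 1, truncation tail ~ (6/pi^2)/N
        assert d[0] == pytest.approx(1e-3, rel=5e-4)
        d_inf = kn.model_diameter(np.array([1e9]), 1e-3, 1.6e-3, modes)
        assert d_inf[0] == pytest.approx(1.6e-3, rel=1e-12)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            kn.model_diameter([0.0], 1e-3, 2e-3, [(0.6, -1.0)])

    def test_overweight_modes_rejected(self):
        with pytest.raises(ValueError, match="> 1"):
            kn.model_diameter([0.0], 1e-3, 2e-3, [(0.8, 10.0), (0.4, 1.0)])

    def test_shrinking_sign_convention(self):
        d = kn.model_diameter(np.array([0.0, 1e9]), 2e-3, 1e-3, [(1.0, 50.0)])
        assert d[0] == pytest.approx(2e-3)
        assert d[1] == pytest.approx(1e-3)


class TestLinearize:
    def test_single_mode_is_exactly_linear(self):
        t = np.linspace(0, 500, 60)
        curve = kn.SwellingCurve(
            t=t, d=kn.model_diameter(t, 1e-3, 1.5e-3, [(0.6, 120.0)]),
            d0=1e-3, d_inf=1.5e-3,
        )
        tt, y, dropped = kn.linearize(curve)
        assert dropped == 0
        slope, intercept = np.polyfit(tt, y, 1)
        assert slope == pytest.approx(-1 / 120.0, rel=1e-9)
        assert intercept == pytest.approx(np.log(0.6), rel=1e-9)

    def test_multimode_curvature_and_asymptote(self):
        tau1 = 200.0
        t = np.linspace(1.0, 5 * tau1, 400)
        d = kn.model_diameter(t, 1e-3, 1.6e-3, kn.pure_diffusion_modes(tau1, 200))
        curve = kn.SwellingCurve(t=t, d=d, d0=1e-3, d_inf=1.6e-3)
        tt, y, _ = kn.linearize(curve)
        early = np.polyfit(tt[:40], y[:40], 1)[0]
        late = np.polyfit(tt[-80:], y[-80:], 1)[0]
        assert early < late < 0  # steeper early decay from the fast modes
        assert late == pytest.approx(-1 / tau1, rel=1e-3)

    def test_plateau_noise_dropped_and_counted(self, rng):
        t = np.linspace(0, 2000, 50)
        d = kn.model_diameter(t, 1e-3, 1.5e-3, [(0.6, 100.0)])
        d = d + 1e-6 * rng.standard_normal(d.shape)
        curve = kn.SwellingCurve(t=t, d=d, d0=1e-3, d_inf=1.5e-3)
        _, _, dropped = kn.linearize(curve)
        assert dropped > 0

    def test_degenerate_plateau_rejected(self):
        t = np.linspace(0, 10, 12)
        curve = kn.SwellingCurve(t=t, d=np.full(12, 1e-3), d0=1e-3, d_inf=1e-3)
        with pytest.raises(ValueError, match="d_inf"):
            kn.linearize(curve)


class TestFirstModeFit:
    def test_exact_single_exponential_recovery(self):
        t = np.linspace(0, 600, 80)
        curve = kn.SwellingCurve(
            t=t, d=kn.model_diameter(t, 1e-3, 1.5e-3, [(0.6, 120.0)]),
            d0=1e-3, d_inf=1.5e-3,
        )
        fit = kn.fit_first_mode(curve)
        assert fit.B1 == pytest.approx(0.6, rel=1e-8)
        assert fit.tau1 == pytest.approx(120.0, rel=1e-8)

    def test_d_inf_estimated_when_missing(self):
        t = np.linspace(0, 800, 120)
        curve = kn.SwellingCurve(
            t=t, d=kn.model_diameter(t, 1e-3, 1.5e-3, [(0.6, 120.0)]),
            d0=1e-3, d_inf=None,
        )
        fit = kn.fit_first_mode(curve)
        assert fit.d_inf == pytest.approx(1.5e-3, rel=1e-4)
        assert fit.tau1 == pytest.approx(120.0, rel=1e-3)

    def test_multimode_long_time_window_recovers_first_mode(self):
        tau1 = 150.0
        t = np.linspace(1.05 * tau1, 5 * tau1, 300)  # sampled at t > tau1
        d = kn.model_diameter(t, 1e-3, 1.6e-3, kn.pure_diffusion_modes(tau1, 300))
        curve = kn.SwellingCurve(t=t, d=d, d0=1e-3, d_inf=1.6e-3)
        # the long-time linear extrapolation itself (no single-mode
        # diameter-space refinement, which would re-weight the early
        # multi-mode points)
        fit = kn.fit_first_mode(curve, window_policy="iterative", refine=False)
        assert fit.B1 == pytest.approx(PURE_DIFFUSION_B1, rel=0.01)
        assert fit.tau1 == pytest.approx(tau1, rel=0.01)

    def test_size_scaling_of_relaxation_time(self):
        # radii a and 2a at one D_c: tau ratio 4
        curves, _ = gen_swelling_curves(
            dc=3e-11, r_ratio=0.25, radii=[2.5e-4, 5.0e-4],
            noise=NoiseSpec(level=0.0, seed=0),
        )
        fits = [kn.fit_first_mode(c, window_policy="all") for c in curves]
        assert fits[1].tau1 / fits[0].tau1 == pytest.approx(4.0, rel=1e-6)

    def test_non_relaxing_data_raises(self):
        t = np.linspace(0, 100, 30)
        d = 1e-3 - 1e-6 * t  # drifting away from its (higher) plateau
        curve = kn.SwellingCurve(t=t, d=d, d0=1e-3, d_inf=1.2e-3)
        with pytest.raises(ValueError, match="non-relaxing"):
            kn.fit_first_mode(curve, refine=False)

    def test_too_few_points_rejected(self):
        t = np.linspace(0, 10, 3)
        curve = kn.SwellingCurve(t=t, d=np.array([1.0, 1.1, 1.2]) * 1e-3,
                                 d0=1e-3, d_inf=1.3e-3)
        with pytest.raises(ValueError):
            kn.fit_first_mode(curve)


class TestBetaFromB1:
    def test_pure_diffusion_point(self):
        beta, r = kn.beta_from_B1(PURE_DIFFUSION_B1)
        assert beta == np.pi
        assert r == 0.0

    def test_noise_tolerance_clamps(self):
        beta, r = kn.beta_from_B1(PURE_DIFFUSION_B1 - 0.01)
        assert (beta, r) == (np.pi, 0.0)

    def test_far_out_of_range_raises(self):
        with pytest.raises(ValueError):
            kn.beta_from_B1(0.4)


class TestCollectiveDiffusion:
    def test_arithmetic_oracle(self):
        # (0.5 mm)^2 / (pi^2 * 100 s), frozen from 20-digit evaluation
        assert kn.collective_diffusion(0.5e-3, np.pi, 100.0) == pytest.approx(
            2.5330295910584442861e-10, rel=1e-12
        )

    def test_invariant_across_bead_size_family(self):
        curves, gt = gen_swelling_curves(
            dc=3e-11, r_ratio=0.25, radii=[2.5e-4, 3.75e-4, 5.0e-4],
            noise=NoiseSpec(level=0.0, seed=0),
        )
        fits = kn.analyze_family(curves, window_policy="all")
        dcs = np.array([f.Dc for f in fits])
        np.testing.assert_allclose(dcs, 3e-11, rtol=1e-6)

    def test_neutral_gel_magnitude_band(self):
        # collective diffusion of typical swollen networks: 1e-11..1e-10 m^2/s
        curves, _ = gen_swelling_curves(
            dc=3e-11, r_ratio=0.25, radii=[5.0e-4],
            noise=NoiseSpec(level=0.01, seed=5),
        )
        fit = kn.analyze_curve(curves[0], window_policy="all")
        assert 1e-11 < fit.Dc < 1e-10

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            kn.collective_diffusion(-1.0, np.pi, 10.0)


class TestMasterCurve:
    def test_identical_parameters_collapse_to_zero(self):
        curves, _ = gen_swelling_curves(
            dc=3e-11, r_ratio=0.25, radii=[2.5e-4, 3.75e-4, 5.0e-4],
            noise=NoiseSpec(level=0.0, seed=0),
        )
        fits = kn.analyze_family(curves, window_policy="all")
        mc = kn.master_curve(curves, fits)
        assert mc.collapse_score == pytest.approx(0.0, abs=1e-9)

    def test_salt_families_separate_into_two_plateaus(self):
        # higher salt -> lower equilibrium swelling -> lower plateau
        fam_lo, _ = gen_swelling_curves(
            dc=3e-11, r_ratio=0.25, radii=[2.5e-4, 5.0e-4], d_ratio=1.6,
            noise=NoiseSpec(level=0.01, seed=1),
        )
        fam_hi, _ = gen_swelling_curves(
            dc=3e-11, r_ratio=0.25, radii=[2.5e-4, 5.0e-4], d_ratio=1.25,
            noise=NoiseSpec(level=0.01, seed=2),
        )
        fits_lo = kn.analyze_family(fam_lo, window_policy="all")
        fits_hi = kn.analyze_family(fam_hi, window_policy="all")
        within = max(
            kn.master_curve(fam_lo, fits_lo).collapse_score,
            kn.master_curve(fam_hi, fits_hi).collapse_score,
        )
        across = kn.master_curve(
            list(fam_lo) + list(fam_hi), fits_lo + fits_hi
        ).collapse_score
        assert across > 5 * within
        plateau_lo = np.mean([c.d[-20:].mean() / c.d0 for c in fam_lo])
        plateau_hi = np.mean([c.d[-20:].mean() / c.d0 for c in fam_hi])
        assert plateau_lo > plateau_hi

    def test_binned_score_agrees_with_pairwise_oracle(self):
        curves, _ = gen_swelling_curves(
            dc=3e-11, r_ratio=0.25, radii=[2.5e-4, 3.75e-4, 5.0e-4],
            noise=NoiseSpec(level=0.01, seed=3),
        )
        fits = kn.analyze_family(curves, window_policy="all")
        mc = kn.master_curve(curves, fits)
        # brute-force estimator: RMS pairwise difference / sqrt(2) after
        # interpolating each pair onto the overlap of mc's bin centers
        diffs = []
        red = [(c.t / f.tau1, c.d / c.d0) for c, f in zip(curves, fits)]
        for i in range(len(red)):
            for j in range(i + 1, len(red)):
                yi = np.interp(mc.bin_centers, *red[i])
                yj = np.interp(mc.bin_centers, *red[j])
                diffs.append((yi - yj) ** 2 / 2.0)
        oracle = np.sqrt(np.mean(diffs))
        assert mc.collapse_score == pytest.approx(oracle, rel=0.10)

    def test_single_curve_returns_rescaled_data_only(self):
        curves, _ = gen_swelling_curves(
            dc=3e-11, r_ratio=0.25, radii=[5e-4], noise=NoiseSpec(level=0.0, seed=0)
        )
        fits = [kn.analyze_curve(curves[0], window_policy="all")]
        mc = kn.master_curve(curves, fits)
        assert mc.collapse_score is None
        assert len(mc.reduced_time) == 1
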