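"""Dispersion fitting: decays, single/global exchange fits, MC errors, CEST."""

import math

import numpy as np
import pytest

from rnaexcite import (
    CESTSetting,
    ExchangeParams,
    RelaxationRates,
    SpinLockSetting,
    SpinProbe,
    difference_cest,
    fit_cest,
    fit_decay_to_r1rho,
    fit_r1rho_global,
    fit_r1rho_single,
    mc_errors,
    normalize_cest,
    reconstruct_es_shift,
    simulate_cest,
)
from rnaexcite.exchange import laguerre_rate
from rnaexcite.fitting import FitResult, ProbeFit
from rnaexcite.profiles import CESTProfile, R1rhoProfile
from rnaexcite.synth import gen_cest_dataset, gen_r1rho_dataset, t1_ground_truth


def laguerre_profile(pES=0.062, kex=453.0, dw_ppm=2.0, R1=2.0, R2=18.0,
                     err=0.01, powers=(100, 150, 200, 300, 500),
                     mults=(-2, -1, -0.5, 0, 0.5, 1, 2), residue=14):
    """Noiseless pre-fit R1rho profile drawn from the closed form."""
    probe = SpinProbe.from_ppm(residue, "N1", 60.8, 0.0, dw_ppm)
    settings, vals = [], []
    for p in powers:
        for m in mults:
            sl = SpinLockSetting.from_hz(p, m * p)
            settings.append(sl)
            r, _ = laguerre_rate(pES, kex, probe.delta_omega, R1, R2,
                                 sl.omega_SL, sl.omega_rf, 0.0)
            vals.append(float(r))
    return R1rhoProfile(
        probe=probe, settings=settings,
        r1rho=np.array(vals), r1rho_err=np.full(len(vals), err),
    )


class TestDecayFit:
    def test_exact_mono_exponential_recovered(self):
        t = np.arange(0.0, 0.061, 0.01)
        y = 100.0 * np.exp(-30.0 * t)
        rate, sd = fit_decay_to_r1rho(t, y, np.ones_like(t), n_mc=0)
        assert abs(rate - 30.0) < 1e-6

    def test_flat_decay_gives_zero_rate(self):
        t = np.arange(0.0, 0.08, 0.01)
        rate, _ = fit_decay_to_r1rho(t, np.full(t.size, 57.0), np.ones_like(t),
                                     n_mc=0)
        assert rate == pytest.approx(0.0, abs=1e-9)

    def test_mc_sd_tracks_linearized_covariance(self):
        t = np.linspace(0.0, 0.07, 8)
        I0, R, sigma = 100.0, 30.0, 1.0
        y = I0 * np.exp(-R * t)
        _, sd = fit_decay_to_r1rho(t, y, np.full(t.size, sigma), n_mc=200, seed=4)
        # analytic oracle: cov = sigma^2 (J^T J)^-1 for f = I0 exp(-R t)
        J = np.column_stack([np.exp(-R * t), -I0 * t * np.exp(-R * t)])
        sd_lin = math.sqrt((sigma**2 * np.linalg.inv(J.T @ J))[1, 1])
        assert sd_lin / 2 < sd < sd_lin * 2

    def test_deterministic_under_seed(self):
        t = np.linspace(0.0, 0.07, 8)
        y = 100.0 * np.exp(-25.0 * t)
        a = fit_decay_to_r1rho(t, y, np.ones_like(t), seed=3)
        b = fit_decay_to_r1rho(t, y, np.ones_like(t), seed=3)
        assert a == b

    def test_too_few_delays_rejected(self):
        with pytest.raises(ValueError):
            fit_decay_to_r1rho([0.0, 0.01], [10, 9], [1, 1])


class TestSingleFit:
    def test_noiseless_profile_recovers_all_parameters(self):
        prof = laguerre_profile()
        fit = fit_r1rho_single(prof, diagnose=False)
        assert fit.params.pES == pytest.approx(0.062, rel=1e-3)
        assert fit.params.kex == pytest.approx(453.0, rel=1e-3)
        pf = fit.probe_fits[14]
        assert abs(pf.delta_omega_ppm) == pytest.approx(2.0, rel=1e-3)
        assert pf.R1 == pytest.approx(2.0, rel=1e-3)
        assert pf.R2 == pytest.approx(18.0, rel=1e-3)

    def test_no_exchange_data_flagged(self):
        prof = laguerre_profile(pES=0.0, kex=0.0, dw_ppm=0.0)
        fit = fit_r1rho_single(prof)
        assert "no_exchange_information" in fit.flags

    def test_wrong_sign_start_recovers_magnitude_or_flags(self):
        prof = laguerre_profile(dw_ppm=2.0)
        init = FitResult(
            params=ExchangeParams.from_populations(0.05, 400.0),
            probe_fits={14: ProbeFit(-2.0, 2.0, 18.0)},
            chi2=0.0, dof=1,
        )
        fit = fit_r1rho_single(prof, init=init)
        recovered = abs(fit.probe_fits[14].delta_omega_ppm)
        assert recovered == pytest.approx(2.0, rel=1e-2) or (
            "ambiguous_dw_sign" in fit.flags
        )


class TestGlobalFit:
    def test_global_equals_single_when_truths_coincide(self):
        profiles = [laguerre_profile(dw_ppm=2.0, residue=14),
                    laguerre_profile(dw_ppm=2.0, residue=21)]
        g = fit_r1rho_global(profiles, diagnose=False)
        s = fit_r1rho_single(profiles[0], diagnose=False)
        assert abs(g.params.pES - s.params.pES) < 1e-6
        assert abs(g.params.kex - s.params.kex) / s.params.kex < 1e-6

    def test_global_chi2_is_sum_over_probes(self):
        rng = np.random.default_rng(0)
        profiles = []
        for residue, dw in ((14, 1.5), (21, 2.5)):
            p = laguerre_profile(dw_ppm=dw, residue=residue)
            p.r1rho = p.r1rho + rng.normal(0, 0.01, p.r1rho.size)
            profiles.append(p)
        g = fit_r1rho_global(profiles, diagnose=False)
        # shared parameters cannot beat unconstrained per-probe fits
        singles = sum(
            fit_r1rho_single(p, diagnose=False).chi2 for p in profiles
        )
        assert g.chi2 >= singles - 1e-6

    def test_model_misspecification_detectable(self):
        fast = laguerre_profile(kex=900.0, residue=14)
        slow = laguerre_profile(kex=300.0, residue=21)
        g = fit_r1rho_global([fast, slow], diagnose=False)
        singles = sum(fit_r1rho_single(p, diagnose=False).chi2 for p in [fast, slow])
        assert g.chi2 > singles + 1.0


class TestMCErrors:
    def make_fit(self, profiles):
        return fit_r1rho_global(profiles, diagnose=False)

    def test_vanishing_errors_give_vanishing_sds(self):
        prof = laguerre_profile(err=1e-12)
        fit = self.make_fit([prof])
        err = mc_errors(fit, [prof], n_mc=10, seed=1)
        assert err["pES"] < 1e-8
        assert err["kex"] < 1e-4

    def test_sds_scale_linearly_with_measurement_error(self):
        a = laguerre_profile(err=0.05)
        b = laguerre_profile(err=0.10)
        fit_a, fit_b = self.make_fit([a]), self.make_fit([b])
        sd_a = mc_errors(fit_a, [a], n_mc=50, seed=2)["pES"]
        sd_b = mc_errors(fit_b, [b], n_mc=50, seed=2)["pES"]
        assert sd_b / sd_a == pytest.approx(2.0, rel=0.3)

    def test_deterministic_under_seed(self):
        prof = laguerre_profile(err=0.05)
        fit = self.make_fit([prof])
        e1 = mc_errors(fit, [prof], n_mc=10, seed=5)
        e2 = mc_errors(fit, [prof], n_mc=10, seed=5)
        assert e1 == e2

    def test_paper_scale_population_uncertainty(self):
        """A four-probe dataset at 2% noise yields pB uncertainties on the
        0.1-0.5 percentage-point scale."""
        truth = t1_ground_truth(seed=42, noise=0.02)
        profiles, truth = gen_r1rho_dataset(truth)
        fit = fit_r1rho_global(profiles, seed=1, diagnose=False)
        err = mc_errors(fit, profiles, n_mc=50, seed=2)
        assert 0.05 <= 100 * err["pES"] <= 0.5


class TestCESTOperations:
    def make_profile(self, intensity, component="alpha"):
        probe = SpinProbe.from_ppm(1, "H1", 600.0, gs_ppm=12.0)
        setting = CESTSetting(
            b1_Hz=15.0, mixing_time=0.2,
            carrier_grid=tuple(np.linspace(10, 14, intensity.size).tolist()),
        )
        return CESTProfile(probe=probe, setting=setting, component=component,
                           intensity=intensity)

    def test_normalization_is_a_ratio(self):
        prof = self.make_profile(np.full(5, 500.0))
        out = normalize_cest(prof, 1000.0)
        assert np.allclose(out.intensity, 0.5)
        same = normalize_cest(self.make_profile(np.full(5, 7.0)), 7.0)
        assert np.allclose(same.intensity, 1.0)

    def test_normalization_rejects_nonpositive_reference(self):
        with pytest.raises(ValueError):
            normalize_cest(self.make_profile(np.ones(5)), 0.0)

    def test_default_reference_is_far_off_resonance(self):
        assert CESTSetting.ppm_scan().reference_offset == -12000.0

    def test_difference_of_identical_components_is_zero(self):
        a = self.make_profile(np.linspace(1.0, 0.2, 9))
        b = self.make_profile(np.linspace(1.0, 0.2, 9), component="beta")
        d = difference_cest(a, b)
        assert d.component == "difference"
        assert np.allclose(d.intensity, 0.0)

    def test_mismatched_grids_rejected(self):
        a = self.make_profile(np.ones(9))
        b = self.make_profile(np.ones(10), component="beta")
        with pytest.raises(ValueError, match="grids"):
            difference_cest(a, b)

    def test_difference_profile_peaks_at_both_state_positions(self):
        truth = t1_ground_truth(seed=3, noise=0.0)
        pairs, truth = gen_cest_dataset(truth, seed=3)
        alpha, beta = pairs[3]
        d = difference_cest(alpha, beta)
        grid = d.setting.grid
        step = grid[1] - grid[0]
        gs = alpha.probe.gs_ppm
        es = gs + alpha.probe.delta_omega_ppm
        v = np.abs(d.intensity)
        peaks = [grid[i] for i in range(1, v.size - 1)
                 if v[i] >= v[i - 1] and v[i] >= v[i + 1] and v[i] > 0.02]
        assert any(abs(p - es) <= step for p in peaks)
        assert any(abs(p - gs) <= 2 * step for p in peaks)


class TestCESTFit:
    def test_recovers_es_shift_with_frozen_exchange(self):
        truth = t1_ground_truth(seed=6, noise=0.02)
        pairs, truth = gen_cest_dataset(truth, seed=6)
        alpha, _ = pairs[2]
        res = fit_cest(alpha, truth.params)
        expected = alpha.probe.gs_ppm + alpha.probe.delta_omega_ppm
        assert res.es_shift_ppm == pytest.approx(expected, abs=0.03)

    def test_default_scan_matches_acquisition_grid(self):
        setting = CESTSetting.ppm_scan(larmor_MHz=600.0)
        grid = setting.grid
        assert grid[0] == pytest.approx(8.5)
        assert grid[-1] <= 15.5
        assert (grid[1] - grid[0]) * 600.0 == pytest.approx(30.0)

    def test_null_data_collapses_or_flags(self):
        probe = SpinProbe.from_ppm(1, "H1", 600.0, gs_ppm=12.0, delta_omega_ppm=0.0)
        setting = CESTSetting.ppm_scan(larmor_MHz=600.0, start_ppm=10.5,
                                       stop_ppm=13.5)
        none = ExchangeParams.from_populations(0.0, 0.0)
        prof = simulate_cest(none, probe, setting, RelaxationRates(2.5, 30.0))
        res = fit_cest(prof, ExchangeParams.from_populations(0.06, 453.0))
        assert "dw_collapsed" in res.flags or abs(res.delta_omega_ppm) < 0.15

    def test_unidentifiable_population_rejected(self):
        probe = SpinProbe.from_ppm(1, "H1", 600.0, gs_ppm=12.0)
        setting = CESTSetting.ppm_scan(larmor_MHz=600.0, start_ppm=11.0,
                                       stop_ppm=13.0)
        prof = simulate_cest(
            ExchangeParams.from_populations(0.001, 400.0), probe, setting,
            RelaxationRates(2.5, 30.0),
        )
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_cest(prof, ExchangeParams.from_populations(0.001, 400.0))


class TestReconstructShift:
    def test_addition_and_identity(self):
        assert reconstruct_es_shift(145.0, 2.0) == pytest.approx(147.0)
        assert reconstruct_es_shift(145.0, 0.0) == pytest.approx(145.0)

    def test_downfield_transition_moves_es_downfield(self):
        # G.U -> G-C type transitions shift the imino resonance downfield
        assert reconstruct_es_shift(145.0, 2.0) > 145.0
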