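"""HN/Cole–Cole fitting, loss-peak times, master plots, and the KWW transform."""

import dataclasses
import math

import numpy as np
import pytest

import amorphkin as ak
from amorphkin.exceptions import ValidationError
from amorphkin.relaxation import _kww_loss_raw


def hn_reference(freq, delta_eps, tau, a, b, eps_inf=1.0, sigma_dc=0.0):
    """Independent complex-arithmetic evaluation of the HN formula."""
    out_r, out_i = [], []
    for f in freq:
        w = 2 * math.pi * f
        z = complex(eps_inf, 0.0)
        z += delta_eps / (1 + (1j * w * tau) ** a) ** b
        loss = -z.imag + (sigma_dc / (ak.types.VACUUM_PERMITTIVITY * w) if sigma_dc else 0.0)
        out_r.append(z.real)
        out_i.append(loss)
    return np.array(out_r), np.array(out_i)


class TestHnModel:
    def test_debye_peak_position_and_height(self):
        tau = 1e-3
        freq = np.logspace(-2, 5, 2801)
        _, loss = ak.hn_eps(freq, [2.0], [tau], [1.0], [1.0])
        i = np.argmax(loss)
        assert freq[i] == pytest.approx(1 / (2 * math.pi * tau), rel=3e-3)
        assert loss[i] == pytest.approx(1.0, rel=1e-5)  # delta_eps / 2

    def test_ohmic_conductivity_has_slope_minus_one(self):
        freq = np.logspace(-1, 6, 57)
        _, loss = ak.hn_eps(freq, [1e-12], [1e-5], [1.0], [1.0], sigma_dc=1e-9)
        slope = np.polyfit(np.log10(freq), np.log10(loss), 1)[0]
        assert slope == pytest.approx(-1.0, abs=1e-9)

    def test_agrees_with_independent_complex_evaluation(self):
        freq = np.logspace(-1, 6, 57)
        er, ei = ak.hn_eps(freq, [8.9], [1e-4], [0.8], [0.6], eps_inf=3.0,
                           sigma_dc=1e-10)
        rr, ri = hn_reference(freq, 8.9, 1e-4, 0.8, 0.6, eps_inf=3.0, sigma_dc=1e-10)
        np.testing.assert_allclose(er, rr, rtol=1e-12)
        np.testing.assert_allclose(ei, ri, rtol=1e-12)

    def test_real_part_is_analytic_hn_real_part(self):
        # Kramers–Kronig consistency collapses to a single-formula identity
        freq = np.logspace(-1, 6, 57)
        w = 2 * np.pi * freq
        er, _ = ak.hn_eps(freq, [5.0], [1e-3], [0.7], [0.4], eps_inf=2.0)
        expected = 2.0 + (5.0 / (1 + (1j * w * 1e-3) ** 0.7) ** 0.4).real
        np.testing.assert_allclose(er, expected, rtol=1e-12)


class TestTauMax:
    def test_debye_and_cole_cole_reduce_to_tau_hn(self):
        assert ak.tau_max_from_hn(ak.HNProcess(1, 1e-3, 1.0, 1.0)) == pytest.approx(1e-3)
        for a in (0.3, 0.6, 0.9):
            p = ak.HNProcess(1, 2e-5, a, 1.0)
            assert ak.tau_max_from_hn(p) == pytest.approx(2e-5, rel=1e-12)

    def test_matches_grid_argmax_for_asymmetric_process(self):
        p = ak.HNProcess(1.0, 1.0, 0.8, 0.6)
        tm = ak.tau_max_from_hn(p)
        f = np.logspace(np.log10(1 / (2 * np.pi * tm)) - 2,
                        np.log10(1 / (2 * np.pi * tm)) + 2, 1_000_000)
        _, loss = ak.hn_eps(f, [1.0], [1.0], [0.8], [0.6])
        t_num = 1 / (2 * np.pi * f[np.argmax(loss)])
        assert tm == pytest.approx(t_num, rel=1e-4)

    def test_peak_formula_against_argmax_100_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b = rng.uniform(0.2, 1.0, 2)
            p = ak.HNProcess(1.0, 1.0, a, b)
            tm = ak.tau_max_from_hn(p)
            lg = np.log10(1 / (2 * np.pi * tm))
            f = np.logspace(lg - 1.5, lg + 1.5, 200_001)
            _, loss = ak.hn_eps(f, [1.0], [1.0], [a], [b])
            t_num = 1 / (2 * np.pi * f[np.argmax(loss)])
            assert abs(tm / t_num - 1) < 1e-3


class TestFitHn:
    def test_noiseless_round_trip_to_per_mille(self, alpha_spectral_truth):
        (sp,) = ak.gen_bds_temperature_series(
            alpha_spectral_truth, None, [330.0],
            secondary=((alpha_spectral_truth.processes[0],
                        ak.ArrheniusParams(-4.0, 0.0)),),
        )
        fit = ak.fit_hn(sp, include_conductivity=True, include_real=True)
        p, q = alpha_spectral_truth.processes[0], fit.processes[0]
        assert q.delta_eps == pytest.approx(p.delta_eps, rel=1e-3)
        assert q.tau_hn == pytest.approx(p.tau_hn, rel=1e-3)
        assert q.a == pytest.approx(p.a, abs=1e-3)
        assert q.b == pytest.approx(p.b, abs=1e-3)
        assert fit.eps_inf == pytest.approx(alpha_spectral_truth.eps_inf, rel=1e-3)
        assert fit.sigma_dc == pytest.approx(alpha_spectral_truth.sigma_dc, rel=1e-2)

    def test_monte_carlo_recovery_with_multiplicative_noise(self, alpha_spectral_truth):
        noisy = dataclasses.replace(alpha_spectral_truth, noise_sd=0.02)
        tau_errs, de_errs = [], []
        for seed in range(20):
            (sp,) = ak.gen_bds_temperature_series(
                noisy, None, [330.0],
                secondary=((noisy.processes[0], ak.ArrheniusParams(-4.0, 0.0)),),
                seed=seed,
            )
            fit = ak.fit_hn(sp, include_conductivity=True, include_real=True,
                            config=ak.StudyConfig(seed=seed))
            q = fit.processes[0]
            de_errs.append(abs(q.delta_eps / 8.9 - 1))
            tau_errs.append(abs(q.tau_hn / 1e-4 - 1))
            assert abs(q.a - 0.85) < 0.05 and abs(q.b - 0.55) < 0.05
        assert max(de_errs) < 0.05
        assert np.mean(tau_errs) < 0.05 and max(tau_errs) < 0.10

    def test_debye_input_drives_free_shape_exponents_to_one(self):
        freq = np.logspace(-1, 6, 57)
        er, ei = ak.hn_eps(freq, [5.0], [1e-3], [1.0], [1.0], eps_inf=3.0)
        sp = ak.DielectricSpectrum(frequency=freq, eps_real=er, eps_imag=ei)
        fit = ak.fit_hn(sp, include_conductivity=False, include_real=True)
        assert fit.processes[0].a == pytest.approx(1.0, abs=1e-3)
        assert fit.processes[0].b == pytest.approx(1.0, abs=1e-3)

    def test_scale_equivariance_in_frequency(self, alpha_spectral_truth):
        truth = dataclasses.replace(alpha_spectral_truth, sigma_dc=0.0)
        base = truth.processes[0]
        c = 100.0
        fits = []
        for tau, fgrid in [(base.tau_hn, np.logspace(-1, 6, 57)),
                           (base.tau_hn / c, np.logspace(-1, 6, 57) * c)]:
            er, ei = ak.hn_eps(fgrid, [base.delta_eps], [tau], [base.a], [base.b],
                               eps_inf=3.0)
            sp = ak.DielectricSpectrum(frequency=fgrid, eps_real=er, eps_imag=ei)
            fits.append(ak.fit_hn(sp, include_conductivity=False, include_real=True))
        p1, p2 = fits[0].processes[0], fits[1].processes[0]
        assert p2.a == pytest.approx(p1.a, abs=1e-6)
        assert p2.b == pytest.approx(p1.b, abs=1e-6)
        assert p2.tau_hn * c == pytest.approx(p1.tau_hn, rel=1e-6)


class TestSecondaryColeCole:
    def _two_cc_spectrum(self, noise=0.0, seed=0):
        truth = ak.SpectralTruth(
            processes=(ak.HNProcess(0.5, 1e-3, 0.4, 1.0),
                       ak.HNProcess(0.3, 1e-6, 0.3, 1.0)),
            eps_inf=3.0, sigma_dc=0.0, noise_sd=noise,
        )
        beta = (truth.processes[0], ak.ArrheniusParams(-3.0, 0.0))
        gamma = (truth.processes[1], ak.ArrheniusParams(-6.0, 0.0))
        (sp,) = ak.gen_bds_temperature_series(truth, None, [250.0],
                                              secondary=(beta, gamma), seed=seed)
        return sp

    def test_round_trip_two_processes(self):
        fit = ak.fit_secondary_cole_cole(self._two_cc_spectrum())
        assert fit.processes[0].tau_hn == pytest.approx(1e-3, rel=0.05)
        assert fit.processes[1].tau_hn == pytest.approx(1e-6, rel=0.05)
        assert all(p.b == 1.0 for p in fit.processes)

    def test_slow_process_labeled_first(self):
        fit = ak.fit_secondary_cole_cole(self._two_cc_spectrum(noise=0.01, seed=4))
        assert fit.processes[0].tau_hn > fit.processes[1].tau_hn

    def test_single_process_input_flags_degenerate_second(self):
        freq = np.logspace(-1, 6, 57)
        er, ei = ak.hn_eps(freq, [0.5], [1e-3], [0.4], [1.0], eps_inf=3.0)
        sp = ak.DielectricSpectrum(frequency=freq, eps_real=er, eps_imag=ei,
                                   temperature=250.0)
        fit = ak.fit_secondary_cole_cole(sp, n_processes=2)
        assert len(fit.degenerate) == 1


class TestMasterPlot:
    temps = list(range(310, 352, 4))

    def test_recovered_shifts_match_vft_truth(self):
        vft = ak.STUDY["vft_neat"]
        series = ak.gen_kww_temperature_series(8.9, 0.60, vft, self.temps)
        master = ak.build_master_plot(series, T_ref=314.0)
        tau_ref = float(vft.tau(314.0))
        for T, s in master.shifts.items():
            assert s == pytest.approx(math.log10(float(vft.tau(T)) / tau_ref),
                                      abs=0.02)

    def test_reference_shift_is_zero(self):
        series = ak.gen_kww_temperature_series(8.9, 0.6, ak.STUDY["vft_neat"],
                                               self.temps)
        master = ak.build_master_plot(series, T_ref=314.0)
        assert master.shifts[314.0] == 0.0

    def test_shape_invariant_series_superimposes(self):
        series = ak.gen_kww_temperature_series(8.9, 0.6, ak.STUDY["vft_neat"],
                                               self.temps)
        master = ak.build_master_plot(series, T_ref=314.0)
        # merged curve must collapse onto a single line: interpolate onto a
        # common grid and check the scatter between neighbouring points
        lx = np.log10(master.freq_reduced)
        ly = np.log10(master.loss_norm)
        scatter = np.abs(np.diff(ly) / np.maximum(np.diff(lx), 1e-9))
        dense = np.diff(lx) < 0.01  # near-duplicate abscissae from merging
        assert np.max(np.abs(np.diff(ly)[dense])) < 0.01


class TestKwwLoss:
    def test_beta_one_is_debye_identically(self):
        x = np.logspace(-3, 3, 61)
        np.testing.assert_allclose(ak.kww_loss(x, 1.0, 1.0), 2 * x / (1 + x**2),
                                   atol=1e-10)

    def test_beta_half_matches_brute_force_quadrature(self):
        # independent oracle: dense trapezoid after the v = (t/tau)^beta
        # substitution, eps'' = int exp(-v) sin(x v^(1/beta)) dv
        v = np.linspace(0.0, 42.0, 2_000_001)
        for x in (1e-2, 0.1, 1.0, 10.0, 100.0):
            oracle = np.trapezoid(np.exp(-v) * np.sin(x * v**2), v)
            assert abs(_kww_loss_raw(x, 0.5) - oracle) < 1e-6

    def test_fwhm_broadens_monotonically_as_beta_drops(self):
        x = np.logspace(-4, 5, 400)
        widths = []
        for beta in (1.0, 0.8, 0.6, 0.45, 0.3):
            y = ak.kww_loss(x, 1.0, beta)
            above = x[y >= 0.5]
            widths.append(math.log10(above.max() / above.min()))
        assert all(w2 > w1 for w1, w2 in zip(widths, widths[1:]))

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValidationError):
            ak.kww_loss(np.array([1.0]), 1.0, 1.5)


class TestFitKww:
    def test_recovers_stretching_exponent(self):
        series = ak.gen_kww_temperature_series(8.9, 0.60, ak.STUDY["vft_neat"],
                                               TestMasterPlot.temps)
        res = ak.fit_kww(ak.build_master_plot(series, T_ref=314.0))
        assert res.beta_kww == pytest.approx(0.60, abs=0.01)

    def test_debye_master_curve_gives_beta_one(self):
        series = ak.gen_kww_temperature_series(8.9, 1.0, ak.STUDY["vft_neat"],
                                               TestMasterPlot.temps)
        res = ak.fit_kww(ak.build_master_plot(series, T_ref=314.0), beta_init=0.9)
        assert res.beta_kww == pytest.approx(1.0, abs=0.01)

    def test_neighbouring_betas_distinguishable_at_one_percent_noise(self):
        for seed in range(3):
            series = ak.gen_kww_temperature_series(
                8.9, 0.60, ak.STUDY["vft_neat"], TestMasterPlot.temps,
                seed=seed, noise_sd=0.01,
            )
            res = ak.fit_kww(ak.build_master_plot(series, T_ref=314.0))
            assert abs(res.beta_kww - 0.60) < abs(res.beta_kww - 0.58)


class TestDielectricStrength:
    def test_recovery_of_tabulated_strength(self, alpha_spectral_truth):
        (sp,) = ak.gen_bds_temperature_series(
            alpha_spectral_truth, None, [330.0],
            secondary=((alpha_spectral_truth.processes[0],
                        ak.ArrheniusParams(-4.0, 0.0)),),
        )
        fit = ak.fit_hn(sp, include_conductivity=True, include_real=True)
        assert ak.dielectric_strength(fit, 0) == pytest.approx(8.9, rel=0.01)

    def test_static_limit_identity(self):
        freq = np.logspace(-1, 6, 57)
        er, ei = ak.hn_eps(freq, [8.9], [1e-4], [0.85], [0.55], eps_inf=3.0)
        sp = ak.DielectricSpectrum(frequency=freq, eps_real=er, eps_imag=ei)
        fit = ak.fit_hn(sp, include_conductivity=False, include_real=True)
        static = sum(p.delta_eps for p in fit.processes) + fit.eps_inf
        assert static == pytest.approx(er[0], rel=5e-3)

    def test_index_out_of_range(self, alpha_spectral_truth):
        freq = np.logspace(-1, 6, 57)
        er, ei = ak.hn_eps(freq, [1.0], [1e-4], [0.8], [0.8], eps_inf=3.0)
        sp = ak.DielectricSpectrum(frequency=freq, eps_real=er, eps_imag=ei)
        fit = ak.fit_hn(sp, include_conductivity=False)
        with pytest.raises(ValidationError):
            ak.dielectric_strength(fit, 5)
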