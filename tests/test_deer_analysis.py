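import numpy as np
import pytest

import deerloop as dl
from deerloop.constants import DIPOLAR_CONSTANT_MHZ_NM3 as D
from deerloop.deer_analysis import (DistanceDistribution, ROI, compute_mnr,
                                    dipolar_frequency_mhz, fit_deer, kernel,
                                    roi_from_distribution, simulate_deer)

R_GRID = np.arange(1.5, 8.0, 0.05)
T_GRID = np.arange(-150.0, 3500.0, 8.0)


def _gaussian_p(mean, sd, r=R_GRID):
    p = np.exp(-0.5 * ((r - mean) / sd) ** 2)
    return p / np.trapezoid(p, r)


class TestKernel:
    def test_unit_value_at_time_zero(self):
        k = kernel(np.array([0.0]), np.array([2.0, 3.5, 6.0]))
        np.testing.assert_allclose(k, 1.0, atol=1e-12)

    def test_fresnel_matches_quadrature(self):
        t = np.linspace(0, 8000.0, 200)
        r = np.array([1.5, 2.5, 4.0, 6.0, 8.0])
        kf = kernel(t, r, method="fresnel")
        kq = kernel(t, r, method="quad")
        assert np.max(np.abs(kf - kq)) < 1e-8

    def test_bounded_oscillation(self):
        k = kernel(np.linspace(0, 10000, 500), np.array([2.0, 5.0]))
        assert np.all(np.abs(k) <= 1.0 + 1e-12)

    def test_even_in_time(self):
        t = np.linspace(-2000, 2000, 401)
        k = kernel(t, np.array([3.0]))
        np.testing.assert_allclose(k, k[::-1], atol=1e-12)

    def test_dominant_frequency_at_3nm(self):
        # the perpendicular dipolar frequency D/r^3 = 52.04/27 = 1.927 MHz
        t = np.arange(0, 16384.0, 8.0)
        k = kernel(t, np.array([3.0]))[:, 0]
        spec = np.abs(np.fft.rfft(k - k.mean()))
        freqs = np.fft.rfftfreq(t.size, d=8e-3)  # MHz
        peak = freqs[int(np.argmax(spec))]
        df = freqs[1] - freqs[0]
        assert abs(peak - D / 27.0) <= df

    def test_invalid_distance(self):
        with pytest.raises(ValueError):
            kernel(np.array([0.0, 8.0]), np.array([-1.0]))


class TestSimulateDeer:
    def test_lambda_zero_is_pure_background(self):
        trace = simulate_deer(T_GRID, R_GRID, _gaussian_p(4.0, 0.4),
                              [(0.0, 0.0)], background_rate=0.08, V0=0.9)
        expected = 0.9 * np.exp(-0.08 * np.abs(T_GRID) * 1e-3)
        np.testing.assert_allclose(trace.V, expected, atol=1e-12)

    def test_narrow_pair_oscillates_at_dipolar_frequency(self):
        p = _gaussian_p(3.0, 0.02)
        t = np.arange(0.0, 16384.0, 8.0)
        trace = simulate_deer(t, R_GRID, p, [(0.5, 0.0)])
        spec = np.abs(np.fft.rfft(trace.V - trace.V.mean()))
        freqs = np.fft.rfftfreq(t.size, d=8e-3)
        assert abs(freqs[int(np.argmax(spec))] - D / 27.0) \
            <= 2 * (freqs[1] - freqs[0])

    def test_secondary_pathway_refocuses_at_its_time(self):
        p = _gaussian_p(4.0, 0.3)
        t2 = 1600.0
        one = simulate_deer(T_GRID, R_GRID, p, [(0.25, 0.0)])
        two = simulate_deer(T_GRID, R_GRID, p, [(0.25, 0.0), (0.1, t2)])
        diff = np.abs(two.V / one.V - (1 - 0.1))
        assert abs(T_GRID[int(np.argmax(diff))] - t2) < 100.0

    def test_deterministic_per_seed(self):
        a = simulate_deer(T_GRID, R_GRID, _gaussian_p(4, 0.4),
                          [(0.3, 0.0)], noise_sigma=0.01, seed=5)
        b = simulate_deer(T_GRID, R_GRID, _gaussian_p(4, 0.4),
                          [(0.3, 0.0)], noise_sigma=0.01, seed=5)
        np.testing.assert_array_equal(a.V, b.V)

    def test_depths_above_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_deer(T_GRID, R_GRID, _gaussian_p(4, 0.4),
                          [(0.7, 0.0), (0.5, 1000.0)])


class TestFitDeer:
    def test_noiseless_single_gaussian_recovery(self):
        trace = simulate_deer(T_GRID, R_GRID, _gaussian_p(4.5, 0.5),
                              [(0.3, 0.0)], background_rate=0.05)
        fit = fit_deer(trace, n_boot=0)
        assert fit.mean_r == pytest.approx(4.5, abs=0.05)
        assert fit.std_r == pytest.approx(0.5, abs=0.1)
        assert fit.lambda_fit[0] == pytest.approx(0.3, abs=0.02)
        assert fit.background_rate == pytest.approx(0.05, abs=0.01)

    def test_self_consistency_noiseless_residual(self):
        rng = np.random.default_rng(17)
        r = np.arange(1.5, 8.0, 0.1)
        for _ in range(10):
            p = _gaussian_p(rng.uniform(3.0, 5.5), rng.uniform(0.3, 0.8),
                            r=r)
            lam = rng.uniform(0.1, 0.5)
            trace = simulate_deer(T_GRID, r, p, [(lam, 0.0)],
                                  background_rate=rng.uniform(0, 0.1))
            # matched distance grid: residual reflects the solver, not
            # discretisation differences between simulation and fit
            fit = fit_deer(trace, n_boot=0, r_nm=r, ftol=1e-14)
            assert fit.residual_rms < 1e-6 * fit.V0

    def test_pure_background_flags_no_modulation(self):
        trace = simulate_deer(T_GRID, R_GRID, _gaussian_p(4, 0.4),
                              [(0.0, 0.0)], background_rate=0.05,
                              noise_sigma=1e-4, seed=0)
        fit = fit_deer(trace, n_boot=0)
        assert max(fit.lambda_fit) < 0.02
        assert "no_modulation" in fit.flags or "flat_P" in fit.flags

    def test_two_pathway_depth_recovery_at_mnr_150(self):
        p = _gaussian_p(4.5, 0.5)
        lam = (0.24, 0.06)
        sigma = 0.24 / 150
        errs = []
        for seed in range(5):
            trace = simulate_deer(T_GRID, R_GRID, p,
                                  [(lam[0], 0.0), (lam[1], 1600.0)],
                                  background_rate=0.05,
                                  noise_sigma=sigma, seed=seed)
            fit = fit_deer(trace, n_boot=0)
            fitted = sorted(fit.lambda_fit, reverse=True)
            errs.append([abs(fitted[0] - lam[0]) / lam[0],
                         abs(fitted[1] - lam[1]) / lam[1]])
        med = np.median(errs, axis=0)
        assert med[0] < 0.2 and med[1] < 0.2

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            fit_deer(dl.DEERTrace(t=np.arange(0, 80, 8.0),
                                  V=np.ones(10)))

    def test_bootstrap_ci_covers_true_mean(self):
        p = _gaussian_p(4.5, 0.5)
        true_mean = np.trapezoid(R_GRID * p, R_GRID)
        hits = 0
        n_rep = 12
        for seed in range(n_rep):
            trace = simulate_deer(T_GRID, R_GRID, p, [(0.3, 0.0)],
                                  background_rate=0.05,
                                  noise_sigma=0.3 / 150, seed=200 + seed)
            fit = fit_deer(trace, n_boot=20, seed=seed)
            lo, hi = fit.mean_ci
            hits += (lo <= true_mean <= hi)
        assert hits >= 0.9 * n_rep


class TestMnr:
    def test_product_identity(self):
        d = DistanceDistribution(r=R_GRID, P=_gaussian_p(4, 0.4),
                                 lambda_fit=[0.3], V0=1.0, sigma=0.01)
        assert compute_mnr(d) == pytest.approx(30.0)

    def test_full_modulation_equals_snr(self):
        d = DistanceDistribution(r=R_GRID, P=_gaussian_p(4, 0.4),
                                 lambda_fit=[1.0], V0=1.0, sigma=0.02)
        assert compute_mnr(d) == pytest.approx(50.0)

    def test_noiseless_flagged_infinite(self):
        d = DistanceDistribution(r=R_GRID, P=_gaussian_p(4, 0.4),
                                 lambda_fit=[0.3], V0=1.0, sigma=0.0)
        assert np.isinf(compute_mnr(d))
        assert "noiseless" in d.flags

    def test_fitted_mnr_matches_nominal(self):
        # nominal lambda = 0.4, SNR = 375 -> MNR 150 within 10%
        p = _gaussian_p(4.0, 0.5)
        mnrs = []
        for seed in range(15):
            trace = simulate_deer(T_GRID, R_GRID, p, [(0.4, 0.0)],
                                  background_rate=0.05,
                                  noise_sigma=1.0 / 375, seed=seed)
            mnrs.append(compute_mnr(fit_deer(trace, n_boot=0)))
        assert np.mean(mnrs) == pytest.approx(150.0, abs=15.0)


class TestRoi:
    def test_exact_gaussian_roi(self):
        d = DistanceDistribution(r=R_GRID, P=_gaussian_p(5.0, 0.8))
        roi = roi_from_distribution(d, alpha=2.0)
        assert roi.low == pytest.approx(3.4, abs=0.01)
        assert roi.high == pytest.approx(6.6, abs=0.01)
        assert not roi.poor_fit

    def test_bimodal_flagged_poor_fit(self):
        p = _gaussian_p(3.0, 0.2) + _gaussian_p(5.5, 0.2)
        p /= np.trapezoid(p, R_GRID)
        roi = roi_from_distribution(DistanceDistribution(r=R_GRID, P=p))
        assert R_GRID[0] < roi.mean < R_GRID[-1]
        assert 3.0 < roi.mean < 5.5
        assert roi.poor_fit

    def test_zero_alpha_rejected(self):
        d = DistanceDistribution(r=R_GRID, P=_gaussian_p(5.0, 0.8))
        with pytest.raises(ValueError):
            roi_from_distribution(d, alpha=0.0)

    def test_degenerate_single_bin(self):
        p = np.zeros_like(R_GRID)
        p[40] = 1.0
        with pytest.warns(UserWarning, match="degenerate"):
            roi = roi_from_distribution(
                DistanceDistribution(r=R_GRID, P=p))
        assert roi.high - roi.low == pytest.approx(R_GRID[1] - R_GRID[0])

    def test_roi_invariants(self):
        roi = ROI(mean=4.0, sigma=0.5, low=3.0, high=5.0, alpha=2.0)
        assert roi.low < roi.high
        with pytest.raises(ValueError):
            ROI(mean=4.0, sigma=0.5, low=5.0, high=3.0, alpha=2.0)


def test_distribution_io_round_trip(tmp_path):
    d = DistanceDistribution(r=R_GRID, P=_gaussian_p(4.2, 0.5),
                             lambda_fit=[0.3], V0=1.0, sigma=0.01)
    d.write(str(tmp_path / "dist"))
    data = np.loadtxt(tmp_path / "dist.txt")
    np.testing.assert_allclose(data[:, 0], R_GRID)
    np.testing.assert_allclose(data[:, 1], d.P)


def test_mean_dipolar_frequency():
    d = DistanceDistribution(r=R_GRID, P=_gaussian_p(3.0, 0.05))
    assert d.mean_dipolar_frequency_mhz() == pytest.approx(
        dipolar_frequency_mhz(3.0), rel=0.01)
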