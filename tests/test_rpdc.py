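"""MVAR fitting, renormalized PDC, bootstrap, and time-reversal tests."""

import numpy as np
import pytest

from bsnet import rpdc


def simulate_var(coeffs, sigma, n, seed, warmup=200):
    model = rpdc.MVARModel(coeffs.shape[0], coeffs, sigma, 0, 32.0)
    return model.simulate(n, np.random.default_rng(seed), warmup)


@pytest.fixture(scope="module")
def var2_truth():
    a = np.zeros((2, 3, 3))
    a[0] = 0.4 * np.eye(3)
    a[0, 1, 0] = 0.4
    a[1, 2, 1] = 0.3
    return a


class TestFit:
    def test_known_var2_coefficients_recovered(self, var2_truth):
        x = simulate_var(var2_truth, np.eye(3), 1920, seed=0)
        m = rpdc.fit_mvar(x)
        assert m.order >= 2
        rmse = np.sqrt(np.mean((m.coeffs[:2] - var2_truth) ** 2))
        assert rmse <= 0.05

    def test_statsmodels_cross_check(self, var2_truth):
        """Independent oracle: statsmodels' VAR fit at the same fixed order."""
        from statsmodels.tsa.api import VAR

        x = simulate_var(var2_truth, np.eye(3), 1500, seed=1)
        x = x - x.mean(axis=1, keepdims=True)  # both fits on demeaned data
        ours = rpdc.fit_mvar(x, order=2)
        sm = VAR(x.T).fit(maxlags=2, trend="n")
        assert np.allclose(ours.coeffs, sm.coefs, atol=1e-8)
        assert np.allclose(ours.sigma, sm.sigma_u, rtol=1e-6)

    def test_white_noise_selects_trivial_model(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((3, 2000))
        m = rpdc.fit_mvar(x)
        if m.order > 0:
            assert np.max(np.abs(m.coeffs)) < 0.1  # ~3 standard errors at n=2000
        else:
            assert m.order == 0

    def test_self_consistency_refit(self, var2_truth):
        x = simulate_var(var2_truth, np.eye(3), 4000, seed=4)
        m1 = rpdc.fit_mvar(x, order=2)
        x2 = m1.simulate(4000, np.random.default_rng(5))
        m2 = rpdc.fit_mvar(x2, order=2)
        assert np.sqrt(np.mean((m2.coeffs - m1.coeffs) ** 2)) < 0.05

    def test_short_data_rejected_or_capped(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((4, 60))
        m = rpdc.fit_mvar(x, max_order=20)
        assert m.order <= 60 // 40 + 1  # order budget shrinks with n


class TestRPDC:
    def test_directed_pair_detected_not_reversed(self):
        a = np.zeros((1, 2, 2))
        a[0] = [[0.5, 0.0], [0.6, 0.4]]
        x = simulate_var(a, 0.25 * np.eye(2), 1920, seed=7)
        spec = rpdc.compute_rpdc(rpdc.fit_mvar(x, order=2))
        lam = spec.band_mean()
        assert lam[1, 0] > spec.chi2_pair_threshold(1, 0)
        assert lam[0, 1] < spec.chi2_pair_threshold(0, 1)

    def test_channel_relabeling_equivariance(self, var2_truth):
        x = simulate_var(var2_truth, np.eye(3), 1500, seed=8)
        perm = [2, 0, 1]
        lam = rpdc.compute_rpdc(rpdc.fit_mvar(x, order=2)).band_mean()
        lam_p = rpdc.compute_rpdc(rpdc.fit_mvar(x[perm], order=2)).band_mean()
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert lam_p[i, j] == pytest.approx(
                        lam[perm[i], perm[j]], rel=1e-8)

    def test_type_i_error_calibrated(self):
        """Pointwise chi2 threshold at alpha=0.01 over independent noise.

        Smaller replicate count than the full calibration; the acceptance
        suite runs the 200-replicate version.
        """
        rng = np.random.default_rng(9)
        exceed = total = 0
        for _ in range(50):
            x = rng.standard_normal((5, 1920))
            spec = rpdc.compute_rpdc(rpdc.fit_mvar(x, order=3))
            off = ~np.eye(5, dtype=bool)
            exceed += np.sum(spec.values[:, off] > spec.chi2_threshold)
            total += spec.values[:, off].size
        assert 0.001 <= exceed / total <= 0.04

    def test_order_zero_model_rejected(self):
        rng = np.random.default_rng(10)
        m = rpdc.fit_mvar(rng.standard_normal((2, 500)), order=1)
        m.order = 0
        m.coeffs = np.zeros((0, 2, 2))
        with pytest.raises(ValueError):
            rpdc.compute_rpdc(m)


class TestBootstrap:
    def test_fixed_seed_reproducible(self, var2_truth):
        x = simulate_var(var2_truth, np.eye(3), 1920, seed=11)
        n1 = rpdc.bootstrap_threshold(x, n_boot=100, seed=12)
        n2 = rpdc.bootstrap_threshold(x, n_boot=100, seed=12)
        assert np.array_equal(n1.thresholds, n2.thresholds, equal_nan=True)

    def test_coupled_pair_exceeds_threshold(self):
        a = np.zeros((1, 2, 2))
        a[0] = [[0.5, 0.0], [0.6, 0.4]]
        x = simulate_var(a, 0.25 * np.eye(2), 1920, seed=13)
        null = rpdc.bootstrap_threshold(x, n_boot=100, seed=14, order=2)
        lam = rpdc.compute_rpdc(rpdc.fit_mvar(x, order=2)).band_mean()
        assert lam[1, 0] > null.thresholds[1, 0]

    def test_independent_noise_stays_below_threshold(self):
        ok = n_pairs = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            x = rng.standard_normal((3, 1920))
            null = rpdc.bootstrap_threshold(x, n_boot=100, seed=seed, order=2)
            lam = rpdc.compute_rpdc(rpdc.fit_mvar(x, order=2)).band_mean()
            off = ~np.eye(3, dtype=bool)
            ok += np.sum(lam[off] <= null.thresholds[off])
            n_pairs += off.sum()
        assert ok / n_pairs >= 0.95

    def test_too_few_resamples_rejected(self, var2_truth):
        x = simulate_var(var2_truth, np.eye(3), 1000, seed=15)
        with pytest.raises(ValueError):
            rpdc.bootstrap_threshold(x, n_boot=50)


class TestTimeReversal:
    def test_lagged_causal_pair_confirmed(self):
        a = np.zeros((1, 2, 2))
        a[0] = [[0.5, 0.0], [0.6, 0.4]]
        x = simulate_var(a, 0.25 * np.eye(2), 3000, seed=16)
        dec = rpdc.decide_edges(x, n_boot=100, seed=17)
        by_pair = {(d.source, d.target): d for d in dec}
        assert by_pair[(0, 1)].accepted
        assert by_pair[(0, 1)].trt_verdict == "strong_asymmetry_confirmed"
        assert not by_pair[(1, 0)].accepted

    def test_zero_lag_mixture_rejected(self):
        from scipy.signal import butter, sosfiltfilt

        rng = np.random.default_rng(18)
        sos = butter(2, [1 / 16, 4 / 16], "bandpass", output="sos")
        z = sosfiltfilt(sos, rng.standard_normal(4000))
        mix = np.vstack([z + 0.1 * rng.standard_normal(4000),
                         0.8 * z + 0.1 * rng.standard_normal(4000)])
        dec = rpdc.decide_edges(mix, n_boot=100, seed=19)
        assert not any(d.accepted for d in dec)

    def test_symmetric_coupling_rarely_yields_directed_edges(self):
        a = np.zeros((1, 2, 2))
        a[0] = [[0.4, 0.25], [0.25, 0.4]]
        bad = 0
        for seed in range(5):
            x = simulate_var(a, 0.25 * np.eye(2), 1920, seed=40 + seed)
            dec = rpdc.decide_edges(x, n_boot=100, seed=50 + seed)
            bad += any(d.accepted for d in dec)
        # the three-stage rule may pass occasionally on sampling asymmetry
        assert bad <= 2


class TestDecimation:
    def test_decimation_rate_and_antialiasing(self):
        fs = 512.0
        t = np.arange(int(10 * fs)) / fs
        # 5 Hz passes; 40 Hz would alias to 8 Hz without the filter
        x = np.vstack([np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 40 * t)] * 2)
        y = rpdc.decimate_to_model_rate(x, fs, 32.0)
        assert y.shape == (2, 320)
        from scipy.signal import periodogram
        f, p = periodogram(y[0], fs=32.0)
        p5 = p[np.argmin(np.abs(f - 5.0))]
        p8 = p[np.argmin(np.abs(f - 8.0))]
        assert p5 > 100 * p8

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            rpdc.decimate_to_model_rate(np.zeros((2, 100)), 100.0, 32.0)
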