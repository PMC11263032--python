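import numpy as np
import pytest

from ictalcycles.cycles import (clean_series, detect_cycle, fit_red_noise,
                                mc_pvalue, periodogram)
from ictalcycles.synth import generate_hourly_red_noise


class TestCleanSeries:
    def test_spike_replaced_by_neighbour_interpolation(self, rng):
        v = rng.standard_normal(100) * 0.1
        v[50] = 10.0
        out = clean_series(v)
        assert out[50] == pytest.approx((v[49] + v[51]) / 2, abs=1e-9)

    def test_clean_series_identity(self, rng):
        v = rng.standard_normal(100)
        v = np.clip(v, -2.5, 2.5)  # keep everything under 3 sigma
        np.testing.assert_allclose(clean_series(v), v)

    def test_gap_linear_interpolation(self):
        v = np.sin(np.arange(100) / 5.0)
        v[10], v[14] = 1.0, 5.0
        v[11:14] = np.nan
        out = clean_series(v, z_thresh=np.inf)
        np.testing.assert_allclose(out[11:14], [2.0, 3.0, 4.0])

    def test_rejects_mostly_missing(self):
        v = np.full(100, np.nan)
        v[:40] = 1.0
        with pytest.raises(ValueError, match="missing"):
            clean_series(v)

    def test_rejects_short_series(self):
        with pytest.raises(ValueError, match="48"):
            clean_series(np.ones(30))


class TestPeriodogram:
    def test_24h_sinusoid_peaks_at_24h_bin(self):
        t = np.arange(336)
        f, p = periodogram(np.cos(2 * np.pi * t / 24))
        assert f[np.argmax(p)] == pytest.approx(1 / 24, abs=1e-12)

    def test_12h_sinusoid_peaks_at_12h_not_24h(self):
        t = np.arange(336)
        f, p = periodogram(np.cos(2 * np.pi * t / 12))
        assert f[np.argmax(p)] == pytest.approx(1 / 12, abs=1e-12)

    def test_white_noise_spectrum_flat_on_average(self, rng):
        acc = None
        for _ in range(300):
            f, p = periodogram(rng.standard_normal(336))
            acc = p if acc is None else acc + p
        acc /= 300
        mid = acc[1:-1]
        assert mid.max() / mid.min() < 1.35


class TestRedNoiseFit:
    def test_exact_power_law_recovery(self):
        f = np.fft.rfftfreq(96)[1:]
        p = 2.0 / f**1.5
        alpha, scale, rv = fit_red_noise(f, p)
        assert alpha == pytest.approx(1.5, abs=1e-6)
        assert rv == pytest.approx(0.0, abs=1e-12)

    def test_white_noise_alpha_near_zero(self, rng):
        alphas = []
        for _ in range(100):
            f, p = periodogram(rng.standard_normal(336))
            alphas.append(fit_red_noise(f, p)[0])
        assert np.mean(alphas) == pytest.approx(0.0, abs=0.1)

    def test_24h_spike_excluded_from_fit(self):
        f = np.fft.rfftfreq(96)[1:]
        p = 1.0 / f**1.0
        p_spiked = p.copy()
        p_spiked[np.argmin(np.abs(f - 1 / 24))] *= 100
        assert fit_red_noise(f, p) == pytest.approx(fit_red_noise(f, p_spiked))


class TestMCPvalue:
    def test_far_above_null_hits_addone_floor(self):
        f = np.fft.rfftfreq(96)[1:]
        p = np.ones_like(f)
        b = np.argmin(np.abs(f - 1 / 24))
        p[b] = 1e12
        pv = mc_pvalue(f, p, alpha_hat=0.0, noise_scale=0.0, resid_var=0.04,
                       n_sim=10_000, rng=0)
        assert pv == pytest.approx(1 / 10_001, abs=1e-9)

    def test_null_median_gives_half(self):
        f = np.fft.rfftfreq(96)[1:]
        p = np.ones_like(f)  # observed log-power 0 = null mean everywhere
        pv = mc_pvalue(f, p, alpha_hat=0.0, noise_scale=0.0, resid_var=0.04,
                       n_sim=20_000, rng=1)
        assert pv == pytest.approx(0.5, abs=0.02)

    def test_monotone_in_observed_power(self):
        f = np.fft.rfftfreq(96)[1:]
        b = np.argmin(np.abs(f - 1 / 24))
        pvs = []
        for boost in (1.0, 3.0, 10.0, 100.0):
            p = np.ones_like(f)
            p[b] = boost
            pvs.append(mc_pvalue(f, p, 0.0, 0.0, 1.0, n_sim=5000, rng=7))
        assert all(a >= b_ for a, b_ in zip(pvs, pvs[1:]))

    def test_rejects_tiny_n_sim(self):
        f = np.fft.rfftfreq(96)[1:]
        with pytest.raises(ValueError, match="n_sim"):
            mc_pvalue(f, np.ones_like(f), 0.0, 0.0, 1.0, n_sim=50)


class TestDetectCycle:
    def test_deterministic_per_seed(self, rng):
        s = generate_hourly_red_noise(336, 1.0, rng)
        r1 = detect_cycle(s, n_sim=1000, rng=5)
        r2 = detect_cycle(s, n_sim=1000, rng=5)
        assert r1.p24 == r2.p24

    def test_planted_24h_cycle_detected(self, rng):
        t = np.arange(336)
        s = np.cos(2 * np.pi * t / 24) + 0.3 * rng.standard_normal(336)
        r = detect_cycle(s, n_sim=2000, rng=3)
        assert r.significant and r.p24 < 0.01

    def test_12h_machinery(self, rng):
        t = np.arange(336)
        s = np.cos(2 * np.pi * t / 12) + 0.3 * rng.standard_normal(336)
        assert detect_cycle(s, n_sim=2000, rng=4, period_h=12.0).significant

    def test_degenerate_series_not_significant(self):
        r = detect_cycle(np.zeros(336))
        assert r.degenerate and r.p24 == 1.0 and not r.significant

    def test_null_calibration_small(self, rng):
        """Type-I error near nominal 0.05 on pure red noise (48 runs here;
        the full 200-series calibration lives in the acceptance suite)."""
        hits = sum(detect_cycle(generate_hourly_red_noise(336, 1.0, rng),
                                n_sim=500, rng=rng).significant
                   for _ in range(48))
        assert hits / 48 <= 0.15
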