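import numpy as np
import pytest
from scipy import signal as sps
from scipy.special import i0, i1
from scipy.stats import poisson

from ictalcycles.cycles import detect_cycle
from ictalcycles.metrics import variance_metric
from ictalcycles.phase import plv
from ictalcycles.synth import (SyntheticConfig, apply_circadian_modulation,
                               colored_spectrum_amplitudes, generate_background,
                               ied_template, inject_ieds, sample_seizure_times,
                               simulate_patient_windows, simulate_recording,
                               variance_draws)


class TestBackground:
    def test_white_noise_variance_near_target(self):
        x = generate_background(4, 256.0, 600.0, 0.0, 0, variance=2.0)
        assert x.var(axis=-1, ddof=1) == pytest.approx(2.0, rel=0.05)

    def test_one_over_f_slope(self):
        x = generate_background(64, 256.0, 60.0, 1.0, 3)
        f, p = sps.welch(x, fs=256.0, nperseg=1024, axis=-1)
        pm = p.mean(axis=0)
        sel = (f >= 1) & (f <= 50)
        slope = np.polyfit(np.log10(f[sel]), np.log10(pm[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_deterministic_per_seed(self):
        a = generate_background(2, 256.0, 10.0, 1.0, 99)
        b = generate_background(2, 256.0, 10.0, 1.0, 99)
        np.testing.assert_array_equal(a, b)

    def test_zero_mean(self):
        x = generate_background(2, 256.0, 60.0, 1.5, 1)
        assert np.abs(x.mean(axis=-1)).max() < 1e-12

    def test_rejects_bad_args(self):
        with pytest.raises(ValueError, match="positive"):
            generate_background(1, 256.0, -5.0, 1.0, 0)


class TestCircadianModulation:
    def test_depth_zero_is_identity(self, rng):
        x = rng.standard_normal((2, 1000))
        np.testing.assert_array_equal(apply_circadian_modulation(x, 256.0, 0.0), x)

    def test_hourly_variance_ratio(self, rng):
        """depth 0.5 -> max/min hourly variance ratio (1.5/0.5)^2 = 9."""
        fs = 16.0
        x = rng.standard_normal((1, int(24 * 3600 * fs)))
        y = apply_circadian_modulation(x, fs, 0.5, phase=0.0)
        hv = [np.var(y[0, int(h * 3600 * fs):int((h + 1) * 3600 * fs)])
              for h in range(24)]
        assert max(hv) / min(hv) == pytest.approx(9.0, rel=0.2)
        assert np.argmax(hv) in (0, 23)  # peak at the hour containing phase 0

    def test_planted_cycle_detected_in_hourly_variance(self, rng):
        fs = 8.0
        x = rng.standard_normal((1, int(14 * 24 * 3600 * fs)))
        y = apply_circadian_modulation(x, fs, 0.5)
        hv = np.array([np.var(y[0, int(h * 3600 * fs):int((h + 1) * 3600 * fs)])
                       for h in range(14 * 24)])
        assert detect_cycle(hv, n_sim=1000, rng=1).significant

    def test_rejects_bad_depth(self, rng):
        with pytest.raises(ValueError, match="depth"):
            apply_circadian_modulation(rng.standard_normal(10), 256.0, 1.5)


class TestInjectIEDs:
    def test_zero_rate_no_events(self, rng):
        x = rng.standard_normal((1, 200 * 60))
        y, ev = inject_ieds(x, 200.0, [0], 0.0, ied_template(200.0), rng)
        np.testing.assert_array_equal(x, y)
        assert len(ev[0]) == 0

    def test_poisson_count_within_99_interval(self):
        counts = []
        for s in range(20):
            x = np.zeros((1, 200 * 3600))
            _, ev = inject_ieds(x, 200.0, [0], 2.0, ied_template(200.0), s)
            counts.append(len(ev[0]))
        lo, hi = poisson.ppf([0.005, 0.995], 120)
        assert lo <= np.mean(counts) <= hi

    def test_template_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="template"):
            inject_ieds(np.zeros((1, 10)), 200.0, [0], 1.0, np.ones(100), 0)

    def test_event_times_match_added_peaks(self, rng):
        x = np.zeros((1, 200 * 120))
        tpl = ied_template(200.0, amplitude=5.0)
        y, ev = inject_ieds(x, 200.0, [0], 1.0, tpl, rng)
        for t in ev[0]:
            assert y[0, int(round(t * 200))] == pytest.approx(5.0, rel=0.05)


class TestSeizureSampling:
    def test_degenerate_kappa_gives_plv_one(self):
        _, ph = sample_seizure_times(50, 1.0, 1e6, 24.0, 10, 0)
        assert plv(ph) == pytest.approx(1.0, abs=1e-3)

    def test_uniform_kappa_zero_plv_small(self):
        _, ph = sample_seizure_times(1000, 0.0, 0.0, 24.0, 10, 1)
        assert plv(ph) <= 0.08

    def test_kappa_two_matches_bessel_ratio(self):
        _, ph = sample_seizure_times(500, 0.3, 2.0, 24.0, 10, 2)
        assert plv(ph) == pytest.approx(i1(2) / i0(2), abs=0.05)

    def test_onsets_inside_span_and_sorted(self):
        iv, _ = sample_seizure_times(30, 0.0, 1.0, 24.0, 7, 3)
        assert (iv[:, 0] >= 0).all() and (iv[:, 1] <= 7 * 86400).all()
        assert (np.diff(iv[:, 0]) >= 0).all()


class TestVarianceDraws:
    def test_parseval_identity_matches_time_domain(self, rng):
        """The spectral shortcut equals variance_metric of the explicit
        irfft window built from the same spectrum coefficients."""
        n, fs = 512, 256.0
        amp = colored_spectrum_amplitudes(n, fs, 1.5)
        a = rng.standard_normal(len(amp))
        b = rng.standard_normal(len(amp))
        spec = amp * (a + 1j * b)
        spec[0] = 0.0
        spec[-1] = amp[-1] * np.sqrt(2.0) * a[-1]
        x = np.fft.irfft(spec, n)
        direct = variance_metric(x)[0]
        e = (a[1:-1] ** 2 + b[1:-1] ** 2) / 2.0
        shortcut = (4.0 * (e @ amp[1:-1] ** 2)
                    + amp[-1] ** 2 * 2.0 * a[-1] ** 2) / (n * (n - 1))
        assert shortcut == pytest.approx(direct, rel=1e-9)

    def test_unit_mean_and_determinism(self):
        amp = colored_spectrum_amplitudes(2048, 256.0, 1.0)
        v1 = variance_draws(4000, amp, 2048, np.random.default_rng(0))
        v2 = variance_draws(4000, amp, 2048, np.random.default_rng(0))
        np.testing.assert_array_equal(v1, v2)
        assert v1.mean() == pytest.approx(1.0, rel=0.05)


class TestConfig:
    @pytest.mark.parametrize("kw", [dict(circadian_depth=1.5), dict(fs=300),
                                    dict(seizure_phase_kappa=-1),
                                    dict(n_patients=0)])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SyntheticConfig(**kw)


class TestSimulated:
    def test_recording_determinism(self):
        cfg = SyntheticConfig(n_channels=3, seed=5)
        r1, t1 = simulate_recording(cfg, duration_s=600.0)
        r2, t2 = simulate_recording(cfg, duration_s=600.0)
        np.testing.assert_array_equal(r1.signal, r2.signal)
        np.testing.assert_array_equal(t1.seizure_phases, t2.seizure_phases)

    def test_patient_windows_determinism_and_shapes(self):
        cfg = SyntheticConfig(n_channels=2, n_days=3, windows_per_hour=2, seed=9)
        a = simulate_patient_windows(cfg, 0, metrics=("VM", "IEDF"))
        b = simulate_patient_windows(cfg, 0, metrics=("VM", "IEDF"))
        np.testing.assert_array_equal(a.values["VM"], b.values["VM"])
        assert a.values["VM"].shape == (3 * 24 * 2, 2)
        assert a.values["IEDF"][:, ~a.soz_mask].sum() == 0  # SOZ-only discharges

    def test_metric_selectivity(self):
        """Variance modulation alone drives VM cycles but not NS on
        independent channels."""
        cfg = SyntheticConfig(n_channels=4, n_days=14, windows_per_hour=2,
                              circadian_depth=0.5, coupling_depth=0.0,
                              ied_rate_depth=0.0, seed=31)
        pw = simulate_patient_windows(cfg, 0, metrics=("VM", "NS"), ns_samples=64)
        from ictalcycles.pipeline import patient_cycle, patient_hourly

        assert patient_cycle(patient_hourly(pw, "VM"), n_sim=1000, rng=1).significant
        assert not patient_cycle(patient_hourly(pw, "NS"), n_sim=1000, rng=2).significant
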