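import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ictalcycles.metrics import (acf, aggregate_hourly, build_window_grid,
                                 classify_candidates, count_ieds,
                                 detect_ied_candidates, distance_band_pairs,
                                 iedf_metric, kuramoto_order, ns_metric,
                                 scm_metric, sharpness_classifier, tcm_metric,
                                 variance_metric)
from ictalcycles.synth import ar1_frames, generate_background, ied_template

HOUR = np.array([[0.0, 3600.0]])


class TestWindowGrid:
    def test_no_seizures_thirty_windows(self):
        g = build_window_grid(HOUR, np.empty((0, 2)))
        assert len(g.windows) == 30 and not g.excluded.any()

    def test_exclusion_arithmetic(self):
        """Seizure 30:00-31:00 with +-5 min margin excludes exactly the 6
        windows starting 24:00 through 34:00."""
        g = build_window_grid(HOUR, np.array([[1800.0, 1860.0]]))
        assert g.excluded.sum() == 6
        np.testing.assert_array_equal(
            g.windows[g.excluded, 0], [1440, 1560, 1680, 1800, 1920, 2040])

    def test_seizure_spanning_hour_excludes_all(self):
        g = build_window_grid(HOUR, np.array([[0.0, 3600.0]]))
        assert g.excluded.all()


class TestVariance:
    def test_textbook_value(self):
        assert variance_metric([1, 2, 3, 4, 5])[0] == 2.5

    def test_constant_window_is_zero(self):
        assert variance_metric(np.ones(100))[0] == 0.0

    def test_unit_gaussian_at_window_size(self, rng):
        v = variance_metric(rng.standard_normal(30720))
        assert v[0] == pytest.approx(1.0, abs=0.02)

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            variance_metric([1.0])


class TestTCM:
    @pytest.mark.parametrize("phi,expected,tol", [
        (0.5, 0.125, 0.02),
        (0.8, 0.125 * np.log(0.5) / np.log(0.8), 0.05),
    ])
    def test_ar1_closed_form(self, phi, expected, tol, rng):
        """AR(1) frames have ACF phi^k, so the half-decay lag is
        0.125 * ln(0.5)/ln(phi) seconds."""
        vals = tcm_metric(ar1_frames(np.full(100, phi), 960, rng))
        assert vals.mean() == pytest.approx(expected, abs=tol)

    def test_white_noise_interpolates_to_half_frame(self, rng):
        vals = tcm_metric(rng.standard_normal((200, 960)))
        assert vals.mean() == pytest.approx(0.0625, abs=0.005)

    def test_never_crossing_flagged(self, rng):
        """A near-unit-root series whose ACF stays above 0.5 over the
        searched lag range is flagged and pinned to the range span."""
        x = ar1_frames(np.full(1, 0.999), 960, rng)
        vals, flags = tcm_metric(x, return_flags=True, max_lag=8)
        assert flags[0] and vals[0] == pytest.approx(9 * 0.125)

    def test_scale_and_offset_invariant(self, rng):
        x = ar1_frames(np.full(5, 0.6), 960, rng)
        np.testing.assert_allclose(tcm_metric(x), tcm_metric(3.0 * x + 10.0),
                                   atol=1e-12)


class TestNS:
    def test_identical_channels_give_one(self):
        t = np.arange(2560) / 256.0
        x = np.tile(np.sin(2 * np.pi * 70 * t), (8, 1))
        assert ns_metric(x) == pytest.approx(1.0, abs=1e-6)

    def test_equally_spaced_phases_give_zero(self):
        ph = np.tile(np.arange(8)[:, None] * 2 * np.pi / 8, (1, 50))
        assert kuramoto_order(ph).mean() == pytest.approx(0.0, abs=1e-9)

    def test_two_channels_quarter_cycle(self):
        ph = np.array([[0.0], [np.pi / 2]])
        assert kuramoto_order(ph)[0] == pytest.approx(np.sqrt(2) / 2, abs=1e-12)

    def test_literal_re_differs_for_common_phase(self):
        ph = np.full((4, 10), 2.0)
        assert kuramoto_order(ph).mean() == pytest.approx(1.0)
        assert kuramoto_order(ph, literal_re=True).mean() == pytest.approx(np.cos(2.0))

    def test_rejects_single_channel(self):
        with pytest.raises(ValueError):
            ns_metric(np.zeros((1, 100)))

    def test_rescaling_invariance(self, rng):
        x = rng.standard_normal((4, 2000))
        assert ns_metric(x) == pytest.approx(ns_metric(x * [[1], [5], [0.1], [100.0]]),
                                             abs=1e-9)


class TestSCM:
    def test_identical_channels_give_one(self, rng):
        x = np.tile(rng.standard_normal(960), (4, 1))
        xyz = np.array([[0, 0, 0], [20, 0, 0], [0, 40, 0], [30, 30, 0]], float)
        assert scm_metric(x, xyz) == pytest.approx(1.0)

    def test_independent_channels_near_zero(self, rng):
        xyz = np.arange(10)[:, None] * [12.0, 0, 0]
        vals = [scm_metric(rng.standard_normal((10, 960)), xyz) for _ in range(5)]
        assert abs(np.mean(vals)) <= 0.05

    def test_distance_band_filter(self):
        xyz = np.array([[0, 0, 0], [5, 0, 0], [100, 0, 0], [140, 0, 0]], float)
        np.testing.assert_array_equal(distance_band_pairs(xyz), [[2, 3]])

    def test_no_pair_in_band_gives_nan(self, rng):
        xyz = np.array([[0, 0, 0], [5, 0, 0]], float)
        assert np.isnan(scm_metric(rng.standard_normal((2, 960)), xyz))


class TestIED:
    def test_flat_signal_no_events(self):
        assert count_ieds(np.zeros((1, 24000)), 200.0)[0] == 0

    def test_single_spike_recovered_within_50ms(self):
        rng = np.random.default_rng(11)
        bg = generate_background(1, 200.0, 120, 1.5, rng)[0]
        tpl = ied_template(200.0, amplitude=8 * bg.std())
        x = bg.copy()
        t_true = 60.0 + np.argmax(np.abs(tpl)) / 200.0
        x[int(60 * 200):int(60 * 200) + len(tpl)] += tpl
        cands = detect_ied_candidates(x[None, :], 200.0)
        acc = classify_candidates(x[None, :], 200.0, cands)[0]
        assert len(acc) == 1 and abs(acc[0] - t_true) < 0.05

    def test_ten_spikes_recovered(self):
        rng = np.random.default_rng(42)
        bg = generate_background(1, 200.0, 120, 1.5, rng)[0]
        tpl = ied_template(200.0, amplitude=8 * bg.std())
        x = bg.copy()
        for t in 10 + 11.0 * np.arange(10):
            x[int(t * 200):int(t * 200) + len(tpl)] += tpl
        assert count_ieds(x[None, :], 200.0)[0] == pytest.approx(10, abs=1)

    def test_smooth_bump_rejected(self):
        rng = np.random.default_rng(5)
        bg = generate_background(1, 200.0, 120, 1.5, rng)[0]
        bump = 8 * bg.std() * np.sin(np.pi * np.arange(40) / 40)
        x = bg.copy()
        x[12000:12040] += bump
        assert count_ieds(x[None, :], 200.0)[0] == count_ieds(bg[None, :], 200.0)[0]

    def test_plugin_classifier_contract(self):
        rng = np.random.default_rng(11)
        bg = generate_background(2, 200.0, 120, 1.5, rng)
        tpl = ied_template(200.0, amplitude=8 * bg.std())
        x = bg.copy()
        x[0, 2000:2000 + len(tpl)] += tpl
        always_no = lambda seg, fs, p: False
        assert count_ieds(x, 200.0, classifier=always_no).sum() == 0

    def test_iedf_arithmetic(self):
        soz = np.array([True, True, True, False])
        assert iedf_metric([4, 5, 3, 7], soz) == 2.0
        assert iedf_metric([0, 0, 0, 9], soz) == 0.0
        assert np.isnan(iedf_metric([1, 1], np.array([False, False])))


class TestAggregateHourly:
    def test_means_and_subsets(self):
        g = build_window_grid(HOUR, np.empty((0, 2)))
        hs = aggregate_hourly(np.full(30, 2.0), g)
        assert hs.values[0] == 2.0
        hs = aggregate_hourly(np.tile([1.0, 3.0], 15), g)
        assert hs.values[0] == 2.0
        sub = np.zeros(30, bool)
        sub[[0, 1, 2]] = True
        hs = aggregate_hourly(np.r_[1.0, 3.0, 1.0, np.zeros(27)], g, window_subset=sub)
        assert hs.values[0] == pytest.approx(5 / 3)

    def test_fully_excluded_hour_is_missing(self):
        g = build_window_grid(HOUR, np.array([[0.0, 3600.0]]))
        hs = aggregate_hourly(np.ones(30), g)
        assert hs.missing[0]

    def test_empty_channel_subset_rejected(self):
        g = build_window_grid(HOUR, np.empty((0, 2)))
        with pytest.raises(ValueError, match="channel"):
            aggregate_hourly(np.ones((30, 4)), g, channel_subset=np.zeros(4, bool))


class TestOracleEquivalence:
    """Brute-force reimplementations agree with the pipeline to 1e-9."""

    def test_variance(self, rng):
        x = rng.standard_normal(1000)
        m = x.sum() / len(x)
        brute = sum((xi - m) ** 2 for xi in x) / (len(x) - 1)
        assert variance_metric(x)[0] == pytest.approx(brute, abs=1e-9)

    def test_pearson(self, rng):
        x, y = rng.standard_normal((2, 1000))
        mx, my = x.mean(), y.mean()
        brute = (np.sum((x - mx) * (y - my))
                 / np.sqrt(np.sum((x - mx) ** 2) * np.sum((y - my) ** 2)))
        xyz = np.array([[0, 0, 0], [40, 0, 0]], float)
        assert scm_metric(np.vstack([x, y]), xyz) == pytest.approx(brute, abs=1e-9)

    def test_acf(self, rng):
        x = rng.standard_normal(1000)
        xc = x - x.mean()
        brute = np.array([np.sum(xc[: len(x) - k] * xc[k:]) for k in range(30)])
        brute = brute / brute[0]
        np.testing.assert_allclose(acf(x, max_lag=29)[0], brute, atol=1e-9)

    def test_plv_complex_mean(self, rng):
        from ictalcycles.phase import plv

        ph = rng.uniform(-np.pi, np.pi, 1000)
        re = np.mean([np.cos(p) for p in ph])
        im = np.mean([np.sin(p) for p in ph])
        assert plv(ph) == pytest.approx(np.hypot(re, im), abs=1e-9)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 2**16))
def test_vm_scales_quadratically_ns_invariant(scale, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((3, 512))
    np.testing.assert_allclose(variance_metric(scale * x),
                               scale**2 * variance_metric(x), rtol=1e-9)
    assert ns_metric(scale * x) == pytest.approx(ns_metric(x), abs=1e-9)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 2**16), n_ch=st.integers(2, 6))
def test_kuramoto_bounded(seed, n_ch):
    rng = np.random.default_rng(seed)
    r = kuramoto_order(rng.uniform(-np.pi, np.pi, (n_ch, 64)))
    assert np.all((r >= 0) & (r <= 1 + 1e-12))
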