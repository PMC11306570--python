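"""Pupil cleaning chain: MAD speed filter, gap padding, zero-phase
low-pass, baseline correction and window means."""

import numpy as np
import pytest

from contagionkit import (
    baseline_correct,
    interpolate_and_filter,
    mad_speed_filter,
    remove_gaps,
    trial_window_mean,
)
from contagionkit.pupil import dilation_speed
from tests.conftest import make_trace


class TestMadSpeedFilter:
    def test_constant_trace_untouched(self):
        out = mad_speed_filter(make_trace(np.full(50, 4.0)))
        assert out.mask.all()

    def test_ramp_with_spike_masks_spike_and_neighbours(self):
        # 11-sample ramp with a +1 mm single-sample spike: the two-sided
        # max speed assigns the jump to the spike and both adjacent
        # samples; with MAD = 0 the threshold equals the ramp slope, so
        # exactly those three samples are removed (derived by evaluating
        # d, median and MAD on the fixture by hand).
        x = np.linspace(4.0, 4.1, 11)
        x[5] += 1.0
        out = mad_speed_filter(make_trace(x), k=4.0)
        np.testing.assert_array_equal(np.flatnonzero(~out.mask), [4, 5, 6])

    def test_infinite_k_disables_filter(self):
        rng = np.random.default_rng(0)
        mask = rng.random(100) > 0.2
        trace = make_trace(rng.normal(4, 0.5, 100), mask=mask)
        out = mad_speed_filter(trace, k=np.inf)
        np.testing.assert_array_equal(out.mask, mask)

    def test_too_few_valid_samples_fully_masked_with_warning(self):
        trace = make_trace([4.0, 4.1, 4.2], mask=np.array([1, 0, 1], bool))
        with pytest.warns(UserWarning):
            out = mad_speed_filter(trace)
        assert not out.mask.any()

    def test_removes_all_large_spikes_few_clean_samples(self):
        # spikes of >= 10x noise SD are always removed; the share of
        # clean samples removed stays small (the median+4*MAD rule on a
        # Gaussian max-speed statistic removes ~1.5-2% by construction)
        rng = np.random.default_rng(99)
        clean_removed = []
        for _ in range(5):
            x = 4.0 + rng.normal(0, 0.05, 4000)
            spikes = rng.choice(4000, 10, replace=False)
            x[spikes] += 0.5 * rng.choice([-1, 1], 10)
            out = mad_speed_filter(make_trace(x))
            removed = set(np.flatnonzero(~out.mask))
            assert set(spikes) <= removed
            clean = removed - set(spikes) - set(spikes - 1) - set(spikes + 1)
            clean_removed.append(len(clean) / 4000)
        assert np.mean(clean_removed) < 0.03

    def test_dilation_speed_two_sided_max(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        x = np.array([0.0, 1.0, 1.0, 4.0])
        np.testing.assert_allclose(dilation_speed(t, x), [1.0, 1.0, 3.0, 3.0])


class TestRemoveGaps:
    def test_gap_of_exactly_max_left_alone(self):
        mask = np.ones(40, bool)
        mask[10:20] = False  # exactly 10 samples: interpolable
        out = remove_gaps(make_trace(np.full(40, 4.0), mask=mask))
        np.testing.assert_array_equal(out.mask, mask)

    def test_gap_of_eleven_padded_both_sides(self):
        mask = np.ones(40, bool)
        mask[12:23] = False  # 11 samples -> 11 + 5 + 5 = 21 masked
        out = remove_gaps(make_trace(np.full(40, 4.0), mask=mask))
        assert (~out.mask).sum() == 21
        np.testing.assert_array_equal(np.flatnonzero(~out.mask), np.arange(7, 28))

    def test_gap_at_start_pads_right_only(self):
        mask = np.ones(40, bool)
        mask[:12] = False
        out = remove_gaps(make_trace(np.full(40, 4.0), mask=mask))
        np.testing.assert_array_equal(np.flatnonzero(~out.mask), np.arange(0, 17))


class TestInterpolateAndFilter:
    def test_dc_gain_is_one(self):
        out = interpolate_and_filter(make_trace(np.full(600, 3.0)))
        np.testing.assert_allclose(out.values, 3.0, atol=1e-9)

    @pytest.mark.parametrize(
        "freq,min_gain,max_gain",
        [(1.0, 0.99, 1.01), (20.0, 0.0, 0.01)],
    )
    def test_passband_and_stopband_gain(self, freq, min_gain, max_gain):
        t = np.arange(int(10 * 120)) / 120.0
        x = 4.0 + 0.5 * np.sin(2 * np.pi * freq * t)
        out = interpolate_and_filter(make_trace(x))
        mid = slice(240, -240)  # avoid edge transients
        gain = (out.values[mid].max() - out.values[mid].min()) / 1.0
        assert min_gain <= gain <= max_gain

    def test_zero_lag_preserves_peak_index(self):
        t = np.arange(1200) / 120.0
        x = 4.0 + 0.3 * np.exp(-0.5 * ((t - 5.0) / 0.4) ** 2)
        out = interpolate_and_filter(make_trace(x))
        assert np.argmax(out.values) == np.argmax(x)

    def test_all_invalid_yields_invalid_output(self):
        trace = make_trace(np.full(100, np.nan), mask=np.zeros(100, bool))
        out = interpolate_and_filter(trace)
        assert not out.mask.any()


class TestBaselineAndWindow:
    def test_constant_equal_to_baseline_gives_zeros(self):
        x = np.full(1200, 4.2)
        seg, base = baseline_correct(make_trace(x), trial_onset=5.0)
        assert base == pytest.approx(4.2)
        np.testing.assert_allclose(seg.values, 0.0, atol=1e-12)

    def test_baseline_arithmetic(self):
        t = np.arange(1200) / 120.0
        x = np.where(t < 5.0, 4.2, 4.3)
        seg, base = baseline_correct(make_trace(x), trial_onset=5.0)
        assert base == pytest.approx(4.2)
        np.testing.assert_allclose(seg.values, 0.1, atol=1e-12)

    def test_additive_shift_invariance(self):
        rng = np.random.default_rng(1)
        x = 4.0 + rng.normal(0, 0.1, 1200)
        seg1, _ = baseline_correct(make_trace(x), 5.0)
        seg2, _ = baseline_correct(make_trace(x + 1.7), 5.0)
        np.testing.assert_allclose(seg1.values, seg2.values, atol=1e-12)

    def test_missing_baseline_flags_invalid(self):
        mask = np.ones(1200, bool)
        mask[int(4.0 * 120) : int(5.0 * 120)] = False
        seg, base = baseline_correct(make_trace(np.full(1200, 4.0), mask=mask), 5.0)
        assert np.isnan(base) and not seg.mask.any()

    def test_window_mean_constant_and_ramp(self):
        v = trial_window_mean(make_trace(np.full(360, 0.05)), onset=0.0)
        assert v.window_mean_baselined == pytest.approx(0.05)
        ramp = np.linspace(0, 0.2, 360)  # 0 -> 0.2 over 3 s: mean 0.1
        v = trial_window_mean(make_trace(ramp), onset=0.0)
        assert v.window_mean_baselined == pytest.approx(0.1, abs=1e-3)

    def test_empty_window_invalid(self):
        v = trial_window_mean(make_trace(np.full(10, 1.0)), onset=100.0)
        assert not v.valid and v.reason == "no_data"


def test_chain_idempotent_on_clean_constant_trace():
    trace = make_trace(np.full(1200, 3.5))
    once = interpolate_and_filter(remove_gaps(mad_speed_filter(trace)))
    twice = interpolate_and_filter(remove_gaps(mad_speed_filter(once)))
    np.testing.assert_allclose(once.values, twice.values, atol=1e-10)
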