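"""Pupil-diameter preprocessing.

The cleaning chain follows the order: dilation-speed (MAD) filtering,
gap removal with edge padding, linear interpolation onto a uniform
grid, zero-phase Butterworth low-pass, averaging across eyes, then
per-trial subtractive baseline correction and 0-3 s window means.

The dilation speed at sample *i* is the larger of the absolute slopes
to its two neighbours; samples whose speed exceeds
``median + k * MAD`` (raw MAD, no normal-consistency factor) are
discarded.  Note that a single-sample spike contaminates the slopes of
both adjacent samples, so the rule removes the spike together with its
immediate neighbours by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .core import SampledStream

# a pupil trace is an ordinary sampled stream of diameters (mm)
PupilTrace = SampledStream


@dataclass
class PupilTrialValue:
    trial: int
    baseline_mean: float
    window_mean_baselined: float
    valid: bool = True
    reason: str = ""


def dilation_speed(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Two-sided maximum neighbour slope for each sample."""
    dt = np.diff(t)
    s = np.abs(np.diff(x)) / dt
    d = np.empty_like(x)
    d[0] = s[0]
    d[-1] = s[-1]
    if len(x) > 2:
        d[1:-1] = np.maximum(s[:-1], s[1:])
    return d


def mad_speed_filter(
    trace: PupilTrace, k: float = 4.0, speed_floor: float = 1.0
) -> PupilTrace:
    """Mask samples with dilation speed above ``median + k * MAD``.

    ``speed_floor`` (mm/s) guards the degenerate case of a near-
    noiseless trace, where median and MAD of the speeds collapse to
    ~zero and the relative rule would flag every sample of a smooth
    physiological response: a sample is only removed if its speed also
    exceeds the floor.  Tracker artifacts produce speeds of tens of
    mm/s at 120 Hz, far above both the floor and any realistic
    dilation velocity, so the floor never shelters them.

    With fewer than 3 valid samples the trace is returned fully masked
    with a warning.  ``k = inf`` disables the filter.
    """
    out = trace.copy()
    if not np.isfinite(k):
        return out
    tv, xv = trace.valid()
    if len(tv) < 3:
        warnings.warn("mad_speed_filter: fewer than 3 valid samples", stacklevel=2)
        out.mask[:] = False
        return out
    d = dilation_speed(tv, xv)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    bad = (d > med + k * mad) & (d > speed_floor)
    idx = np.flatnonzero(trace.mask)
    out.mask[idx[bad]] = False
    return out


def _invalid_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of consecutive invalid samples."""
    padded = np.r_[True, mask, True]
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts = edges[::2]
    stops = edges[1::2]
    return list(zip(starts.tolist(), stops.tolist()))


def remove_gaps(
    trace: PupilTrace, max_gap_samples: int = 10, pad_samples: int = 5
) -> PupilTrace:
    """Pad long missing runs: for every run of strictly more than
    ``max_gap_samples`` consecutive invalid samples, additionally mask
    ``pad_samples`` samples on each side.  Shorter gaps are left to be
    bridged by interpolation.
    """
    out = trace.copy()
    for start, stop in _invalid_runs(trace.mask):
        if stop - start > max_gap_samples:
            out.mask[max(0, start - pad_samples) : start] = False
            out.mask[stop : stop + pad_samples] = False
    return out


def interpolate_and_filter(
    trace: PupilTrace,
    rate_hz: float = 120.0,
    cutoff_hz: float = 4.0,
    order: int = 4,
) -> PupilTrace:
    """Linear interpolation onto a uniform grid followed by a
    forward-backward (zero-phase) Butterworth low-pass.

    ``order`` is the design order of the single-pass filter; the
    two-pass magnitude response is effectively of twice that order.
    Returns a fully valid trace on the grid; an all-invalid input
    yields an all-masked output.
    """
    grid = uniform_grid(trace.t, rate_hz)
    tv, xv = trace.valid()
    if len(tv) < 2:
        return PupilTrace(grid, np.full(len(grid), np.nan), np.zeros(len(grid), bool))
    x = np.interp(grid, tv, xv)
    b, a = butter(order, cutoff_hz, btype="lowpass", fs=rate_hz)
    y = filtfilt(b, a, x)
    return PupilTrace(grid, y, np.ones(len(grid), bool))


def uniform_grid(t: np.ndarray, rate_hz: float) -> np.ndarray:
    n = int(np.floor((t[-1] - t[0]) * rate_hz + 1e-9)) + 1
    return t[0] + np.arange(n) / rate_hz


def valid_support(trace: PupilTrace, grid: np.ndarray) -> np.ndarray:
    """Fraction of cleaned-data support at each grid point (0..1),
    obtained by linearly interpolating the validity indicator."""
    if trace.mask.sum() == 0:
        return np.zeros(len(grid))
    return np.interp(grid, trace.t, trace.mask.astype(float), left=0.0, right=0.0)


def baseline_correct(
    trace: PupilTrace,
    trial_onset: float,
    baseline_s: float = 1.0,
    segment_s: tuple[float, float] = (0.0, 6.0),
) -> tuple[PupilTrace, float]:
    """Subtract the pre-onset baseline mean from a trial segment.

    The baseline is the mean of valid samples in
    ``[onset - baseline_s, onset)``.  Returns the corrected segment and
    the baseline mean; if the baseline window holds no valid samples
    the segment is returned fully masked and the mean is NaN.
    """
    base_sel = (trace.t >= trial_onset - baseline_s) & (trace.t < trial_onset) & trace.mask
    seg_sel = (trace.t >= trial_onset + segment_s[0]) & (trace.t < trial_onset + segment_s[1])
    seg = PupilTrace(
        trace.t[seg_sel] - trial_onset, trace.values[seg_sel].copy(), trace.mask[seg_sel].copy()
    )
    if not base_sel.any():
        seg.mask[:] = False
        return seg, float("nan")
    base = float(trace.values[base_sel].mean())
    seg.values -= base
    return seg, base


def trial_window_mean(
    trace: PupilTrace,
    onset: float,
    window_s: tuple[float, float] = (0.0, 3.0),
    trial: int = 0,
    baseline_mean: float = float("nan"),
) -> PupilTrialValue:
    """Mean of the (baselined) trace over the analysis window."""
    sel = (trace.t >= onset + window_s[0]) & (trace.t < onset + window_s[1]) & trace.mask
    if not sel.any():
        return PupilTrialValue(trial, baseline_mean, float("nan"), False, "no_data")
    return PupilTrialValue(trial, baseline_mean, float(trace.values[sel].mean()))


def preprocess_pupil(
    left: PupilTrace,
    right: PupilTrace,
    rate_hz: float = 120.0,
    mad_k: float = 4.0,
    max_gap_samples: int = 10,
    pad_samples: int = 5,
    cutoff_hz: float = 4.0,
    order: int = 4,
    speed_floor: float = 1.0,
) -> tuple[PupilTrace, np.ndarray, dict[str, int]]:
    """Run the full cleaning chain on both eyes and average them.

    Returns the eye-averaged filtered trace on the uniform grid, the
    mean cleaned-data support per grid point (consumed by downstream
    trial-validity rules), and a tally of samples removed per stage.
    """
    traces = []
    supports = []
    grid = None
    counts = {"samples": 0, "missing_input": 0, "masked_mad": 0, "masked_gap": 0}
    for eye in (left, right):
        after_mad = mad_speed_filter(eye, mad_k, speed_floor)
        cleaned = remove_gaps(after_mad, max_gap_samples, pad_samples)
        counts["samples"] += len(eye)
        counts["missing_input"] += len(eye) - eye.n_valid
        counts["masked_mad"] += eye.n_valid - after_mad.n_valid
        counts["masked_gap"] += after_mad.n_valid - cleaned.n_valid
        filt = interpolate_and_filter(cleaned, rate_hz, cutoff_hz, order)
        if grid is None:
            grid = filt.t
        traces.append(filt)
        supports.append(valid_support(cleaned, grid))
    assert grid is not None
    vals = np.vstack([tr.values for tr in traces])
    oks = np.vstack([tr.mask for tr in traces])
    support = np.vstack(supports)
    with np.errstate(invalid="ignore"):
        mean_vals = np.where(
            oks.all(axis=0),
            vals.mean(axis=0),
            np.where(oks[0], vals[0], np.where(oks[1], vals[1], np.nan)),
        )
    mask = oks.any(axis=0)
    mean_support = np.where(
        oks.all(axis=0), support.mean(axis=0), np.where(oks[0], support[0], support[1])
    )
    return PupilTrace(grid, mean_vals, mask), mean_support, counts
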