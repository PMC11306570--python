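"""Heart rate from RR intervals.

RR intervals outside 300-2000 ms are discarded, ectopic beats are
removed with a Malik-style 20% neighbour-difference rule, the
remaining normal-to-normal (NN) intervals are linearly interpolated
onto a uniform 2 Hz grid, and heart rate is 60000 / NN(ms) beats per
minute.  Trial values are plain means over the first 3 s from onset;
no baseline subtraction is applied to heart rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import SampledStream


@dataclass
class RRSeries:
    """Beat timestamps (s) and the RR interval (ms) ending at each beat."""

    t: np.ndarray
    rr: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.rr)
        self.mask = np.asarray(self.mask, dtype=bool)

    def copy(self) -> "RRSeries":
        return RRSeries(self.t.copy(), self.rr.copy(), self.mask.copy())


@dataclass
class HRTrialValue:
    trial: int
    hr_mean_bpm: float
    valid: bool = True
    reason: str = ""


def filter_rr_range(series: RRSeries, lo_ms: float = 300.0, hi_ms: float = 2000.0) -> RRSeries:
    """Mask intervals outside ``[lo_ms, hi_ms]`` (bounds inclusive)."""
    out = series.copy()
    out.mask &= (series.rr >= lo_ms) & (series.rr <= hi_ms)
    return out


def remove_ectopic(series: RRSeries, rel_threshold: float = 0.2) -> RRSeries:
    """Mask intervals deviating from the previous *retained* interval
    by more than ``rel_threshold`` (Malik criterion).

    The scan is sequential: once an interval is rejected, the next one
    is compared against the last accepted interval, so an isolated
    ectopic beat does not cascade into its successors.
    """
    out = series.copy()
    idx = np.flatnonzero(series.mask)
    if len(idx) < 2:
        warnings.warn("remove_ectopic: fewer than 2 valid intervals", stacklevel=2)
        return out
    last = series.rr[idx[0]]
    for i in idx[1:]:
        if abs(series.rr[i] - last) / last > rel_threshold:
            out.mask[i] = False
        else:
            last = series.rr[i]
    return out


def rr_to_hr(
    series: RRSeries, resample_hz: float = 2.0, conversion_constant: float = 60000.0
) -> SampledStream:
    """Interpolate NN intervals onto a uniform grid and convert to bpm.

    The grid starts at the first valid beat time.  Grid samples that
    fall in a stretch where consecutive valid beats are further apart
    than ``max_beat_gap_s`` are produced but masked invalid by
    :func:`nn_support` downstream.  An all-masked series yields an
    empty invalid stream.
    """
    tv = series.t[series.mask]
    nn = series.rr[series.mask]
    if len(tv) < 2:
        return SampledStream(np.array([0.0]), np.array([np.nan]), np.array([False]))
    n = int(np.floor((tv[-1] - tv[0]) * resample_hz)) + 1
    grid = tv[0] + np.arange(n) / resample_hz
    nn_grid = np.interp(grid, tv, nn)
    hr = conversion_constant / nn_grid
    return SampledStream(grid, hr, np.ones(n, dtype=bool))


def nn_support(series: RRSeries, grid: np.ndarray, max_beat_gap_s: float = 3.0) -> np.ndarray:
    """True where a grid time is bracketed by valid beats no more than
    ``max_beat_gap_s`` apart; interpolation across longer dropouts is
    not trusted."""
    tv = series.t[series.mask]
    if len(tv) < 2:
        return np.zeros(len(grid), dtype=bool)
    idx = np.searchsorted(tv, grid)
    prev = tv[np.clip(idx - 1, 0, len(tv) - 1)]
    nxt = tv[np.clip(idx, 0, len(tv) - 1)]
    ok = (nxt - prev) <= max_beat_gap_s
    return ok & (grid >= tv[0]) & (grid <= tv[-1])


def trial_hr_mean(
    hr: SampledStream,
    onset: float,
    window_s: tuple[float, float] = (0.0, 3.0),
    trial: int = 0,
) -> HRTrialValue:
    """Mean heart rate over ``[onset, onset + 3]`` (inclusive ends; at
    2 Hz this is at most 7 samples)."""
    sel = (hr.t >= onset + window_s[0]) & (hr.t <= onset + window_s[1] + 1e-9) & hr.mask
    if not sel.any():
        return HRTrialValue(trial, np.nan, False, "no_data")
    return HRTrialValue(trial, float(hr.values[sel].mean()))


def preprocess_rr(
    series: RRSeries,
    lo_ms: float = 300.0,
    hi_ms: float = 2000.0,
    rel_threshold: float = 0.2,
    resample_hz: float = 2.0,
    conversion_constant: float = 60000.0,
    max_beat_gap_s: float = 3.0,
) -> SampledStream:
    """Full RR chain: range filter, ectopic removal, resampled HR."""
    cleaned = remove_ectopic(filter_rr_range(series, lo_ms, hi_ms), rel_threshold)
    hr = rr_to_hr(cleaned, resample_hz, conversion_constant)
    if len(hr) > 1 or hr.mask.any():
        hr.mask &= nn_support(cleaned, hr.t, max_beat_gap_s)
    return hr
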