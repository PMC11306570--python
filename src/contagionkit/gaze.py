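"""Gaze-stream preprocessing and per-trial AOI proportions.

Raw binocular gaze is resampled to a uniform grid (missing samples
excluded, the rest linearly interpolated) and averaged across the
available eyes.  Per trial, the proportion of gaze inside the eye AOI
is the number of valid samples classified inside the polygon divided
by the number of valid samples in the first 3 s of the stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aoi import EyeAOI, points_in_polygon
from .core import SampledStream


@dataclass
class GazeTrialSummary:
    trial: int
    n_total_samples: int
    n_missing: int
    n_in_aoi: int
    proportion_in_aoi: float
    valid: bool = True
    reason: str = ""


def _interp_eye(
    stream: SampledStream, grid: np.ndarray, max_bridge_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate one eye's (x, y) track onto the grid.

    Grid samples are valid only where the enclosing pair of valid raw
    samples is no further apart than ``max_bridge_s``; longer stretches
    of missing raw data stay missing instead of being bridged.
    """
    tv, xv = stream.valid()
    n = len(grid)
    if len(tv) == 0:
        return np.full((n, 2), np.nan), np.zeros(n, dtype=bool)
    out = np.column_stack(
        [np.interp(grid, tv, xv[:, 0]), np.interp(grid, tv, xv[:, 1])]
    )
    # gap between neighbouring valid raw samples, evaluated at grid times
    idx = np.searchsorted(tv, grid)
    prev = tv[np.clip(idx - 1, 0, len(tv) - 1)]
    nxt = tv[np.clip(idx, 0, len(tv) - 1)]
    gap = nxt - prev
    # grid points coinciding with a valid raw sample are always valid
    pos = np.clip(np.searchsorted(tv, grid - 1e-9), 0, len(tv) - 1)
    exact = np.abs(tv[pos] - grid) < 1e-9
    ok = (gap <= max_bridge_s) & (grid >= tv[0]) & (grid <= tv[-1])
    return out, ok | exact


def preprocess_gaze(
    left: SampledStream,
    right: SampledStream,
    rate_hz: float = 120.0,
    max_bridge_s: float | None = None,
) -> SampledStream:
    """Resample binocular gaze to ``rate_hz`` and average across eyes.

    Single-eye samples pass through unchanged; samples with neither eye
    valid are marked missing.  Returns a stream of (x, y) pairs on the
    uniform grid; the mask carries per-sample validity.
    """
    if max_bridge_s is None:
        max_bridge_s = 1.5 / rate_hz
    t0 = min(left.t[0], right.t[0])
    t1 = max(left.t[-1], right.t[-1])
    n = int(np.floor((t1 - t0) * rate_hz)) + 1
    grid = t0 + np.arange(n) / rate_hz
    xl, okl = _interp_eye(left, grid, max_bridge_s)
    xr, okr = _interp_eye(right, grid, max_bridge_s)
    both = okl & okr
    values = np.full((n, 2), np.nan)
    values[both] = 0.5 * (xl[both] + xr[both])
    only_l = okl & ~okr
    values[only_l] = xl[only_l]
    only_r = okr & ~okl
    values[only_r] = xr[only_r]
    mask = okl | okr
    return SampledStream(grid, values, mask)


def gaze_proportion(
    gaze: SampledStream,
    aoi: EyeAOI,
    onset_s: float,
    window_s: tuple[float, float] = (0.0, 3.0),
    trial: int = 0,
) -> GazeTrialSummary:
    """Proportion of valid gaze samples inside the AOI in the window.

    Missing samples are excluded from both numerator and denominator.
    A trial with zero usable samples is returned invalid with reason
    ``"no_data"`` rather than raising.
    """
    lo = onset_s + window_s[0]
    hi = onset_s + window_s[1]
    sel = (gaze.t >= lo) & (gaze.t < hi)
    n_total = int(sel.sum())
    valid = sel & gaze.mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        return GazeTrialSummary(trial, n_total, n_total, 0, np.nan, False, "no_data")
    inside = points_in_polygon(gaze.values[valid], aoi)
    n_in = int(inside.sum())
    return GazeTrialSummary(
        trial=trial,
        n_total_samples=n_total,
        n_missing=n_total - n_valid,
        n_in_aoi=n_in,
        proportion_in_aoi=n_in / n_valid,
    )
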