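"""Electrodermal activity: phasic extraction and trial SCR amplitudes.

The phasic component is isolated by resampling the conductance to a
uniform grid, removing tonic drift with a 1st-order 0.05 Hz high-pass,
and attenuating fast deviations with a 2nd-order zero-phase 5 Hz
low-pass.  A trial's SCR amplitude is the maximum of the phasic signal
in the 3 s after onset minus the mean phasic level in the 1 s before
onset; negative amplitudes are retained.  Per participant, trials with
amplitudes outside mean +/- z*SD are excluded in a single pass.

Note that high-pass filtering necessarily attenuates slow response
components: for a Bateman-shaped response with a 2 s decay constant
the chain's net amplitude gain is about 0.87 (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .core import SampledStream


@dataclass
class PhasicSignal:
    t: np.ndarray
    phasic: np.ndarray
    source_id: str = ""


@dataclass
class SCRTrialValue:
    trial: int
    pre_mean: float
    peak: float
    amplitude: float  # peak - pre_mean, by definition
    excluded: bool = False
    reason: str = ""


def extract_phasic(
    raw: SampledStream,
    resample_hz: float = 120.0,
    hp_cutoff_hz: float = 0.05,
    hp_order: int = 1,
    lp_cutoff_hz: float = 5.0,
    lp_order: int = 2,
    hp_zero_lag: bool = True,
    source_id: str = "",
) -> PhasicSignal:
    """Isolate the phasic skin-conductance component.

    The record should be at least a few high-pass time constants long
    (~3 / (2*pi*hp_cutoff)); shorter records trigger a warning because
    filter edge effects then dominate.
    """
    tv, xv = raw.valid()
    span = tv[-1] - tv[0]
    tau = 1.0 / (2.0 * np.pi * hp_cutoff_hz)
    if span < 3.0 * tau:
        warnings.warn(
            f"record of {span:.1f} s is shorter than 3 high-pass time constants "
            f"({3 * tau:.1f} s); phasic estimates will be edge-dominated",
            stacklevel=2,
        )
    n = int(np.floor(span * resample_hz)) + 1
    grid = tv[0] + np.arange(n) / resample_hz
    x = np.interp(grid, tv, xv)
    bh, ah = butter(hp_order, hp_cutoff_hz, btype="highpass", fs=resample_hz)
    if hp_zero_lag:
        y = filtfilt(bh, ah, x)
    else:  # causal variant, kept configurable
        from scipy.signal import lfilter

        y = lfilter(bh, ah, x - x[0])
    bl, al = butter(lp_order, lp_cutoff_hz, btype="lowpass", fs=resample_hz)
    y = filtfilt(bl, al, y)
    return PhasicSignal(grid, y, source_id)


def scr_amplitude(
    phasic: PhasicSignal,
    trial_onset: float,
    window_s: tuple[float, float] = (0.0, 3.0),
    baseline_s: float = 1.0,
    trial: int = 0,
) -> SCRTrialValue:
    """Peak phasic value in ``(onset, onset + 3]`` minus the mean over
    ``[onset - 1, onset)``; may be negative if the signal falls."""
    pre_sel = (phasic.t >= trial_onset - baseline_s) & (phasic.t < trial_onset)
    win_sel = (phasic.t > trial_onset + window_s[0]) & (
        phasic.t <= trial_onset + window_s[1]
    )
    if not pre_sel.any() or not win_sel.any():
        return SCRTrialValue(trial, np.nan, np.nan, np.nan, True, "no_data")
    pre = float(phasic.phasic[pre_sel].mean())
    peak = float(phasic.phasic[win_sel].max())
    return SCRTrialValue(trial, pre, peak, peak - pre)


def exclude_outlier_trials(
    values: list[SCRTrialValue], z: float = 2.5
) -> list[SCRTrialValue]:
    """Single-pass SD-based exclusion over one participant's trials.

    Amplitudes outside ``mean +/- z*SD`` (SD over all not-yet-excluded
    trials) are marked excluded.  With zero SD, or a non-finite ``z``,
    nothing is excluded.
    """
    usable = [v for v in values if not v.excluded and np.isfinite(v.amplitude)]
    if len(usable) < 3 or not np.isfinite(z):
        return list(values)
    amps = np.array([v.amplitude for v in usable])
    mean, sd = amps.mean(), amps.std(ddof=1)
    if sd == 0:
        return list(values)
    out = []
    for v in values:
        if (
            not v.excluded
            and np.isfinite(v.amplitude)
            and abs(v.amplitude - mean) > z * sd
        ):
            v = replace(v, excluded=True, reason="sd_outlier")
        out.append(v)
    return out
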