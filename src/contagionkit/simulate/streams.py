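"""Raw signal stream generators.

Each generator produces a continuous session-long stream for one
participant from a seeded NumPy generator.  Event-locked effects are
confined to the 0-3 s post-onset analysis window of large-pupil
trials (CROSS condition only for pupil and heart rate).

Design notes
------------
* The pupil dilation bump has raised-cosine edges and is normalized so
  its *discrete mean over the analysis-window samples* equals its
  nominal amplitude; its spectral content sits well below the 4 Hz
  low-pass cutoff, so the preprocessing chain recovers the amplitude
  to numerical precision when noise is disabled.
* The heart-rate change is applied to every beat within a small pad
  around the analysis window (``hr_effect_pad_s``) so the 2 Hz
  interpolated grid sees a steady level across the whole window — an
  anticipatory lead/persistence of about one beat.
* Sensor noise is mildly band-limited (3-sample boxcar) as tracker
  noise at 120 Hz is oversampled rather than white.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..aoi import EyeAOI, points_in_polygon
from ..config import SimConfig
from ..core import SampledStream
from ..hr import RRSeries
from .cohort import Participant
from .measures import pupil_effect_mm


def _session_grid(config: SimConfig, rate_hz: float) -> np.ndarray:
    n = int(round(config.session_duration_s * rate_hz))
    return np.arange(n) / rate_hz


def _smooth_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    w = rng.normal(0.0, sd, n)
    k = np.ones(3) / 3.0
    return np.convolve(w, k, mode="same") * np.sqrt(3.0)  # restore the SD


def _bump_shape(
    u: np.ndarray, length: float, edge: float = 1.0, margin: float = 0.5
) -> np.ndarray:
    """Raised-cosine-edged plateau supported on [margin, length - margin].

    The margin keeps the (already smooth) transients of the zero-phase
    low-pass strictly inside the analysis window, so the window mean
    of the filtered bump equals the window mean of the raw bump to
    numerical precision.
    """
    w = np.zeros_like(u)
    lo, hi = margin, length - margin
    inside = (u >= lo) & (u <= hi)
    ui = u[inside] - lo
    span = hi - lo
    w_in = np.ones_like(ui)
    rise = ui < edge
    w_in[rise] = 0.5 * (1 - np.cos(np.pi * ui[rise] / edge))
    fall = ui > span - edge
    w_in[fall] = 0.5 * (1 - np.cos(np.pi * (span - ui[fall]) / edge))
    w[inside] = w_in
    return w


# ---------------------------------------------------------------------------
# pupil


def simulate_pupil(
    participant: Participant,
    schedule: pd.DataFrame,
    config: SimConfig,
    seed: int,
) -> tuple[SampledStream, SampledStream]:
    """Left and right pupil-diameter traces (mm) at the gaze rate."""
    rng = np.random.default_rng(seed)
    t = _session_grid(config, config.gaze_rate_hz)
    n = len(t)
    rate = config.gaze_rate_hz
    win_lo, win_hi = 0.0, 3.0

    base = float(np.clip(rng.normal(4.0, 0.4), 2.5, 6.5))
    tonic = np.full(n, base)
    if config.pupil_drift_mm > 0:
        for period, frac in ((41.0, 1.0), (67.0, 0.6), (109.0, 0.4)):
            tonic += (
                config.pupil_drift_mm
                * frac
                * np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
            )

    response = np.zeros(n)
    for row in schedule.itertuples(index=False):
        amp = 0.0
        if row.stim_pupil == "large":
            amp += pupil_effect_mm(participant, row.condition, config)
        if config.pupil_trial_sd > 0:
            amp += rng.normal(0.0, config.pupil_trial_sd)
        elif row.stim_pupil != "large":
            continue
        if amp == 0.0:
            continue
        lo = int(np.ceil((row.onset_s + win_lo) * rate - 1e-9))
        hi = int(np.ceil((row.onset_s + win_hi) * rate - 1e-9))  # [onset, onset+3)
        u = t[lo:hi] - row.onset_s
        w = _bump_shape(u, win_hi - win_lo)
        mean_w = w.mean()
        if mean_w > 0:
            response[lo:hi] += amp * (w / mean_w)

    streams = []
    for _eye in ("left", "right"):
        x = tonic + response + rng.normal(0.0, 0.05) + _smooth_noise(
            rng, n, config.pupil_noise_sd
        )
        mask = np.ones(n, dtype=bool)
        streams.append((x, mask))

    # binocular blinks with edge artefacts
    if config.blink_rate_hz > 0:
        n_blinks = rng.poisson(config.blink_rate_hz * config.session_duration_s)
        starts = rng.integers(0, n, n_blinks)
        lengths = rng.integers(5, 31, n_blinks)
        for s, ln in zip(starts, lengths):
            for x, mask in streams:
                mask[s : s + ln] = False
                if s > 0:
                    x[s - 1] += rng.uniform(0.2, 0.5) * rng.choice([-1, 1])
                if s + ln < n:
                    x[s + ln] += rng.uniform(0.2, 0.5) * rng.choice([-1, 1])

    if config.spike_rate_hz > 0:  # single-sample tracker spikes
        n_spikes = rng.poisson(config.spike_rate_hz * config.session_duration_s)
        for idx in rng.integers(0, n, n_spikes):
            for x, _mask in streams:
                x[idx] += rng.uniform(0.3, 1.0) * rng.choice([-1, 1])

    if config.missing_trial_rate > 0:  # whole trials lost (tracking dropouts)
        for row in schedule.itertuples(index=False):
            if rng.random() < config.missing_trial_rate:
                lo = int((row.onset_s - config.isi_fixation_s) * rate)
                hi = int((row.onset_s + row.duration_s) * rate)
                for _x, mask in streams:
                    mask[lo:hi] = False

    out = []
    for x, mask in streams:
        x = x.copy()
        x[~mask] = np.nan
        out.append(SampledStream(t.copy(), x, mask))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# gaze


_POOL_SIZE = 4096


def _point_pools(
    aoi: EyeAOI, frame: tuple[int, int], sd_in: float, center_out, sd_out: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pools of points inside / outside the AOI, cached on the AOI.

    Trial sampling then only draws pool indices, so the expensive
    polygon rejection runs once per stimulus rather than per trial.
    The pool seed is fixed: pools are part of the stimulus geometry,
    not of any participant's randomness.
    """
    cached = getattr(aoi, "_gaze_pools", None)
    if cached is not None:
        return cached
    rng = np.random.default_rng(0xA01)
    w, h = frame
    eye_mid = aoi.vertices.mean(axis=0)

    inside = np.empty((0, 2))
    while len(inside) < _POOL_SIZE:
        cand = rng.normal(eye_mid, sd_in, (2 * _POOL_SIZE, 2))
        cand = cand[points_in_polygon(cand, aoi)]
        inside = np.vstack([inside, cand])
    inside = inside[:_POOL_SIZE]

    outside = np.empty((0, 2))
    while len(outside) < _POOL_SIZE:
        cand = rng.normal(center_out, sd_out, (2 * _POOL_SIZE, 2))
        cand[:, 0] = np.clip(cand[:, 0], 0, w - 1)
        cand[:, 1] = np.clip(cand[:, 1], 0, h - 1)
        cand = cand[~points_in_polygon(cand, aoi)]
        outside = np.vstack([outside, cand])
    outside = outside[:_POOL_SIZE]

    aoi._gaze_pools = (inside, outside)  # type: ignore[attr-defined]
    return inside, outside


def gaze_eye_probability(
    participant: Participant, condition: str, config: SimConfig, subject_effect: float
) -> float:
    """Per-participant probability of looking inside the eye AOI.

    Logistic model: condition median, plus a positive age gradient,
    plus a participant-level random intercept shared across conditions.
    """
    median = (
        config.cross_gaze_median if condition == "CROSS" else config.nocross_gaze_median
    )
    if median >= 1.0 or median <= 0.0:  # saturated bias
        return float(np.clip(median, 0.0, 1.0))
    age_z = (participant.age_months - config.age_mean_months) / config.age_sd_months
    logit = np.log(median / (1 - median)) + config.gaze_age_slope * age_z + subject_effect
    return float(1.0 / (1.0 + np.exp(-logit)))


def simulate_gaze(
    participant: Participant,
    schedule: pd.DataFrame,
    aois: dict[str, EyeAOI] | EyeAOI,
    config: SimConfig,
    seed: int,
) -> tuple[SampledStream, SampledStream]:
    """Left- and right-eye gaze streams in stimulus pixel coordinates.

    During each trial, samples fall inside the trial image's eye AOI
    with the participant/condition-specific probability; other samples
    scatter around the lower face.  Between trials gaze rests near the
    fixation-cross location.  ``gaze_missing_rate`` of samples are
    dropped at random (plus whole-trial dropouts).
    """
    rng = np.random.default_rng(seed)
    t = _session_grid(config, config.gaze_rate_hz)
    n = len(t)
    w, h = config.stim_width, config.stim_height
    subject_effect = rng.normal(0.0, config.gaze_subject_sd)

    cross_pos = np.array([w / 2.0, 0.42 * h])
    xy = np.tile(cross_pos + rng.normal(0, 8, 2), (n, 1))
    xy += rng.normal(0, 2.0, (n, 2))

    for row in schedule.itertuples(index=False):
        aoi = aois[row.image_id] if isinstance(aois, dict) else aois
        lo = int(np.ceil(row.onset_s * config.gaze_rate_hz - 1e-9))
        hi = int(np.ceil((row.onset_s + row.duration_s) * config.gaze_rate_hz - 1e-9))
        m = hi - lo
        p = gaze_eye_probability(participant, row.condition, config, subject_effect)
        look_eyes = rng.random(m) < p
        pool_in, pool_out = _point_pools(
            aoi, (w, h), 0.10 * w, np.array([0.5 * w, 0.68 * h]), 0.12 * w
        )
        pts = np.empty((m, 2))
        k_in = int(look_eyes.sum())
        if k_in:
            pts[look_eyes] = pool_in[rng.integers(0, len(pool_in), k_in)]
        if m - k_in:
            pts[~look_eyes] = pool_out[rng.integers(0, len(pool_out), m - k_in)]
        xy[lo:hi] = pts

    streams = []
    for _eye in ("left", "right"):
        vals = xy.copy()
        if config.gaze_disparity_px > 0:
            vals = vals + rng.normal(0.0, config.gaze_disparity_px, (n, 2))
        mask = rng.random(n) >= config.gaze_missing_rate
        vals[~mask] = np.nan
        streams.append(SampledStream(t.copy(), vals, mask))
    return streams[0], streams[1]


# ---------------------------------------------------------------------------
# electrodermal activity


def scr_kernel(config: SimConfig, rate_hz: float, length_s: float = 15.0) -> np.ndarray:
    """Bateman double-exponential SCR waveform, unit peak amplitude."""
    u = np.arange(int(length_s * rate_hz)) / rate_hz
    k = np.exp(-u / config.scr_decay_tau_s) - np.exp(-u / config.scr_rise_tau_s)
    peak = k.max()
    return k / peak if peak > 0 else k


def simulate_eda(
    schedule: pd.DataFrame, config: SimConfig, seed: int
) -> SampledStream:
    """Skin-conductance stream: tonic drift + phasic SCRs + artefacts."""
    rng = np.random.default_rng(seed)
    rate = config.eda_rate_hz
    t = _session_grid(config, rate)
    n = len(t)

    tonic = np.full(n, config.eda_level_us) + 0.02 * rng.standard_normal()
    if config.eda_drift_us > 0:
        for period, frac in ((97.0, 1.0), (211.0, 0.5)):
            tonic += (
                config.eda_drift_us
                * frac
                * np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi))
            )

    impulses = np.zeros(n)
    for row in schedule.itertuples(index=False):
        amp = config.scr_contagion_us if (
            row.stim_pupil == "large" and row.condition == "CROSS"
        ) else 0.0
        if config.scr_trial_sd_us > 0:
            amp += abs(rng.normal(0.0, config.scr_trial_sd_us))
        if amp > 0:
            idx = int(round(row.onset_s * rate))
            if idx < n:
                impulses[idx] += amp
    if config.scr_spontaneous_rate_hz > 0:
        k = rng.poisson(config.scr_spontaneous_rate_hz * config.session_duration_s)
        for idx in rng.integers(0, n, k):
            impulses[idx] += rng.exponential(config.scr_spontaneous_amp_us)

    from scipy.signal import fftconvolve

    kern = scr_kernel(config, rate)
    phasic = fftconvolve(impulses, kern)[:n]

    x = tonic + phasic + rng.normal(0.0, config.eda_noise_sd, n)

    if config.scr_artifact_trial_rate > 0:  # movement artefacts in trial windows
        for row in schedule.itertuples(index=False):
            if rng.random() < config.scr_artifact_trial_rate:
                at = row.onset_s + rng.uniform(0.0, 3.0)
                dur = rng.uniform(0.3, 1.0)
                amp = rng.uniform(0.5, 1.0) * config.scr_artifact_amp_us
                x += amp * np.exp(-0.5 * ((t - at) / (dur / 2.355)) ** 2)

    return SampledStream(t, x, np.ones(n, dtype=bool))


# ---------------------------------------------------------------------------
# RR intervals


def simulate_rr(
    schedule: pd.DataFrame, config: SimConfig, seed: int
) -> RRSeries:
    """Beat-by-beat RR series with HRV, ectopic beats and range outliers.

    Ground-truth annotations are attached as ``attrs`` on the returned
    series (indices of injected ectopic beats and out-of-range values)
    for known-truth recovery tests.
    """
    rng = np.random.default_rng(seed)
    rest_rr = float(np.clip(rng.normal(config.rr_rest_mean_ms, config.rr_rest_sd_ms), 550, 1050))
    rest_hr = 60000.0 / rest_rr

    # per-trial HR offsets (effect on large CROSS + trial variability)
    windows: list[tuple[float, float, float]] = []
    for row in schedule.itertuples(index=False):
        offset = 0.0
        if row.stim_pupil == "large" and row.condition == "CROSS":
            offset += config.hr_contagion_bpm
        if config.hr_trial_sd_bpm > 0:
            offset += rng.normal(0.0, config.hr_trial_sd_bpm)
        if offset != 0.0:
            windows.append(
                (
                    row.onset_s - config.hr_effect_pad_s,
                    row.onset_s + 3.0 + config.hr_effect_pad_s,
                    offset,
                )
            )

    times: list[float] = []
    rrs: list[float] = []
    ectopic_idx: list[int] = []
    range_idx: list[int] = []
    t = 0.0
    ar = 0.0  # AR(1) HRV state
    i = 0
    total = config.session_duration_s
    while t < total:
        ar = 0.6 * ar + rng.normal(0.0, config.rr_noise_sd_ms) if config.rr_noise_sd_ms else 0.0
        hr_nominal = 60000.0 / (rest_rr + ar)
        # window membership judged at the beat's (nominal) end time: the
        # recorded timestamp, which is what the HR grid interpolates on
        t_end = t + rest_rr / 1000.0
        offset = 0.0
        for lo, hi, off in windows:
            if lo <= t_end <= hi:
                offset += off
        rr = 60000.0 / max(hr_nominal + offset, 20.0)

        u = rng.random()
        if u < config.ectopic_rate_hz * rr / 1000.0:
            rr *= 1.0 + rng.choice([-1.0, 1.0]) * rng.uniform(0.25, 0.45)
            ectopic_idx.append(i)
        elif u < (config.ectopic_rate_hz + config.rr_outlier_rate_hz) * rr / 1000.0:
            rr = float(rng.choice([rng.uniform(120, 280), rng.uniform(2100, 3200)]))
            range_idx.append(i)

        t += rr / 1000.0
        times.append(t)
        rrs.append(rr)
        i += 1

    series = RRSeries(np.array(times), np.array(rrs))
    series.attrs = {  # type: ignore[attr-defined]
        "ectopic_idx": np.array(ectopic_idx, dtype=int),
        "range_idx": np.array(range_idx, dtype=int),
        "rest_hr_bpm": rest_hr,
    }
    return series
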