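"""Configuration objects for simulation and analysis.

Two dataclasses cover the whole toolkit: :class:`SimConfig` holds the
study-design and effect parameters of the synthetic cohort generator,
and :class:`PipelineConfig` holds every preprocessing/statistics
parameter of the analysis chain.  Defaults of :class:`PipelineConfig`
are the published preprocessing settings (4-MAD dilation-speed filter,
10-sample gap rule with 5-sample padding, 4 Hz/4th-order zero-phase
pupil low-pass, 0.05 Hz/1st-order EDA high-pass, 5 Hz/2nd-order EDA
low-pass, 2.5-SD trial exclusion, 300–2000 ms RR bounds, 0–3 s analysis
window, 1 s baseline).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .core import InvalidConfigError

# Published AQ norm statistics (total score mean, SD) used only to
# back-compute plausible raw questionnaire scores from simulated
# z-scores; exposed so alternative norm tables can be supplied.
DEFAULT_AQ_NORMS: dict[str, tuple[float, float]] = {
    "child": (52.3, 15.2),
    "adolescent": (19.5, 7.7),
    "adult": (16.4, 6.1),
}

AQ_MAX_SCORE = {"child": 150, "adolescent": 50, "adult": 50}


@dataclass
class SimConfig:
    """Parameters of the synthetic multimodal cohort generator.

    The block/trial layout mirrors the study design: 8 blocks (4 per
    gaze condition) of 8 trials, 6 s stimuli, 1 s inter-stimulus
    fixation, 10 s pre-block fixation.  Effect sizes are expressed in
    physical units and placed in the 0–3 s post-onset analysis window
    of large-pupil trials; in the CROSS condition the pupil effect is
    additionally scaled by ``1 + beta * aq_z`` with ``beta`` solved so
    the cohort rank correlation between trait score and pupil
    differential targets ``aq_contagion_rho``.
    """

    # design
    n_participants: int = 66
    seed: int = 0
    blocks_per_condition: int = 4
    trials_per_block: int = 8
    stim_duration_s: float = 6.0
    isi_fixation_s: float = 1.0
    block_fixation_s: float = 10.0
    gaze_rate_hz: float = 120.0
    eda_rate_hz: float = 128.0

    # embedded effects
    pupil_contagion_mm: float = 0.04
    hr_contagion_bpm: float = 2.0
    scr_contagion_us: float = 0.0  # no skin-conductance effect observed
    aq_contagion_rho: float = 0.28
    cross_gaze_median: float = 0.747
    nocross_gaze_median: float = 0.512

    # noise / artefact model
    blink_rate_hz: float = 1.0
    pupil_noise_sd: float = 0.05  # per-sample sensor noise, mm
    pupil_trial_sd: float = 0.25  # trial-to-trial response variability, mm
    pupil_drift_mm: float = 0.10  # tonic drift amplitude, mm
    spike_rate_hz: float = 0.1  # single-sample tracker spikes
    missing_trial_rate: float = 0.032
    gaze_missing_rate: float = 0.045
    gaze_age_slope: float = 0.5  # logit-scale age gradient of eye-looking
    gaze_subject_sd: float = 0.65  # logit-scale between-participant spread
    gaze_disparity_px: float = 1.0  # per-eye jitter around the binocular point
    eda_noise_sd: float = 0.01  # microsiemens
    eda_drift_us: float = 0.5  # amplitude of slow tonic drift
    eda_level_us: float = 5.0
    scr_spontaneous_rate_hz: float = 0.03
    scr_spontaneous_amp_us: float = 0.3
    scr_artifact_trial_rate: float = 0.10
    scr_artifact_amp_us: float = 4.0
    scr_rise_tau_s: float = 0.75
    scr_decay_tau_s: float = 2.0
    scr_trial_sd_us: float = 0.2  # trial-to-trial amplitude variability
    rr_rest_mean_ms: float = 750.0
    rr_rest_sd_ms: float = 80.0  # between-participant spread of resting RR
    rr_noise_sd_ms: float = 25.0  # within-participant beat-to-beat variability
    hr_trial_sd_bpm: float = 4.0  # trial-to-trial HR variability
    hr_effect_pad_s: float = 1.2  # HR response onset lead/persistence around the window
    ectopic_rate_hz: float = 0.02
    rr_outlier_rate_hz: float = 0.003  # out-of-range (<300 or >2000 ms) values

    # cohort composition
    diagnosed_fraction: float = 1.0 / 3.0
    age_mean_months: float = 129.9
    age_sd_months: float = 38.5
    age_range_months: tuple[float, float] = (72.0, 216.0)
    aq_z_means: tuple[float, float] = (-0.45, 1.8)  # (typical, diagnosed)
    aq_z_sds: tuple[float, float] = (1.2, 1.5)
    aq_norms: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AQ_NORMS)
    )

    # stimulus frame (pixels) used for landmarks, gaze and images
    stim_width: int = 256
    stim_height: int = 320
    n_stimulus_pairs: int = 16

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 2:
            raise InvalidConfigError("n_participants must be >= 2")
        for name in ("gaze_rate_hz", "eda_rate_hz"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        for name in ("stim_duration_s", "isi_fixation_s", "block_fixation_s"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        for name in (
            "cross_gaze_median",
            "nocross_gaze_median",
            "missing_trial_rate",
            "gaze_missing_rate",
            "diagnosed_fraction",
            "scr_artifact_trial_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("pupil_contagion_mm", "hr_contagion_bpm", "scr_contagion_us"):
            import math

            if not math.isfinite(getattr(self, name)):
                raise InvalidConfigError(f"{name} must be finite")
        if self.blocks_per_condition < 1 or self.trials_per_block < 1:
            raise InvalidConfigError("block/trial counts must be positive")

    @property
    def n_blocks(self) -> int:
        return 2 * self.blocks_per_condition

    @property
    def trials_per_condition(self) -> int:
        return self.blocks_per_condition * self.trials_per_block

    @property
    def block_duration_s(self) -> float:
        return self.block_fixation_s + self.trials_per_block * (
            self.stim_duration_s + self.isi_fixation_s
        )

    @property
    def session_duration_s(self) -> float:
        return self.n_blocks * self.block_duration_s

    @property
    def aq_z_mean(self) -> float:
        """Population mean of the simulated trait z-score mixture."""
        w = self.diagnosed_fraction
        return (1 - w) * self.aq_z_means[0] + w * self.aq_z_means[1]

    def without_noise(self) -> "SimConfig":
        """Copy with every stochastic nuisance term switched off.

        Embedded effects are retained; only sensor noise, drift,
        blinks, artefacts, missingness and trial-to-trial variability
        are zeroed, so injected effects can be recovered exactly.
        """
        return dataclasses.replace(
            self,
            aq_contagion_rho=0.0,  # decouple trait scaling so effects are exact
            blink_rate_hz=0.0,
            pupil_noise_sd=0.0,
            pupil_trial_sd=0.0,
            pupil_drift_mm=0.0,
            spike_rate_hz=0.0,
            missing_trial_rate=0.0,
            gaze_missing_rate=0.0,
            gaze_subject_sd=0.0,
            gaze_disparity_px=0.0,
            eda_noise_sd=0.0,
            eda_drift_us=0.0,
            scr_spontaneous_rate_hz=0.0,
            scr_artifact_trial_rate=0.0,
            rr_noise_sd_ms=0.0,
            hr_trial_sd_bpm=0.0,
            ectopic_rate_hz=0.0,
            rr_outlier_rate_hz=0.0,
            scr_trial_sd_us=0.0,
        )

    def null_effects(self) -> "SimConfig":
        """Copy with all embedded contagion effects set to zero."""
        return dataclasses.replace(
            self,
            pupil_contagion_mm=0.0,
            hr_contagion_bpm=0.0,
            scr_contagion_us=0.0,
            aq_contagion_rho=0.0,
        )

    def replace(self, **kwargs: Any) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PipelineConfig:
    """Analysis parameters; defaults are the published settings."""

    # pupil chain
    mad_k: float = 4.0
    mad_speed_floor: float = 1.0  # mm/s; degenerate-distribution guard
    max_gap_samples: int = 10
    gap_pad_samples: int = 5
    pupil_rate_hz: float = 120.0
    pupil_lp_cutoff_hz: float = 4.0
    pupil_lp_order: int = 4
    min_valid_fraction: float = 0.5  # trial validity rule after cleaning

    # analysis windows
    window_s: tuple[float, float] = (0.0, 3.0)
    baseline_s: float = 1.0

    # EDA chain
    eda_resample_hz: float = 120.0
    eda_hp_cutoff_hz: float = 0.05
    eda_hp_order: int = 1
    eda_hp_zero_lag: bool = True
    eda_lp_cutoff_hz: float = 5.0
    eda_lp_order: int = 2
    scr_outlier_z: float = 2.5
    scr_outlier_per_condition: bool = False  # pool both conditions per participant

    # HR chain
    rr_lo_ms: float = 300.0
    rr_hi_ms: float = 2000.0
    ectopic_rel_threshold: float = 0.2
    hr_resample_hz: float = 2.0
    hr_conversion_constant: float = 60000.0  # ms -> bpm; 6000 via strict_replication
    strict_replication: bool = False
    hr_max_beat_gap_s: float = 3.0  # grid samples bridged across longer gaps are invalid

    # AOI / gaze
    ellipse_height_ratio: float = 0.5
    ellipse_vertices: int = 32
    gaze_rate_hz: float = 120.0

    # statistics
    alpha: float = 0.05
    wilcoxon_exact_n_max: int = 25
    wilcoxon_zero_method: str = "wilcox"  # or "pratt"
    semipartial_residualize: str = "x"  # covariates removed from the trait side
    gaze_covariate_per_condition: bool = True

    def __post_init__(self) -> None:
        if self.mad_k < 0:
            raise InvalidConfigError("mad_k must be >= 0")
        if self.max_gap_samples < 1 or self.gap_pad_samples < 0:
            raise InvalidConfigError("gap parameters out of range")
        if not 0 <= self.min_valid_fraction <= 1:
            raise InvalidConfigError("min_valid_fraction must be in [0, 1]")
        if self.window_s[1] <= self.window_s[0]:
            raise InvalidConfigError("analysis window must have positive length")
        if self.semipartial_residualize not in ("x", "y"):
            raise InvalidConfigError("semipartial_residualize must be 'x' or 'y'")
        if self.wilcoxon_zero_method not in ("wilcox", "pratt"):
            raise InvalidConfigError("wilcoxon_zero_method must be wilcox|pratt")

    @property
    def hr_constant(self) -> float:
        return 6000.0 if self.strict_replication else self.hr_conversion_constant

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def save_config(config: Any, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def _from_mapping(cls: type, data: dict[str, Any]) -> Any:
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if isinstance(value, list) and isinstance(names[key].default, tuple):
            value = tuple(value)
        if key in ("age_range_months", "aq_z_means", "aq_z_sds", "window_s") and isinstance(
            value, list
        ):
            value = tuple(value)
        if key == "aq_norms" and isinstance(value, dict):
            value = {k: tuple(v) for k, v in value.items()}
        kwargs[key] = value
    return cls(**kwargs)


def load_sim_config(path: str | Path) -> SimConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _from_mapping(SimConfig, data)


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _from_mapping(PipelineConfig, data)
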