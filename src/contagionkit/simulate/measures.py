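"""Trial-measure-level simulation and trait-coupling calibration.

``simulate_trial_measures`` draws per-trial arousal measures (pupil
window mean, trial heart rate, SCR amplitude) directly from the same
statistical model that drives the raw-stream generators, without
synthesizing or re-filtering the streams themselves.  It exists for
seed-sweep studies (type-I calibration, power curves) where thousands
of cohorts are needed; single-cohort analyses and known-truth tests
run the full stream generators and preprocessing chains instead.

The pupil effect on large-pupil CROSS trials is
``pupil_contagion_mm * (1 + beta * aq_z)``; ``beta`` is solved
numerically from a pilot simulation at cohort size 10,000 so that the
rank correlation between the trait z-score and the pupil differential
score hits ``aq_contagion_rho``.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import spearmanr

from ..config import SimConfig
from .cohort import Participant, cohort_frame, generate_cohort
from .schedule import generate_schedule

_PILOT_SEED = 715_517  # fixed pilot seed: calibration must not drift with cohorts
_PILOT_N = 10_000


@lru_cache(maxsize=64)
def _solve_beta(
    effect_mm: float,
    diff_sd: float,
    rho_target: float,
    mix_means: tuple[float, float],
    mix_sds: tuple[float, float],
    diag_frac: float,
) -> float:
    if rho_target <= 0 or effect_mm == 0:
        return 0.0
    rng = np.random.default_rng(_PILOT_SEED)
    comp = rng.random(_PILOT_N) < diag_frac
    z = np.where(
        comp,
        rng.normal(mix_means[1], mix_sds[1], _PILOT_N),
        rng.normal(mix_means[0], mix_sds[0], _PILOT_N),
    )
    eps = rng.normal(0.0, diff_sd, _PILOT_N)

    def gap(beta: float) -> float:
        diff = effect_mm * (1.0 + beta * z) + eps
        return spearmanr(z, diff).statistic - rho_target

    if diff_sd == 0:
        # noise-free: any positive coupling gives rho = 1; calibration is moot
        return 0.0
    lo, hi = 0.0, 50.0
    if gap(hi) < 0:  # target not attainable; return the cap
        return hi
    return float(brentq(gap, lo, hi, xtol=1e-4))


def solve_aq_coupling(config: SimConfig) -> float:
    """Trait-coupling slope ``beta`` for the configured effect model."""
    n_large = config.trials_per_condition // 2
    n_small = config.trials_per_condition - n_large
    diff_sd = config.pupil_trial_sd * np.sqrt(1.0 / n_large + 1.0 / n_small)
    return _solve_beta(
        config.pupil_contagion_mm,
        float(diff_sd),
        config.aq_contagion_rho,
        tuple(config.aq_z_means),
        tuple(config.aq_z_sds),
        config.diagnosed_fraction,
    )


def pupil_effect_mm(participant: Participant, condition: str, config: SimConfig) -> float:
    """Event-locked pupil dilation amplitude for a large-pupil trial."""
    if condition != "CROSS":
        return 0.0
    beta = solve_aq_coupling(config)
    return config.pupil_contagion_mm * (1.0 + beta * participant.aq_z)


def simulate_trial_measures(
    config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Per-trial arousal measures for a whole cohort.

    Returns a long table with one row per participant x trial and
    columns ``pupil`` (baselined window mean, mm), ``hr`` (bpm) and
    ``scr`` (amplitude, microsiemens), each with a ``*_valid`` flag.
    """
    if seed is None:
        seed = config.seed
    cohort = generate_cohort(config.replace(seed=seed))
    root = np.random.SeedSequence([seed, 0x7EA])
    frames = []
    for participant, child in zip(cohort, root.spawn(len(cohort))):
        rng = np.random.default_rng(child)
        sched = generate_schedule(config, int(rng.integers(2**31)))
        n = len(sched)
        large = (sched["stim_pupil"] == "large").to_numpy()
        cross = (sched["condition"] == "CROSS").to_numpy()

        pupil_mu = np.where(
            large & cross, pupil_effect_mm(participant, "CROSS", config), 0.0
        )
        pupil = pupil_mu + rng.normal(0.0, config.pupil_trial_sd, n)

        rest_rr = np.clip(
            rng.normal(config.rr_rest_mean_ms, config.rr_rest_sd_ms), 550.0, 1050.0
        )
        rest_hr = 60000.0 / rest_rr
        hr = (
            rest_hr
            + np.where(large & cross, config.hr_contagion_bpm, 0.0)
            + rng.normal(0.0, config.hr_trial_sd_bpm, n)
        )

        scr = (
            0.3
            + np.where(large & cross, config.scr_contagion_us, 0.0)
            + rng.normal(0.0, config.scr_trial_sd_us, n)
        )

        valid = rng.random(n) >= config.missing_trial_rate
        df = sched[["trial", "condition", "stim_pupil"]].copy()
        df.insert(0, "participant", participant.id)
        df["pupil"] = pupil
        df["hr"] = hr
        df["scr"] = scr
        for col in ("pupil", "hr", "scr"):
            df[f"{col}_valid"] = valid
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table.attrs["participants"] = cohort_frame(cohort)
    return table
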