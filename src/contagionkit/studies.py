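"""Seed-sweep simulation studies: type-I calibration and effect recovery.

Two tiers are used, matching how the generator is built:

* ``type1_calibration`` needs hundreds of cohorts, so it draws
  per-trial measures directly from the trial-measure generator (the
  statistical model shared with the stream generators) and runs the
  inference layer on them.  The preprocessing chains are deterministic
  transformations whose behaviour is checked separately by known-truth
  tests; the null calibration concerns the tests themselves.
* ``pupil_recovery_study`` runs the *full* path — stream synthesis,
  cleaning chains, AOI classification, differential scores, Wilcoxon
  and semi-partial Spearman — for the pupil and gaze modalities, once
  per seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig, SimConfig
from .core import CONDITIONS, DegenerateInputError
from .pipeline import analyze_cohort
from .simulate.build import simulate_cohort
from .simulate.measures import simulate_trial_measures
from .stats import spearman_semipartial, wilcoxon_signed_rank

MEASURES = ("pupil", "hr", "scr")


def measure_level_pvalues(config: SimConfig, seed: int) -> dict[tuple[str, str], float]:
    """P-values of the six contagion Wilcoxon tests for one simulated
    cohort of per-trial measures."""
    table = simulate_trial_measures(config, seed)
    out: dict[tuple[str, str], float] = {}
    for modality in MEASURES:
        valid = table[table[f"{modality}_valid"]]
        cell = valid.groupby(["participant", "condition", "stim_pupil"])[modality].mean()
        wide = cell.unstack("stim_pupil")
        diffs = (wide["large"] - wide["small"]).dropna()
        for cond in CONDITIONS:
            d = diffs.xs(cond, level="condition")
            try:
                out[(modality, cond)] = wilcoxon_signed_rank(d.to_numpy()).p_value
            except DegenerateInputError:
                out[(modality, cond)] = np.nan
    return out


def type1_calibration(
    config: SimConfig | None = None,
    n_seeds: int = 400,
    base_seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rejection rate of each contagion test under the global null.

    All effect sizes are forced to zero; each seed simulates a fresh
    cohort of trial measures at the configured size and the six
    Wilcoxon tests are run at level ``alpha``.
    """
    cfg = (config or SimConfig()).null_effects()
    rows: dict[tuple[str, str], list[float]] = {}
    for i in range(n_seeds):
        ps = measure_level_pvalues(cfg, base_seed + i)
        for key, p in ps.items():
            rows.setdefault(key, []).append(p)
    records = []
    for (modality, cond), ps in sorted(rows.items()):
        arr = np.asarray(ps)
        ok = np.isfinite(arr)
        records.append(
            {
                "modality": modality,
                "condition": cond,
                "n_seeds": int(ok.sum()),
                "rejection_rate": float((arr[ok] < alpha).mean()),
            }
        )
    return pd.DataFrame(records)


def binomial_ci(p: float, n: int, z: float = 1.959963985) -> tuple[float, float]:
    """Normal-approximation binomial CI around a nominal rate."""
    half = z * np.sqrt(p * (1 - p) / n)
    return (p - half, p + half)


def pupil_recovery_study(
    config: SimConfig | None = None,
    n_seeds: int = 100,
    base_seed: int = 1000,
    alpha: float = 0.05,
    pcfg: PipelineConfig | None = None,
) -> dict:
    """End-to-end pupil-contagion recovery across seeds.

    For each seed a cohort's pupil and gaze streams are simulated and
    pushed through the complete preprocessing and inference pipeline.
    Reports the fraction of seeds with a significant CROSS pupil
    contagion, the fraction with a non-significant NO-CROSS test, and
    the mean recovered semi-partial Spearman correlation between trait
    z-score and the CROSS pupil differential (controlling age and
    amount of gaze).
    """
    cfg = config or SimConfig()
    pcfg = pcfg or PipelineConfig()
    cross_p, nocross_p, rhos = [], [], []
    for i in range(n_seeds):
        data = simulate_cohort(cfg.replace(seed=base_seed + i), modalities=("pupil", "gaze"))
        results = analyze_cohort(data, pcfg)
        pupil = results["contagion"]["pupil"]
        cross_p.append(pupil["CROSS"].get("wilcoxon", {}).get("p_value", np.nan))
        nocross_p.append(pupil["NO_CROSS"].get("wilcoxon", {}).get("p_value", np.nan))
        rho_entry = results["aq_correlations"]["pupil"].get("CROSS", {})
        rhos.append(rho_entry.get("rho", np.nan))
    cross_p_arr = np.asarray(cross_p)
    nocross_p_arr = np.asarray(nocross_p)
    rho_arr = np.asarray(rhos)
    return {
        "n_seeds": n_seeds,
        "cross_detection_rate": float(np.mean(cross_p_arr < alpha)),
        "nocross_nonsig_rate": float(np.mean(nocross_p_arr >= alpha)),
        "mean_semipartial_rho": float(np.nanmean(rho_arr)),
        "sd_semipartial_rho": float(np.nanstd(rho_arr)),
        "cross_p_values": cross_p,
        "nocross_p_values": nocross_p,
        "rhos": rhos,
    }


def semipartial_recovery_measure_level(
    config: SimConfig | None = None, n_seeds: int = 100, base_seed: int = 5000
) -> dict:
    """Trait-correlation recovery on the fast measure-level path."""
    cfg = config or SimConfig()
    rhos = []
    for i in range(n_seeds):
        table = simulate_trial_measures(cfg, base_seed + i)
        participants = table.attrs["participants"].set_index("id")
        valid = table[table["pupil_valid"]]
        cell = valid.groupby(["participant", "condition", "stim_pupil"])["pupil"].mean()
        wide = cell.unstack("stim_pupil")
        diffs = (wide["large"] - wide["small"]).dropna().xs("CROSS", level="condition")
        idx = diffs.index
        rng = np.random.default_rng(base_seed + i)
        gaze_proxy = rng.normal(0.7, 0.1, len(idx))  # uninformative covariate
        corr = spearman_semipartial(
            participants.loc[idx, "aq_z"].to_numpy(),
            diffs.to_numpy(),
            np.column_stack([participants.loc[idx, "age_months"].to_numpy(), gaze_proxy]),
        )
        rhos.append(corr.rho)
    arr = np.asarray(rhos)
    return {
        "n_seeds": n_seeds,
        "mean_rho": float(arr.mean()),
        "sd_rho": float(arr.std()),
    }
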