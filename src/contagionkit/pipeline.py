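"""End-to-end cohort analysis: trial tables, statistics bundle, I/O.

``analyze_cohort`` turns an in-memory :class:`CohortData` into
per-trial tables for every modality, then into the statistics bundle:
the CROSS vs NO-CROSS gaze comparison, six Wilcoxon tests of the
differential arousal scores (3 modalities x 2 gaze conditions), the
semi-partial Spearman correlations between trait z-scores and each
differential score controlling age and amount of gaze, and the
luminance control analyses.  ``run_pipeline`` adds on-disk input and
output handling plus a run manifest with reconciled exclusion
tallies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aoi import EyeAOI, Landmarks, build_eye_aoi
from .config import PipelineConfig, SimConfig, load_sim_config, save_config
from .core import CONDITIONS, DegenerateInputError, SampledStream, SchemaError, validate_events
from .eda import exclude_outlier_trials, extract_phasic, scr_amplitude
from .gaze import preprocess_gaze
from .hr import RRSeries, filter_rr_range, nn_support, remove_ectopic, rr_to_hr, trial_hr_mean
from .luminance import (
    StimulusImage,
    luminance_pupil_correlation,
    mean_luminance,
    paired_luminance_test,
)
from .pupil import preprocess_pupil
from .simulate.build import CohortData
from .stats import differential_score, spearman, spearman_semipartial, wilcoxon_signed_rank

MODALITIES = ("pupil", "hr", "scr")


# ---------------------------------------------------------------------------
# per-participant trial tables


def gaze_trial_table(
    left: SampledStream,
    right: SampledStream,
    events: pd.DataFrame,
    aois: dict[str, EyeAOI] | EyeAOI,
    pcfg: PipelineConfig,
) -> pd.DataFrame:
    from .aoi import points_in_polygon

    stream = preprocess_gaze(left, right, pcfg.gaze_rate_hz)
    t = stream.t
    # slice window samples per trial, then classify one batch per image
    rows = []
    batches: dict[str, list[tuple[int, np.ndarray]]] = {}
    for row in events.itertuples(index=False):
        lo = int(np.searchsorted(t, row.onset_s + pcfg.window_s[0] - 1e-9))
        hi = int(np.searchsorted(t, row.onset_s + pcfg.window_s[1] - 1e-9))
        valid = stream.mask[lo:hi]
        n_total = hi - lo
        n_valid = int(valid.sum())
        rows.append(
            {
                "trial": row.trial,
                "condition": row.condition,
                "stim_pupil": row.stim_pupil,
                "image_id": row.image_id,
                "n_total": n_total,
                "n_missing": n_total - n_valid,
                "n_in_aoi": 0,
                "value": np.nan,
                "valid": n_valid > 0,
            }
        )
        if n_valid:
            key = row.image_id if isinstance(aois, dict) else "__single__"
            batches.setdefault(key, []).append(
                (len(rows) - 1, stream.values[lo:hi][valid])
            )
    for key, entries in batches.items():
        aoi = aois[key] if isinstance(aois, dict) else aois
        pts = np.concatenate([pts for _, pts in entries])
        inside = points_in_polygon(pts, aoi)
        pos = 0
        for ridx, p in entries:
            k = len(p)
            n_in = int(inside[pos : pos + k].sum())
            pos += k
            rows[ridx]["n_in_aoi"] = n_in
            rows[ridx]["value"] = n_in / k
    return pd.DataFrame(rows)


def pupil_trial_table(
    left: SampledStream,
    right: SampledStream,
    events: pd.DataFrame,
    pcfg: PipelineConfig,
) -> tuple[pd.DataFrame, dict[str, int]]:
    trace, support, counts = preprocess_pupil(
        left,
        right,
        rate_hz=pcfg.pupil_rate_hz,
        mad_k=pcfg.mad_k,
        max_gap_samples=pcfg.max_gap_samples,
        pad_samples=pcfg.gap_pad_samples,
        cutoff_hz=pcfg.pupil_lp_cutoff_hz,
        order=pcfg.pupil_lp_order,
        speed_floor=pcfg.mad_speed_floor,
    )
    t = trace.t
    rows = []
    for row in events.itertuples(index=False):
        b_lo = int(np.searchsorted(t, row.onset_s - pcfg.baseline_s - 1e-9))
        b_hi = int(np.searchsorted(t, row.onset_s - 1e-9))
        w_lo = int(np.searchsorted(t, row.onset_s + pcfg.window_s[0] - 1e-9))
        w_hi = int(np.searchsorted(t, row.onset_s + pcfg.window_s[1] - 1e-9))
        base_ok = trace.mask[b_lo:b_hi]
        win_ok = trace.mask[w_lo:w_hi]
        base = (
            float(trace.values[b_lo:b_hi][base_ok].mean()) if base_ok.any() else np.nan
        )
        win_support = float(support[w_lo:w_hi].mean()) if w_hi > w_lo else 0.0
        base_support = float(support[b_lo:b_hi].mean()) if b_hi > b_lo else 0.0
        valid = (
            win_ok.any()
            and np.isfinite(base)
            and win_support >= pcfg.min_valid_fraction
            and base_support > 0.0
        )
        value = (
            float(trace.values[w_lo:w_hi][win_ok].mean()) - base if valid else np.nan
        )
        rows.append(
            {
                "trial": row.trial,
                "condition": row.condition,
                "stim_pupil": row.stim_pupil,
                "image_id": row.image_id,
                "baseline_mean": base,
                "value": value,
                "valid": valid,
            }
        )
    return pd.DataFrame(rows), counts


def scr_trial_table(
    eda_stream: SampledStream, events: pd.DataFrame, pcfg: PipelineConfig
) -> pd.DataFrame:
    phasic = extract_phasic(
        eda_stream,
        resample_hz=pcfg.eda_resample_hz,
        hp_cutoff_hz=pcfg.eda_hp_cutoff_hz,
        hp_order=pcfg.eda_hp_order,
        lp_cutoff_hz=pcfg.eda_lp_cutoff_hz,
        lp_order=pcfg.eda_lp_order,
        hp_zero_lag=pcfg.eda_hp_zero_lag,
    )
    values = [
        scr_amplitude(phasic, row.onset_s, pcfg.window_s, pcfg.baseline_s, row.trial)
        for row in events.itertuples(index=False)
    ]
    if pcfg.scr_outlier_per_condition:
        kept: list = [None] * len(values)
        for cond in CONDITIONS:
            idx = [i for i, r in enumerate(events.itertuples(index=False)) if r.condition == cond]
            sub = exclude_outlier_trials([values[i] for i in idx], pcfg.scr_outlier_z)
            for i, v in zip(idx, sub):
                kept[i] = v
        values = kept
    else:
        values = exclude_outlier_trials(values, pcfg.scr_outlier_z)
    rows = []
    for row, v in zip(events.itertuples(index=False), values):
        rows.append(
            {
                "trial": row.trial,
                "condition": row.condition,
                "stim_pupil": row.stim_pupil,
                "image_id": row.image_id,
                "pre_mean": v.pre_mean,
                "peak": v.peak,
                "value": v.amplitude if not v.excluded else np.nan,
                "valid": not v.excluded and np.isfinite(v.amplitude),
                "reason": v.reason,
            }
        )
    return pd.DataFrame(rows)


def hr_trial_table(
    rr: RRSeries, events: pd.DataFrame, pcfg: PipelineConfig
) -> tuple[pd.DataFrame, dict[str, int]]:
    in_range = filter_rr_range(rr, pcfg.rr_lo_ms, pcfg.rr_hi_ms)
    cleaned = remove_ectopic(in_range, pcfg.ectopic_rel_threshold)
    counts = {
        "rr_intervals": len(rr.rr),
        "masked_range": int(rr.mask.sum() - in_range.mask.sum()),
        "masked_ectopic": int(in_range.mask.sum() - cleaned.mask.sum()),
    }
    hr = rr_to_hr(cleaned, pcfg.hr_resample_hz, pcfg.hr_constant)
    if len(hr) > 1:
        hr.mask &= nn_support(cleaned, hr.t, pcfg.hr_max_beat_gap_s)
    rows = []
    for row in events.itertuples(index=False):
        v = trial_hr_mean(hr, row.onset_s, pcfg.window_s, row.trial)
        rows.append(
            {
                "trial": row.trial,
                "condition": row.condition,
                "stim_pupil": row.stim_pupil,
                "image_id": row.image_id,
                "value": v.hr_mean_bpm if v.valid else np.nan,
                "valid": v.valid,
            }
        )
    return pd.DataFrame(rows), counts


# ---------------------------------------------------------------------------
# cohort-level assembly


def build_trial_tables(
    data: CohortData, pcfg: PipelineConfig
) -> tuple[dict[str, pd.DataFrame], dict[str, dict]]:
    """Per-modality long tables (participant x trial) plus tallies."""
    gaze_rows, pupil_rows, scr_rows, hr_rows = [], [], [], []
    tallies: dict[str, dict] = {"pupil": {}, "hr": {}}
    for p in data.participants:
        events = data.schedules[p.id]
        if p.id in data.gaze:
            gt = gaze_trial_table(*data.gaze[p.id], events, data.aois, pcfg)
            gt.insert(0, "participant", p.id)
            gaze_rows.append(gt)
        if p.id in data.pupil:
            pt, counts = pupil_trial_table(*data.pupil[p.id], events, pcfg)
            pt.insert(0, "participant", p.id)
            pupil_rows.append(pt)
            for k, v in counts.items():
                tallies["pupil"][k] = tallies["pupil"].get(k, 0) + v
        if p.id in data.eda:
            st = scr_trial_table(data.eda[p.id], events, pcfg)
            st.insert(0, "participant", p.id)
            scr_rows.append(st)
        if p.id in data.rr:
            ht, counts = hr_trial_table(data.rr[p.id], events, pcfg)
            ht.insert(0, "participant", p.id)
            hr_rows.append(ht)
            for k, v in counts.items():
                tallies["hr"][k] = tallies["hr"].get(k, 0) + v
    tables = {}
    for name, rows in (
        ("gaze", gaze_rows),
        ("pupil", pupil_rows),
        ("scr", scr_rows),
        ("hr", hr_rows),
    ):
        if rows:
            tables[name] = pd.concat(rows, ignore_index=True)
    return tables, tallies


def differential_scores(trials: pd.DataFrame, modality: str) -> pd.DataFrame:
    rows = []
    for (pid, cond), sub in trials.groupby(["participant", "condition"], sort=True):
        score = differential_score(sub, pid, modality, cond)
        rows.append(
            {
                "participant": pid,
                "modality": modality,
                "condition": cond,
                "mean_large": score.mean_large,
                "mean_small": score.mean_small,
                "diff": score.diff,
                "valid": score.valid,
            }
        )
    return pd.DataFrame(rows)


def gaze_by_participant(gaze_trials: pd.DataFrame) -> pd.DataFrame:
    """Mean proportion of gaze in the eye AOI per participant/condition."""
    sub = gaze_trials[gaze_trials["valid"].astype(bool)]
    return (
        sub.groupby(["participant", "condition"])["value"].mean().rename("gaze").reset_index()
    )


def _wilcoxon_or_none(diffs) -> dict | None:
    try:
        return wilcoxon_signed_rank(np.asarray(diffs, float)).as_dict()
    except DegenerateInputError:
        return None


def analyze_cohort(
    data: CohortData,
    pcfg: PipelineConfig | None = None,
    luminance: bool = False,
) -> dict:
    """Full statistics bundle for a cohort; see module docstring."""
    pcfg = pcfg or PipelineConfig()
    tables, tallies = build_trial_tables(data, pcfg)
    participants = data.participant_frame().set_index("id")
    results: dict = {"n_participants": len(data.participants), "exclusions": tallies}

    gaze_wide = None
    if "gaze" in tables:
        gp = gaze_by_participant(tables["gaze"])
        gaze_wide = gp.pivot(index="participant", columns="condition", values="gaze")
        paired = gaze_wide.dropna()
        res: dict = {
            "cross_median": float(gaze_wide["CROSS"].median())
            if "CROSS" in gaze_wide
            else None,
            "nocross_median": float(gaze_wide["NO_CROSS"].median())
            if "NO_CROSS" in gaze_wide
            else None,
        }
        if {"CROSS", "NO_CROSS"} <= set(paired.columns) and len(paired) > 0:
            res["wilcoxon_cross_vs_nocross"] = _wilcoxon_or_none(
                paired["CROSS"] - paired["NO_CROSS"]
            )
        for cond in CONDITIONS:
            if cond in gaze_wide:
                merged = gaze_wide[cond].dropna()
                ages = participants.loc[merged.index, "age_months"]
                try:
                    res[f"age_corr_{cond}"] = spearman(ages, merged).as_dict()
                except DegenerateInputError as exc:
                    res[f"age_corr_{cond}"] = {"error": str(exc)}
        results["gaze"] = res

    diffs_all: dict[str, pd.DataFrame] = {}
    contagion: dict = {}
    for modality in MODALITIES:
        if modality not in tables:
            continue
        d = differential_scores(tables[modality], modality)
        diffs_all[modality] = d
        per_cond: dict = {}
        for cond in CONDITIONS:
            sub = d[(d["condition"] == cond) & d["valid"]].dropna(subset=["diff"])
            entry: dict = {
                "n": int(len(sub)),
                "mean_diff": float(sub["diff"].mean()) if len(sub) else None,
            }
            if len(sub) >= 2:
                entry["wilcoxon"] = _wilcoxon_or_none(sub["diff"])
            per_cond[cond] = entry
        contagion[modality] = per_cond
    results["contagion"] = contagion

    # Table-1-style semi-partial correlations: trait z vs differential
    # score, controlling age and amount of gaze (condition-specific).
    aq_corr: dict = {}
    for modality, d in diffs_all.items():
        per_cond = {}
        for cond in CONDITIONS:
            sub = d[(d["condition"] == cond) & d["valid"]].set_index("participant")
            if len(sub) == 0:
                continue
            idx = sub.index
            x = participants.loc[idx, "aq_z"].to_numpy()
            y = sub["diff"].to_numpy()
            cov = [participants.loc[idx, "age_months"].to_numpy()]
            names = ["age_months"]
            if gaze_wide is not None:
                if pcfg.gaze_covariate_per_condition and cond in gaze_wide:
                    cov.append(gaze_wide.reindex(idx)[cond].to_numpy())
                    names.append(f"gaze_{cond}")
                elif not pcfg.gaze_covariate_per_condition:
                    cov.append(gaze_wide.reindex(idx).mean(axis=1).to_numpy())
                    names.append("gaze_pooled")
            try:
                corr = spearman_semipartial(
                    x,
                    y,
                    np.column_stack(cov),
                    residualize=pcfg.semipartial_residualize,
                    covariate_names=names,
                )
                per_cond[cond] = corr.as_dict()
            except DegenerateInputError as exc:
                per_cond[cond] = {"error": str(exc)}
        aq_corr[modality] = per_cond
    results["aq_correlations"] = aq_corr

    if luminance and "pupil" in tables:
        results["luminance"] = luminance_analysis(data, tables["pupil"], pcfg)
    return results


def luminance_analysis(
    data: CohortData, pupil_trials: pd.DataFrame, pcfg: PipelineConfig
) -> dict:
    """Paired large/small luminance comparison and the luminance-pupil
    control correlation, per gaze condition."""
    from .simulate.stimuli import render_stimulus

    cfg = data.config
    out: dict = {}
    rows = []
    for cond in CONDITIONS:
        pairs = []
        lum_diff = {}
        for actor in range(cfg.n_stimulus_pairs):
            lums = {}
            for size in ("large", "small"):
                image_id = f"face{actor:02d}_{size}"
                img = StimulusImage(
                    image_id, render_stimulus(cfg, actor, size, cross=cond == "CROSS")
                )
                aoi = data.aois[image_id]
                lums[size] = mean_luminance(img, aoi)
                rows.append(
                    {
                        "image_id": image_id,
                        "condition": cond,
                        "pupil_size": size,
                        "whole_mean": mean_luminance(img),
                        "eyes_aoi_mean": lums[size],
                    }
                )
            pairs.append((lums["large"], lums["small"]))
            lum_diff[actor] = lums["large"] - lums["small"]
        entry: dict = {}
        try:
            entry["paired_wilcoxon"] = paired_luminance_test(pairs).as_dict()
        except DegenerateInputError as exc:
            entry["paired_wilcoxon"] = {"error": str(exc)}

        sub = pupil_trials[(pupil_trials["condition"] == cond) & pupil_trials["valid"]]
        if len(sub):
            actor_of = sub["image_id"].str.slice(4, 6).astype(int)
            by = sub.assign(actor=actor_of).groupby(["actor", "stim_pupil"])["value"].mean()
            pupil_diffs, image_diffs = [], []
            for actor in range(cfg.n_stimulus_pairs):
                try:
                    pd_diff = by[(actor, "large")] - by[(actor, "small")]
                except KeyError:
                    continue
                pupil_diffs.append(pd_diff)
                image_diffs.append(lum_diff[actor])
            if len(pupil_diffs) >= 4:
                try:
                    entry["luminance_pupil_corr"] = luminance_pupil_correlation(
                        image_diffs, pupil_diffs
                    ).as_dict()
                except DegenerateInputError as exc:
                    entry["luminance_pupil_corr"] = {"error": str(exc)}
        out[cond] = entry
    out["table"] = rows
    return out


# ---------------------------------------------------------------------------
# on-disk cohort loading and the run manifest


def _read_stream_csv(path: Path, time_col: str = "t") -> pd.DataFrame:
    df = pd.read_csv(path)
    if time_col not in df.columns:
        raise SchemaError(f"{path}: missing required column {time_col!r}")
    t = df[time_col].to_numpy(float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        raise SchemaError(f"{path}: non-increasing timestamp at row {int(bad[0]) + 2}")
    return df


def load_cohort(cohort_dir: str | Path) -> CohortData:
    """Load a cohort from the plain-text layout written by
    :func:`contagionkit.simulate.write_cohort`, with schema checks."""
    from .simulate.cohort import Participant

    root = Path(cohort_dir)
    if not (root / "participants.tsv").exists():
        raise SchemaError(f"{root}: participants.tsv not found")
    config = (
        load_sim_config(root / "config.yaml")
        if (root / "config.yaml").exists()
        else SimConfig()
    )
    pdf = pd.read_csv(root / "participants.tsv", sep="\t")
    required = {"id", "age_months", "aq_raw", "aq_version", "aq_z", "diagnosis"}
    missing = required - set(pdf.columns)
    if missing:
        raise SchemaError(f"participants.tsv missing columns: {sorted(missing)}")
    participants = [
        Participant(
            id=str(r.id),
            age_months=float(r.age_months),
            aq_raw=int(r.aq_raw),
            aq_version=str(r.aq_version),
            aq_z=float(r.aq_z),
            diagnosis=bool(r.diagnosis),
        )
        for r in pdf.itertuples(index=False)
    ]

    landmarks: dict[str, Landmarks] = {}
    aois: dict[str, EyeAOI] = {}
    lm_dir = root / "landmarks"
    if lm_dir.is_dir():
        for f in sorted(lm_dir.glob("*.json")):
            lm = Landmarks.load(f)
            landmarks[lm.image_id] = lm
            aois[lm.image_id] = build_eye_aoi(lm)

    data = CohortData(config, participants, landmarks, aois, {})
    for p in participants:
        pdir = root / p.id
        data.schedules[p.id] = validate_events(pd.read_csv(pdir / "events.tsv", sep="\t"))
        gaze_f = pdir / "gaze.csv"
        if gaze_f.exists():
            df = _read_stream_csv(gaze_f)
            t = df["t"].to_numpy(float)
            left = SampledStream(
                t, df[["lx", "ly"]].to_numpy(float), df["valid_l"].to_numpy(bool)
            )
            right = SampledStream(
                t, df[["rx", "ry"]].to_numpy(float), df["valid_r"].to_numpy(bool)
            )
            data.gaze[p.id] = (left, right)
        pupil_f = pdir / "pupil.csv"
        if pupil_f.exists():
            df = _read_stream_csv(pupil_f)
            t = df["t"].to_numpy(float)
            data.pupil[p.id] = (
                SampledStream(t, df["dl"].to_numpy(float)),
                SampledStream(t, df["dr"].to_numpy(float)),
            )
        eda_f = pdir / "eda.csv"
        if eda_f.exists():
            df = _read_stream_csv(eda_f)
            data.eda[p.id] = SampledStream(
                df["t"].to_numpy(float), df["us"].to_numpy(float)
            )
        rr_f = pdir / "rr.csv"
        if rr_f.exists():
            df = _read_stream_csv(rr_f)
            data.rr[p.id] = RRSeries(df["t"].to_numpy(float), df["rr_ms"].to_numpy(float))
    return data


def run_pipeline(
    data: CohortData,
    out_dir: str | Path,
    pcfg: PipelineConfig | None = None,
    luminance: bool = True,
) -> dict:
    """Analyze a cohort and write results, stage tables and manifest."""
    pcfg = pcfg or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    tables, tallies = build_trial_tables(data, pcfg)
    results = analyze_cohort(data, pcfg, luminance=luminance)
    for name, tbl in tables.items():
        tbl.to_csv(out / f"{name}_trials.tsv", sep="\t", index=False)
    save_config(pcfg, out / "pipeline_config.yaml")
    (out / "results.json").write_text(json.dumps(results, indent=1, default=float))

    cfg_text = yaml.safe_dump(asdict(data.config), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "pipeline_config": asdict(pcfg),
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "n_participants": len(data.participants),
        "row_counts": {k: int(len(v)) for k, v in tables.items()},
        "exclusions": tallies,
    }
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=1, default=float))
    tmp.replace(out / "manifest.json")  # atomic finalize
    return results
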