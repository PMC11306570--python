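"""Synthetic cohort generator: design invariants, determinism, noise
model characteristics, and known-truth effect placement."""

import numpy as np
import pandas as pd
import pytest

from contagionkit import PipelineConfig, SimConfig
from contagionkit.core import InvalidConfigError
from contagionkit.hr import filter_rr_range, remove_ectopic
from contagionkit.pipeline import hr_trial_table, pupil_trial_table, scr_trial_table
from contagionkit.simulate import (
    generate_cohort,
    generate_schedule,
    cohort_frame,
    simulate_eda,
    simulate_gaze,
    simulate_pupil,
    simulate_rr,
    solve_aq_coupling,
)
from contagionkit.simulate.build import simulate_cohort
from contagionkit.simulate.stimuli import generate_landmarks
from contagionkit.aoi import build_eye_aoi
from contagionkit.stats import spearman


class TestCohort:
    def test_deterministic_for_fixed_seed(self):
        cfg = SimConfig(seed=1)
        a = cohort_frame(generate_cohort(cfg))
        b = cohort_frame(generate_cohort(cfg))
        pd.testing.assert_frame_equal(a, b)

    def test_diagnosed_oversampling(self):
        cohort = generate_cohort(SimConfig(n_participants=66, seed=2))
        assert sum(p.diagnosis for p in cohort) == 22

    def test_trait_mean_matches_mixture(self):
        cfg = SimConfig(n_participants=1000, seed=7)
        z = np.array([p.aq_z for p in generate_cohort(cfg)])
        assert abs(z.mean() - cfg.aq_z_mean) < 0.2

    def test_age_bounds_and_versions(self):
        for p in generate_cohort(SimConfig(n_participants=200, seed=3)):
            assert 72 <= p.age_months <= 216
            assert p.aq_version in ("child", "adolescent", "adult")

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimConfig(n_participants=1)


class TestSchedule:
    def test_default_design_counts(self):
        sched = generate_schedule(SimConfig(), seed=4)
        assert len(sched) == 64
        assert sched["block"].nunique() == 8
        assert (sched.groupby("block").size() == 8).all()
        by_cond = sched.drop_duplicates("block")["condition"].value_counts()
        assert by_cond["CROSS"] == 4 and by_cond["NO_CROSS"] == 4

    def test_blocks_homogeneous_and_timed(self):
        cfg = SimConfig()
        sched = generate_schedule(cfg, seed=5)
        for _, block in sched.groupby("block"):
            assert block["emotion"].nunique() == 1
            assert block["stim_pupil"].nunique() == 1
            onsets = block["onset_s"].to_numpy()
            np.testing.assert_allclose(np.diff(onsets), 7.0)  # 6 s + 1 s ISI
            # first trial follows the 10 s block fixation
            assert (onsets[0] - (block["block"].iloc[0]) * cfg.block_duration_s) == 10.0
        assert (sched["duration_s"] == 6.0).all()

    def test_seed_permutes_but_preserves_cells(self):
        a = generate_schedule(SimConfig(), seed=6)
        b = generate_schedule(SimConfig(), seed=7)
        cells = lambda s: sorted(  # noqa: E731
            map(tuple, s[["condition", "emotion", "stim_pupil"]].to_numpy())
        )
        assert cells(a) == cells(b)
        assert not a.equals(b)


class TestStreams:
    def test_full_determinism(self, small_config):
        a = simulate_cohort(small_config, modalities=("pupil", "gaze"))
        b = simulate_cohort(small_config, modalities=("pupil", "gaze"))
        pid = a.participants[0].id
        np.testing.assert_array_equal(a.pupil[pid][0].values, b.pupil[pid][0].values)
        np.testing.assert_array_equal(a.gaze[pid][1].values, b.gaze[pid][1].values)

    def test_null_pupil_config_no_condition_difference(self):
        # with every effect zero, large- and small-trial window means
        # are exchangeable: the mean difference across seeds is ~0
        cfg = SimConfig(n_participants=2, seed=0).null_effects()
        pcfg = PipelineConfig()
        diffs = []
        for seed in range(6):
            p = generate_cohort(cfg.replace(seed=seed))[0]
            sched = generate_schedule(cfg, seed + 50)
            tbl, _ = pupil_trial_table(
                *simulate_pupil(p, sched, cfg, seed), sched, pcfg
            )
            ok = tbl[tbl.valid]
            diffs.append(
                ok[ok.stim_pupil == "large"].value.mean()
                - ok[ok.stim_pupil == "small"].value.mean()
            )
        assert abs(np.mean(diffs)) < 0.08

    def test_blink_missing_fraction_in_band(self, small_config):
        p = generate_cohort(small_config)[0]
        sched = generate_schedule(small_config, 9)
        left, _right = simulate_pupil(p, sched, small_config, 21)
        missing = 1.0 - left.mask.mean()
        assert 0.10 < missing < 0.35

    def test_saturated_gaze_bias_gives_proportion_one(self, small_config):
        cfg = small_config.without_noise().replace(cross_gaze_median=1.0)
        p = generate_cohort(cfg)[0]
        sched = generate_schedule(cfg, 10)
        lm = generate_landmarks(cfg, 0)
        aoi = build_eye_aoi(lm)
        left, right = simulate_gaze(p, sched, aoi, cfg, 30)
        from contagionkit.pipeline import gaze_trial_table

        table = gaze_trial_table(left, right, sched, aoi, PipelineConfig())
        cross = table[table.condition == "CROSS"]
        assert cross["value"].min() == 1.0

    def test_gaze_age_gradient_positive(self):
        # model-level: realized eye-looking probability correlates
        # positively with age across the cohort in nearly every seed
        from contagionkit.simulate.streams import gaze_eye_probability

        cfg = SimConfig(n_participants=66)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cohort = generate_cohort(cfg.replace(seed=seed))
            props = [
                gaze_eye_probability(p, "CROSS", cfg, rng.normal(0, cfg.gaze_subject_sd))
                for p in cohort
            ]
            ages = [p.age_months for p in cohort]
            if spearman(ages, props).rho > 0:
                hits += 1
        assert hits >= 95

    def test_tonic_only_eda_has_flat_phasic(self, small_config):
        cfg = small_config.without_noise().replace(scr_contagion_us=0.0)
        sched = generate_schedule(cfg, 11)
        eda = simulate_eda(sched, cfg, 12)
        from contagionkit.eda import extract_phasic

        out = extract_phasic(eda)
        n = len(out.phasic)
        assert np.abs(out.phasic[n // 4 : 3 * n // 4]).max() < 3 * 0.01

    def test_artifact_rate_produces_sd_outliers(self, small_config):
        sched = generate_schedule(small_config, 13)
        eda = simulate_eda(sched, small_config, 14)
        table = scr_trial_table(eda, sched, PipelineConfig())
        assert (~table["valid"]).sum() >= 1

    def test_constant_rr_gives_75_bpm(self, small_config):
        cfg = small_config.without_noise().replace(
            hr_contagion_bpm=0.0, rr_rest_mean_ms=800.0, rr_rest_sd_ms=0.0
        )
        sched = generate_schedule(cfg, 15)
        rr = simulate_rr(sched, cfg, 16)
        table, _ = hr_trial_table(rr, sched, PipelineConfig())
        np.testing.assert_allclose(table["value"].to_numpy(), 75.0, atol=1e-9)

    def test_ectopic_injection_recovered_exactly(self, small_config):
        cfg = small_config.without_noise().replace(ectopic_rate_hz=0.02)
        sched = generate_schedule(cfg, 17)
        rr = simulate_rr(sched, cfg, 18)
        cleaned = remove_ectopic(filter_rr_range(rr))
        assert set(np.flatnonzero(~cleaned.mask)) == set(rr.attrs["ectopic_idx"])

    def test_out_of_range_injection_caught_by_range_filter(self, small_config):
        cfg = small_config.without_noise().replace(rr_outlier_rate_hz=0.01)
        sched = generate_schedule(cfg, 19)
        rr = simulate_rr(sched, cfg, 20)
        truth = set(rr.attrs["range_idx"])
        assert truth  # the injection rate yields at least one
        flagged = set(np.flatnonzero(~filter_rr_range(rr).mask))
        assert flagged == truth


class TestCoupling:
    def test_beta_zero_when_target_or_effect_zero(self):
        assert solve_aq_coupling(SimConfig(aq_contagion_rho=0.0)) == 0.0
        assert solve_aq_coupling(SimConfig(pupil_contagion_mm=0.0)) == 0.0

    def test_beta_reproduces_target_rank_correlation(self):
        from contagionkit.studies import semipartial_recovery_measure_level

        res = semipartial_recovery_measure_level(SimConfig(), n_seeds=20, base_seed=77)
        assert abs(res["mean_rho"] - 0.28) < 0.10
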