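"""Synthetic cohort generator: determinism, effects, on-disk layout."""

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from painfusion.cohort import (
    GeneratorConfig,
    day_bp_deltas,
    generate_dataset,
    generate_subject,
    generate_timeline,
    render_window,
    simulate_features,
    synthesize_recording,
    window_latent_features,
)
from painfusion.features import assemble_session_features, mean_slope
from painfusion.modalities import AU_NAMES, SAMPLING_RATES


def _zero_effect_config(**kw) -> GeneratorConfig:
    cfg = GeneratorConfig(**kw)
    cfg.effect_sizes = {k: 0.0 for k in cfg.effect_sizes}
    cfg.eeg_region_effects = {}
    return cfg


def _fixed_profile(cfg, seed=0):
    return generate_subject(seed, cfg)


class TestGenerateSubject:
    def test_same_seed_identical_profiles(self):
        cfg = GeneratorConfig()
        a = generate_subject(1, cfg)
        b = generate_subject(1, cfg)
        assert a == b

    def test_zero_random_effects_give_identical_baselines(self):
        cfg = GeneratorConfig()
        cfg.random_effect_sd = {k: 0.0 for k in cfg.random_effect_sd}
        profiles = [generate_subject(s, cfg) for s in range(5)]
        for p in profiles[1:]:
            assert p.baseline_means == profiles[0].baseline_means

    def test_sensitivity_lognormal_law_of_large_numbers(self):
        cfg = GeneratorConfig()
        logs = np.log([generate_subject(s, cfg).sensitivity
                       for s in range(1000)])
        se = cfg.sensitivity_log_sd / np.sqrt(1000)
        assert abs(logs.mean()) < 3 * se

    def test_nonfinite_config_rejected(self):
        cfg = GeneratorConfig()
        cfg.noise_sd["sc"] = np.nan
        with pytest.raises(ValueError):
            generate_subject(0, cfg)


class TestGenerateTimeline:
    def test_zero_sensitivity_gives_all_zero_ratings(self):
        cfg = GeneratorConfig(day1_rating_shift=0.0)
        prof = dataclasses.replace(_fixed_profile(cfg), sensitivity=0.0)
        tl = generate_timeline(prof, 1, cfg, seed=3)
        assert tl.vrs == (0,) * cfg.max_sessions
        assert tl.n_sessions == 10 and not tl.withdrew_early

    def test_max_tolerance_runs_all_ten_sessions(self):
        cfg = GeneratorConfig()
        prof = dataclasses.replace(_fixed_profile(cfg), tolerance=10.0)
        for seed in range(5):
            tl = generate_timeline(prof, 2, cfg, seed=seed)
            assert tl.n_sessions == 10 and not tl.withdrew_early

    def test_windows_are_contiguous_20s(self):
        cfg = GeneratorConfig()
        tl = generate_timeline(_fixed_profile(cfg), 2, cfg, seed=0)
        assert tl.baseline_window == (0.0, 20.0)
        prev_end = 20.0
        for lo, hi in tl.session_windows:
            assert lo == prev_end and hi - lo == 20.0
            prev_end = hi

    def test_day1_ratings_exceed_day2_on_average(self):
        cfg = GeneratorConfig()
        prof = _fixed_profile(cfg)
        d1 = [np.mean(generate_timeline(prof, 1, cfg, seed=s).vrs)
              for s in range(500)]
        d2 = [np.mean(generate_timeline(prof, 2, cfg, seed=10_000 + s).vrs)
              for s in range(500)]
        t, p = stats.ttest_ind(d1, d2, alternative="greater")
        assert p < 0.01


class TestSynthesizeRecording:
    def test_sc_effect_recovery_from_rendered_windows(self):
        # configured standardized shift of 1.0 recovered within +/-0.2
        cfg = GeneratorConfig()
        cfg.effect_sizes["sc"] = 1.0
        cfg.random_effect_sd = {k: 0.0 for k in cfg.random_effect_sd}
        prof = _fixed_profile(cfg)
        rng = np.random.default_rng(11)
        fs = SAMPLING_RATES["sc"]
        means = {0: [], 1: []}
        for code in (0, 1):
            for _ in range(200):
                latent = window_latent_features(prof, code, cfg, rng)
                w = render_window("sc", latent, cfg, rng)[:, 0]
                means[code].append(mean_slope(w, fs)[0])
        a, b = np.asarray(means[0]), np.asarray(means[1])
        pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2)
        smd = (b.mean() - a.mean()) / pooled
        assert smd == pytest.approx(1.0, abs=0.2)

    def test_null_generator_ks_calibration(self):
        # with zero effects, baseline vs high-pain SC feature samples are
        # exchangeable: KS rejects at ~nominal 5% rate
        cfg = _zero_effect_config()
        prof = _fixed_profile(cfg)
        rejections = 0
        reps = 200
        rng = np.random.default_rng(21)
        for _ in range(reps):
            a = [window_latent_features(prof, 0, cfg, rng)["sc.mean"]
                 for _ in range(200)]
            b = [window_latent_features(prof, 2, cfg, rng)["sc.mean"]
                 for _ in range(200)]
            if stats.ks_2samp(a, b).pvalue < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.09

    def test_fe_recording_shape_and_range(self):
        cfg = GeneratorConfig()
        prof = _fixed_profile(cfg)
        tl = generate_timeline(prof, 1, cfg, seed=0)
        rec = synthesize_recording(prof, tl, "fe", cfg, seed=5)
        assert rec.channels == AU_NAMES
        assert rec.samples.shape == (int(tl.duration_s * 30), 17)
        assert rec.samples.min() >= 0.0 and rec.samples.max() <= 1.0

    def test_sample_counts_match_rate_and_duration(self):
        cfg = GeneratorConfig(max_sessions=2)
        prof = _fixed_profile(cfg)
        tl = generate_timeline(dataclasses.replace(prof, tolerance=10.0),
                               2, cfg, seed=1)
        for m in ("eeg", "em", "sc", "bvp", "emg", "rr", "st"):
            rec = synthesize_recording(prof, tl, m, cfg, seed=2)
            expected = int(tl.duration_s * SAMPLING_RATES[m])
            assert abs(len(rec.samples) - expected) <= 1

    def test_bp_is_exactly_two_readings(self):
        cfg = GeneratorConfig()
        prof = _fixed_profile(cfg)
        tl = generate_timeline(prof, 1, cfg, seed=0)
        rec = synthesize_recording(prof, tl, "bp", cfg, seed=0)
        assert rec.samples.shape == (2, 2)
        assert rec.sampling_rate is None

    def test_systolic_delta_positive_on_average(self):
        cfg = GeneratorConfig()
        prof = _fixed_profile(cfg)
        rng = np.random.default_rng(0)
        deltas = [day_bp_deltas(prof, cfg, rng)[0] for _ in range(200)]
        assert np.mean(deltas) > 0

    def test_unknown_modality_rejected(self):
        cfg = GeneratorConfig()
        prof = _fixed_profile(cfg)
        tl = generate_timeline(prof, 1, cfg, seed=0)
        with pytest.raises(ValueError):
            synthesize_recording(prof, tl, "ecg", cfg, seed=0)


class TestSimulateFeatures:
    def test_deterministic_given_seed(self):
        cfg = GeneratorConfig(n_subjects=3, n_days=1)
        a = simulate_features(cfg, seed=9)
        b = simulate_features(cfg, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_one_row_per_window_and_labels(self):
        cfg = GeneratorConfig(n_subjects=2, n_days=2)
        df = simulate_features(cfg, seed=1)
        counts = df.groupby(["subject", "day"])["window"].count()
        assert (counts >= 2).all() and (counts <= 11).all()
        assert set(df["label"]) <= {"B", "LP", "HP"}
        assert (df[df["window"] == 0]["label"] == "B").all()

    def test_default_cohort_size(self):
        cfg = GeneratorConfig()
        assert cfg.n_subjects == 26 and cfg.n_days == 3


class TestGenerateDataset:
    def test_structure_two_subjects_one_day(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=2, n_days=1, max_sessions=2)
        manifest = generate_dataset(cfg, tmp_path, seed=4)
        assert len(manifest["recordings"]) == 2
        for entry in manifest["recordings"]:
            day_dir = tmp_path / entry["path"]
            for fname in ("eeg.csv", "em.csv", "fe.csv", "physio.csv",
                          "bp.csv", "ratings.csv"):
                assert (day_dir / fname).exists()
        assert json.loads((tmp_path / "manifest.json").read_text())[
            "schema_version"] == 1

    def test_same_seed_byte_identical_tree(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=1, n_days=1, max_sessions=3)

        def tree_hashes(root: Path) -> dict[str, str]:
            return {
                str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted(root.rglob("*")) if p.is_file()
            }

        generate_dataset(cfg, tmp_path / "a", seed=13)
        generate_dataset(cfg, tmp_path / "b", seed=13)
        assert tree_hashes(tmp_path / "a") == tree_hashes(tmp_path / "b")

    def test_roundtrip_through_feature_assembly(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=1, n_days=1, max_sessions=4)
        generate_dataset(cfg, tmp_path, seed=8)
        feats = assemble_session_features(tmp_path)
        ratings = pd.read_csv(
            tmp_path / "subject_S01" / "day_1" / "ratings.csv")
        assert len(feats) == len(ratings) + 1  # baseline + sessions
        # extracted SC means sit in a plausible range around the baseline
        assert feats["sc.mean"].between(0, 20).all()
        assert feats.loc[0, "label"] == "B"

    def test_disabled_modality_omits_columns(self, tmp_path):
        cfg = GeneratorConfig(
            n_subjects=1, n_days=1, max_sessions=2,
            modalities=("fe", "sc", "bvp", "emg", "rr", "st", "bp"),
        )
        generate_dataset(cfg, tmp_path, seed=2)
        feats = assemble_session_features(tmp_path)
        assert not any(c.startswith("em.") for c in feats.columns)
        assert not any(c.startswith("eeg.") for c in feats.columns)

    def test_missing_modality_file_rejected(self, tmp_path):
        cfg = GeneratorConfig(n_subjects=1, n_days=1, max_sessions=2)
        generate_dataset(cfg, tmp_path, seed=2)
        (tmp_path / "subject_S01" / "day_1" / "em.csv").unlink()
        from painfusion.features import SchemaError
        with pytest.raises(SchemaError):
            assemble_session_features(tmp_path)
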