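"""Feature table, correlation, clustering and task-contrast tests."""

import numpy as np
import pandas as pd
import pytest

from hjortheeg import (
    TaskCode,
    Trial,
    build_feature_table,
    cluster_features,
    electrode_correlation,
    feature_correlation,
    generate_trial,
    permutation_null_agreement,
    task_contrast,
)
from hjortheeg.analysis import FEATURE_COLUMNS


def _trial(data, task=TaskCode.REST, subject="S01", index=0):
    return Trial(data=data, sampling_rate=125.0, task=task, subject=subject, trial_index=index)


def _synthetic_table(n_rows=1000, seed=0, tasks=("Rest", "CRH")):
    """Feature table with independent feature columns (no real signals)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "subject": "S01",
        "task": np.resize(list(tasks), n_rows),
        "trial": np.arange(n_rows) // 16,
        "electrode": (np.arange(n_rows) % 16) + 1,
        "window_start": 0,
        "activity": rng.gamma(2.0, 50.0, size=n_rows),
        "mobility": rng.uniform(0.3, 1.4, size=n_rows),
        "complexity": rng.uniform(1.1, 3.0, size=n_rows),
    })


class TestBuildFeatureTable:
    def test_row_count_windowed(self, rng):
        trials = [_trial(rng.normal(size=(16, 500)), index=i) for i in range(2)]
        table = build_feature_table(trials, window_length=125, hop=125)
        assert len(table) == 2 * 16 * 4
        assert list(table.columns) == [
            "subject", "task", "trial", "electrode", "window_start",
            "activity", "mobility", "complexity",
        ]

    def test_full_trial_mode_one_row_per_electrode(self, rng):
        trials = [_trial(rng.normal(size=(16, 500)))]
        assert len(build_feature_table(trials)) == 16

    def test_flat_channel_rows_present_with_sentinel(self, rng, caplog):
        data = rng.normal(size=(16, 500))
        data[4] = 0.0
        with caplog.at_level("WARNING"):
            table = build_feature_table([_trial(data)], window_length=125, hop=125)
        flagged = table[table["mobility"].isna()]
        assert set(flagged["electrode"]) == {5}
        assert len(flagged) == 4  # one per window
        assert "4 rows" in caplog.text

    def test_inconsistent_sampling_rates_rejected(self, rng):
        a = _trial(rng.normal(size=(4, 100)))
        b = Trial(data=rng.normal(size=(4, 100)), sampling_rate=250.0,
                  task=TaskCode.REST, subject="S01")
        with pytest.raises(ValueError, match="sampling rates"):
            build_feature_table([a, b])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_feature_table([])


class TestFeatureCorrelation:
    def test_symmetric_unit_diagonal_bounded(self):
        corr = feature_correlation(_synthetic_table()).matrix
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)
        assert (corr.to_numpy() <= 1.0).all() and (corr.to_numpy() >= -1.0).all()

    def test_identical_columns_correlate_to_one(self):
        table = _synthetic_table()
        table["complexity"] = table["mobility"]
        corr = feature_correlation(table).matrix
        assert corr.loc["mobility", "complexity"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        corr = feature_correlation(_synthetic_table(n_rows=10_000, seed=3)).matrix
        off_diagonal = corr.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.abs(off_diagonal).max() < 0.05

    def test_missing_rows_excluded_listwise(self):
        table = _synthetic_table(n_rows=100)
        table.loc[:9, "mobility"] = np.nan
        assert feature_correlation(table).n_rows == 90

    def test_too_few_complete_rows_rejected(self):
        table = _synthetic_table(n_rows=5)
        table.loc[:2, "activity"] = np.nan
        with pytest.raises(ValueError, match="complete rows"):
            feature_correlation(table)

    def test_zero_variance_column_named(self):
        table = _synthetic_table()
        table["activity"] = 1.0
        with pytest.raises(ValueError, match="activity"):
            feature_correlation(table)

    def test_electrode_correlation_shape(self):
        corr = electrode_correlation(_synthetic_table(n_rows=320), feature="activity")
        assert corr.shape == (16, 16)
        assert np.allclose(np.diag(corr), 1.0)


class TestClusterFeatures:
    def test_two_task_recovery_with_default_generator(self, rest_and_crh_trials):
        table = build_feature_table(rest_and_crh_trials)
        result = cluster_features(table, k=2, seed=11)
        assert result.agreement >= 0.9

    def test_row_permutation_invariance(self):
        table = _synthetic_table(n_rows=200, seed=5)
        shuffled = table.sample(frac=1.0, random_state=9)
        a = cluster_features(table, k=3, seed=1)
        b = cluster_features(shuffled, k=3, seed=1)
        assert a.agreement == b.agreement
        assert np.array_equal(a.assignments.to_numpy(), b.assignments.to_numpy())

    def test_k_equal_to_rows_gives_singletons(self):
        table = _synthetic_table(n_rows=12, seed=2)
        result = cluster_features(table, k=12, seed=0)
        assert len(set(result.assignments)) == 12
        assert np.isfinite(result.agreement)

    def test_k_larger_than_complete_rows_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_features(_synthetic_table(n_rows=10), k=11, seed=0)

    def test_missing_rows_dropped_before_clustering(self):
        table = _synthetic_table(n_rows=60, seed=4)
        table.loc[:4, "complexity"] = np.nan
        result = cluster_features(table, k=2, seed=0)
        assert len(result.assignments) == 55

    def test_eight_task_agreement_beats_permutation_null(self, config):
        trials = []
        for task in TaskCode:
            trials += [generate_trial(config, task, "S01", i) for i in range(6)]
        table = build_feature_table(trials)
        result = cluster_features(table, k=8, seed=3)
        null = permutation_null_agreement(table, result, n_permutations=200, seed=3)
        assert result.agreement > np.percentile(null, 95)


class TestTaskContrast:
    def test_movement_activity_above_rest_everywhere(self, rest_and_crh_trials):
        table = build_feature_table(rest_and_crh_trials)
        contrast = task_contrast(table, TaskCode.CRH, TaskCode.REST)
        assert (contrast["activity_mean_diff"] > 0).all()
        assert (contrast["activity_ratio"] > 1).all()

    def test_rest_elevated_electrodes_flagged(self, rest_and_crh_trials):
        table = build_feature_table(rest_and_crh_trials)
        contrast = task_contrast(table, TaskCode.CRH, TaskCode.REST)
        assert set(contrast.index[contrast["high_amplitude_b"]]) == {14, 15}

    def test_same_task_contrast_is_exactly_zero(self, rest_and_crh_trials):
        table = build_feature_table(rest_and_crh_trials[:10])
        contrast = task_contrast(table, TaskCode.REST, TaskCode.REST)
        for feature in FEATURE_COLUMNS:
            assert (contrast[f"{feature}_mean_diff"] == 0.0).all()

    def test_single_trial_per_task_flags_undefined_effect(self, config):
        trials = [generate_trial(config, TaskCode.REST, "S01", 0),
                  generate_trial(config, TaskCode.CRH, "S01", 0)]
        contrast = task_contrast(build_feature_table(trials), TaskCode.CRH, TaskCode.REST)
        assert contrast["activity_cohens_d"].isna().all()
        assert np.isfinite(contrast["activity_mean_diff"]).all()

    def test_absent_task_rejected(self, rest_and_crh_trials):
        table = build_feature_table(rest_and_crh_trials)
        with pytest.raises(ValueError, match="PLF"):
            task_contrast(table, TaskCode.PLF, TaskCode.REST)


def test_pipeline_idempotent_over_csv_round_trip(config, tmp_path):
    """CSV round-tripping the trials changes no analysis output."""
    from hjortheeg import load_session, write_trial_csv

    trials = [generate_trial(config, t, "S01", i)
              for i, t in enumerate([TaskCode.REST, TaskCode.CRH] * 5)]
    rows = []
    for i, trial in enumerate(trials):
        name = f"t{i}.csv"
        write_trial_csv(trial, tmp_path / name)
        rows.append((name, trial.subject, trial.task.value))
    manifest = pd.DataFrame(rows, columns=["filename", "subject", "task"])
    reloaded = load_session(tmp_path, manifest)

    before = build_feature_table(trials, window_length=125, hop=25)
    after = build_feature_table(reloaded, window_length=125, hop=25)
    pd.testing.assert_frame_equal(before, after)
    assert cluster_features(before, k=2, seed=1).agreement == \
        cluster_features(after, k=2, seed=1).agreement
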