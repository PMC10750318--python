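"""Feature-table assembly, correlation analysis, clustering and task contrasts.

The feature table is a long-form :class:`pandas.DataFrame` with one row
per (subject, task, trial, electrode, window_start) and the three Hjorth
parameters as columns.  Downstream analyses are the minimal standard
reading of "correlation analysis and clustering behaviour":

* Pearson correlation between the three features over complete rows;
* k-means (standardized features, fixed seed, 10 restarts) with the
  adjusted Rand index against the task labels as agreement statistic;
* descriptive per-electrode contrasts between two tasks (mean
  difference, activity ratio of means, Cohen's d).

Rows carrying the missing-value sentinel (NaN, produced by degenerate
windows) are excluded from correlation and clustering; the exclusion
count is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score
from sklearn.preprocessing import StandardScaler

from .hjorth import windowed_hjorth
from .io import TaskCode, Trial

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "KEY_COLUMNS",
    "CorrelationMatrix",
    "ClusterResult",
    "build_feature_table",
    "feature_correlation",
    "electrode_correlation",
    "cluster_features",
    "permutation_null_agreement",
    "task_contrast",
]

FEATURE_COLUMNS = ("activity", "mobility", "complexity")
KEY_COLUMNS = ("subject", "task", "trial", "electrode", "window_start")


def build_feature_table(
    trials: list[Trial],
    window_length: int | None = None,
    hop: int | None = None,
) -> pd.DataFrame:
    """Windowed Hjorth features of every trial as one long-form table.

    ``window_length=None`` means full-trial mode: one window spanning
    each whole trial (one row per trial and electrode).  All trials must
    share sampling rate and sample count.  Degenerate windows yield NaN
    mobility/complexity (bulk mode); their count is logged.
    """
    if not trials:
        raise ValueError("trials must be non-empty")
    rates = {t.sampling_rate for t in trials}
    if len(rates) != 1:
        raise ValueError(f"inconsistent sampling rates across trials: {sorted(rates)}")
    lengths = {t.n_samples for t in trials}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent trial lengths: {sorted(lengths)}")

    n_samples = lengths.pop()
    if window_length is None:
        window_length = n_samples
    if hop is None:
        hop = window_length

    records = []
    for trial in trials:
        series = windowed_hjorth(trial, window_length, hop, strict=False)
        for electrode, windows in series.windows.items():
            for start, triple in windows:
                records.append(
                    (
                        trial.subject,
                        trial.task.value,
                        trial.trial_index,
                        electrode,
                        start,
                        triple.activity,
                        triple.mobility,
                        triple.complexity,
                    )
                )
    table = pd.DataFrame(records, columns=list(KEY_COLUMNS) + list(FEATURE_COLUMNS))
    n_missing = int(table[list(FEATURE_COLUMNS)].isna().any(axis=1).sum())
    if n_missing:
        logger.warning("feature table contains %d rows with missing features", n_missing)
    return table


def _complete_rows(table: pd.DataFrame) -> pd.DataFrame:
    complete = table.dropna(subset=list(FEATURE_COLUMNS))
    dropped = len(table) - len(complete)
    if dropped:
        logger.info("excluded %d incomplete rows from analysis", dropped)
    return complete


@dataclass(frozen=True)
class CorrelationMatrix:
    """Feature-feature correlation matrix with its method label."""

    matrix: pd.DataFrame  # 3x3, indexed by feature name
    method: str
    n_rows: int


def feature_correlation(table: pd.DataFrame, method: str = "pearson") -> CorrelationMatrix:
    """Correlation between activity, mobility and complexity.

    Computed over complete rows only (listwise exclusion of the missing
    sentinel).  Requires at least 3 complete rows; a zero-variance
    feature column makes the correlation undefined and raises an error
    naming the column.
    """
    complete = _complete_rows(table)
    if len(complete) < 3:
        raise ValueError(f"need at least 3 complete rows, got {len(complete)}")
    features = complete[list(FEATURE_COLUMNS)]
    for column in FEATURE_COLUMNS:
        if float(features[column].var(ddof=0)) == 0.0:
            raise ValueError(f"correlation undefined: column {column!r} has zero variance")
    return CorrelationMatrix(
        matrix=features.corr(method=method), method=method, n_rows=len(complete)
    )


def electrode_correlation(
    table: pd.DataFrame, feature: str = "activity", method: str = "pearson"
) -> pd.DataFrame:
    """Electrode-electrode correlation of one feature across trials/windows.

    Optional companion view to :func:`feature_correlation`: rows are
    (subject, task, trial, window_start) observations, columns are
    electrodes.
    """
    if feature not in FEATURE_COLUMNS:
        raise ValueError(f"unknown feature {feature!r}")
    wide = _complete_rows(table).pivot_table(
        index=["subject", "task", "trial", "window_start"],
        columns="electrode",
        values=feature,
    )
    return wide.corr(method=method)


@dataclass(frozen=True)
class ClusterResult:
    """A k-means partition of the feature rows and its label agreement."""

    assignments: pd.Series  # cluster id per complete row, canonical order
    k: int
    agreement: float  # adjusted Rand index vs task labels
    seed: int
    method: str = "kmeans"


def _canonical_order(table: pd.DataFrame) -> pd.DataFrame:
    # fixed row ordering so clustering is invariant to input permutation
    return table.sort_values(list(KEY_COLUMNS), kind="mergesort").reset_index(drop=True)


def cluster_features(table: pd.DataFrame, k: int, seed: int) -> ClusterResult:
    """Standardize features, run k-means, score agreement with task labels.

    Rows are sorted into a canonical key order before clustering, so the
    result is bitwise reproducible regardless of input row order.  Uses
    10 restarts with a fixed seed; agreement is the adjusted Rand index
    between cluster assignments and the rows' task labels.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    complete = _canonical_order(_complete_rows(table))
    if k > len(complete):
        raise ValueError(f"k={k} exceeds the {len(complete)} complete rows")

    x = StandardScaler().fit_transform(complete[list(FEATURE_COLUMNS)].to_numpy())
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(x)
    ari = float(adjusted_rand_score(complete["task"].to_numpy(), labels))
    return ClusterResult(
        assignments=pd.Series(labels, index=complete.index, name="cluster"),
        k=k,
        agreement=ari,
        seed=seed,
    )


def permutation_null_agreement(
    table: pd.DataFrame,
    result: ClusterResult,
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the agreement under task-label shuffling.

    Shuffles the task labels of the complete rows ``n_permutations``
    times and recomputes the adjusted Rand index against the fixed
    cluster assignment, giving the chance level to compare
    ``result.agreement`` against.
    """
    complete = _canonical_order(_complete_rows(table))
    labels = complete["task"].to_numpy()
    rng = np.random.default_rng(seed)
    assignment = result.assignments.to_numpy()
    return np.array(
        [
            adjusted_rand_score(rng.permutation(labels), assignment)
            for _ in range(n_permutations)
        ]
    )


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    # pooled-SD standardized effect; undefined (NaN) with < 2 samples per group
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        return float("nan")
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0.0:
        return float("nan")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def task_contrast(
    table: pd.DataFrame, task_a: TaskCode, task_b: TaskCode
) -> pd.DataFrame:
    """Per-electrode descriptive contrast between two tasks (a minus b).

    For each electrode and feature: the mean difference, Cohen's d, and
    (for activity) the ratio of means.  ``high_amplitude_b`` flags the
    two electrodes with the highest mean activity under ``task_b`` —
    with Rest as the reference task this marks the Rest-elevated
    electrodes.  With a single trial per task the standardized effect is
    NaN (undefined), not an error.
    """
    task_a, task_b = TaskCode(task_a).value, TaskCode(task_b).value
    complete = _complete_rows(table)
    for task in (task_a, task_b):
        if not (complete["task"] == task).any():
            raise ValueError(f"task {task!r} not present in the feature table")

    rows_a = complete[complete["task"] == task_a]
    rows_b = complete[complete["task"] == task_b]

    records = []
    for electrode in sorted(complete["electrode"].unique()):
        ea = rows_a[rows_a["electrode"] == electrode]
        eb = rows_b[rows_b["electrode"] == electrode]
        record: dict[str, float] = {"electrode": electrode}
        for feature in FEATURE_COLUMNS:
            a = ea[feature].to_numpy()
            b = eb[feature].to_numpy()
            record[f"{feature}_mean_diff"] = float(a.mean() - b.mean())
            record[f"{feature}_cohens_d"] = _cohens_d(a, b)
        mean_b = eb["activity"].mean()
        record["activity_ratio"] = float(ea["activity"].mean() / mean_b) if mean_b else float("nan")
        record["mean_activity_b"] = float(mean_b)
        records.append(record)

    contrast = pd.DataFrame(records).set_index("electrode")
    top_two = contrast["mean_activity_b"].nlargest(2).index
    contrast["high_amplitude_b"] = contrast.index.isin(top_two)
    return contrast.drop(columns="mean_activity_b")
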