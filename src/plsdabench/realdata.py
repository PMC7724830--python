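"""One-vs-all feature ranking on a labeled abundance table, scored against a
ground-truth importance table.

Intended for multiclass abundance data (e.g. taxa x samples with a
community-type label per sample) where an external per-class feature
importance in [0, 1] is available.  For each target class the samples
are relabeled target-vs-rest, a projection method ranks the features,
and the ranking is scored by the cumulative (per-class normalized)
importance captured within the top fraction of features as the
selection threshold varies.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .evaluation import make_estimator, rank_features
from .exceptions import InvalidInputError

__all__ = [
    "load_importance_table",
    "normalize_importance",
    "one_vs_all_rank",
    "cumulative_specificity_curve",
    "DEFAULT_THRESHOLDS",
]

#: default selection thresholds: 2%, 4%, ..., 100% of the features
DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.02, 1.0001, 0.02), 4))


def normalize_importance(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize importances to sum to 1 within each class.

    Expects columns ``feature_id``, ``class_id``, ``importance``;
    importances must be non-negative with a positive per-class sum.
    """
    required = {"feature_id", "class_id", "importance"}
    if not required.issubset(table.columns):
        raise InvalidInputError(f"importance table needs columns {sorted(required)}")
    table = table.copy()
    if (table["importance"] < 0).any():
        raise InvalidInputError("importances must be non-negative")
    sums = table.groupby("class_id")["importance"].transform("sum")
    if (sums <= 0).any():
        raise InvalidInputError("every class needs a positive total importance")
    table["importance"] = table["importance"] / sums
    return table


def load_importance_table(path) -> pd.DataFrame:
    """Read a (feature_id, class_id, importance) CSV and normalize per class."""
    return normalize_importance(pd.read_csv(path))


def one_vs_all_rank(
    X, labels, target_class, method: str = "plsda", n_components: int = 1
):
    """Rank features for separating ``target_class`` from all other classes.

    ``X`` may be a DataFrame (columns = feature ids) or an array; the
    return value is the full list of feature ids (or indices) in
    decreasing selection-score order, ties broken toward the first
    column.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.columns)
        values = X.to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        feature_ids = list(range(values.shape[1]))
    labels = np.asarray(labels)
    if labels.shape[0] != values.shape[0]:
        raise InvalidInputError("labels do not match the number of samples")
    mask = labels == target_class
    if not mask.any():
        raise InvalidInputError(f"class {target_class!r} is absent from the labels")
    if mask.all():
        raise InvalidInputError(f"class {target_class!r} is the only class present")
    y = mask.astype(int)
    est = make_estimator(method, n_components=n_components)
    est.fit(values, y)
    order = rank_features(est)
    return [feature_ids[i] for i in order]


def cumulative_specificity_curve(
    ranking,
    truth: pd.DataFrame,
    class_id,
    thresholds=DEFAULT_THRESHOLDS,
    method: str = "",
) -> pd.DataFrame:
    """Cumulative ground-truth importance of the top-ranked features.

    At each threshold t the value is the summed normalized importance
    (for ``class_id``) of the first ``ceil(t * m)`` features of
    ``ranking``; features without an importance entry contribute 0.
    Monotone non-decreasing in t, and equal to 1 at t = 1 whenever every
    listed feature of the class appears in the ranking.
    """
    ranking = list(ranking)
    if not ranking:
        raise InvalidInputError("empty ranking")
    truth = normalize_importance(truth)
    cls = truth[truth["class_id"] == class_id]
    if cls.empty:
        raise InvalidInputError(f"class {class_id!r} missing from the importance table")
    imp = dict(zip(cls["feature_id"], cls["importance"]))
    m = len(ranking)
    per_feature = np.asarray([imp.get(f, 0.0) for f in ranking])
    cumulative = np.concatenate([[0.0], np.cumsum(per_feature)])
    rows = []
    for t in thresholds:
        if not 0 < t <= 1:
            raise InvalidInputError(f"thresholds must be in (0, 1], got {t}")
        k = math.ceil(t * m)
        rows.append(
            {
                "class_id": class_id,
                "method": method,
                "fraction_selected": float(t),
                "cumulative_importance": float(cumulative[k]),
            }
        )
    return pd.DataFrame(rows)
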