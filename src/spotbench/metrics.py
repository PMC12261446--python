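"""Evaluation metrics for predicted vs true cell-type proportions.

RMSE and Jensen-Shannon divergence are computed per spot and averaged
(global pooling available as an option for RMSE); NMI compares majority-type
labelings; the rare-type F1 scores presence/absence detection at a
configurable proportion threshold; a paired two-sided Wilcoxon signed-rank
test compares two strategies across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon
from scipy.stats import wilcoxon
from sklearn.metrics import f1_score as _sk_f1
from sklearn.metrics import normalized_mutual_info_score

from .datasets import ProportionMatrix

__all__ = [
    "rmse",
    "jsd",
    "majority_labels",
    "nmi",
    "f1_rare",
    "paired_strategy_test",
    "evaluate",
    "MetricReport",
]


def _aligned(true: ProportionMatrix, pred: ProportionMatrix):
    if true.values.shape[0] != pred.values.shape[0]:
        raise ValueError(
            f"spot counts differ: {true.values.shape[0]} vs {pred.values.shape[0]}")
    if not np.array_equal(true.type_labels, pred.type_labels):
        if set(true.type_labels) != set(pred.type_labels):
            raise ValueError("proportion matrices have different type-label sets")
        pred = pred.reorder(true.type_labels)
    return true.values, pred.values


def rmse(true: ProportionMatrix, pred: ProportionMatrix, pooling: str = "per_spot") -> float:
    """Root mean squared proportion error.

    ``per_spot`` (default): per-spot RMSE over types, averaged over spots.
    ``global``: single RMSE over all spot-type entries.
    """
    t, p = _aligned(true, pred)
    sq = (t - p) ** 2
    if pooling == "per_spot":
        return float(np.sqrt(sq.mean(axis=1)).mean())
    if pooling == "global":
        return float(np.sqrt(sq.mean()))
    raise ValueError(f"unknown pooling {pooling!r}")


def jsd(true: ProportionMatrix, pred: ProportionMatrix) -> float:
    """Mean per-spot Jensen-Shannon divergence (base-2 logs, range [0, 1]).

    Rows are renormalized defensively; ``0 * log 0`` is treated as 0.
    """
    t, p = _aligned(true, pred)
    # scipy returns the JS *distance* (sqrt of the divergence)
    per_spot = jensenshannon(t, p, base=2, axis=1) ** 2
    per_spot = np.nan_to_num(per_spot, nan=0.0)  # identical zero rows
    return float(per_spot.mean())


def majority_labels(p: ProportionMatrix) -> np.ndarray:
    """Per-spot majority type; ties go to the lexicographically smallest label."""
    order = np.argsort(p.type_labels, kind="stable")
    vals = p.values[:, order]
    labels = p.type_labels[order]
    return labels[np.argmax(vals, axis=1)]


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information (arithmetic-mean normalization).

    Identical labelings score 1; if either labeling has zero entropy and the
    two are not identical, the score is defined as 0.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("labelings must have equal length")
    if len(a) == 0:
        raise ValueError("labelings must be nonempty")
    if np.array_equal(a, b):
        return 1.0
    if len(np.unique(a)) == 1 or len(np.unique(b)) == 1:
        return 0.0
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def f1_rare(true: ProportionMatrix, pred: ProportionMatrix, type_label: str,
            threshold: float = 0.05) -> float:
    """F1 of per-spot presence detection for one (typically rare) cell type.

    A type is "present" in a spot when its proportion is >= ``threshold``.
    Returns 0 when there are no true and no predicted positives.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    t, p = _aligned(true, pred)
    matches = np.flatnonzero(true.type_labels == str(type_label))
    if len(matches) == 0:
        raise KeyError(f"unknown type label {type_label!r}")
    col = matches[0]
    y_true = t[:, col] >= threshold
    y_pred = p[:, col] >= threshold
    return float(_sk_f1(y_true, y_pred, zero_division=0.0))


def paired_strategy_test(metric_a, metric_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired metric values.

    Uses the exact null distribution for n <= 25 (no ties/zeros), the normal
    approximation otherwise.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired lists must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    if np.all(d == 0):
        raise ValueError("all paired differences are zero")
    n_eff = int((d != 0).sum())
    method = "exact" if (n_eff <= 25 and len(np.unique(np.abs(d[d != 0]))) == n_eff) else "auto"
    return float(wilcoxon(a, b, alternative="two-sided", method=method).pvalue)


@dataclass
class MetricReport:
    """Table of metric rows (one per dataset x method x strategy cell)."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    METRIC_COLUMNS = ("rmse", "jsd", "nmi")

    def add(self, row: dict) -> None:
        self.rows = pd.concat([self.rows, pd.DataFrame([row])], ignore_index=True)

    def aggregate(self, by=("method", "modality", "strategy")) -> pd.DataFrame:
        """Mean +- sd of each numeric metric across datasets."""
        by = [c for c in by if c in self.rows.columns]
        numeric = [c for c in self.rows.columns
                   if c.startswith(self.METRIC_COLUMNS) or c.startswith("f1")]
        g = self.rows.groupby(by, dropna=False)[numeric]
        agg = g.agg(["mean", "std"])
        agg.columns = [f"{m}_{s}" for m, s in agg.columns]
        return agg.reset_index()


def evaluate(true: ProportionMatrix, pred: ProportionMatrix, rare_types=(),
             threshold: float = 0.05, **annotations) -> dict:
    """One report row: RMSE, JSD, NMI on majority labels, per-type F1."""
    row = dict(annotations)
    row["rmse"] = rmse(true, pred)
    row["jsd"] = jsd(true, pred)
    row["nmi"] = nmi(majority_labels(true), majority_labels(pred))
    for t in rare_types:
        row[f"f1_{t}"] = f1_rare(true, pred, t, threshold=threshold)
    return row
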