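"""Feature-selection strategies for the reference, applied identically to spots.

Three strategies are provided, mirroring common practice for spot
deconvolution inputs:

* highly accessible peaks — peaks ranked by total fragment count (optionally
  by the fraction of cells with any signal);
* highly variable peaks across clusters — the clusters are the predefined
  cell-type labels; peaks are ranked by the variance of their per-type mean
  log-normalized accessibility;
* highly variable genes, "seurat" flavor — total-count normalization, log1p,
  then mean-binned normalized dispersion, following the classic Seurat/Scanpy
  recipe.

Selectors are scikit-learn style estimators (``fit`` on reference counts,
``transform`` subsets columns in rank order); module-level functions wrap
them and return a :class:`FeatureSelection` record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .datasets import ReferenceDataset, SpotDataset

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSelection",
    "HighlyAccessibleSelector",
    "ClusterHVPSelector",
    "SeuratHVGSelector",
    "select_highly_accessible",
    "select_highly_variable_peaks",
    "select_hvg_seurat",
    "apply_selection",
]


@dataclass
class FeatureSelection:
    """Outcome of a selection: ordered feature names, indices and scores."""

    modality: str
    strategy: str
    n_features: int
    selected: np.ndarray  # feature names, rank order
    indices: np.ndarray  # column indices into the reference matrix, rank order
    scores: np.ndarray  # ranking statistic along `selected`


def _rank_descending(scores: np.ndarray, n: int) -> np.ndarray:
    """Indices of the top-n scores, descending, ties broken by ascending index."""
    order = np.lexsort((np.arange(len(scores)), -scores))
    return order[:n]


def _depth_normalize(X: sp.csr_matrix, target: float | None = None) -> sp.csr_matrix:
    """Scale each cell to a common total count (median of totals by default).

    Cells with zero total are left untouched, matching scanpy's
    ``normalize_total``.
    """
    X = sp.csr_matrix(X, dtype=float, copy=True)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if target is None:
        target = np.median(totals[totals > 0])
    scale = np.ones_like(totals)
    nz = totals > 0
    scale[nz] = target / totals[nz]
    return sp.diags(scale) @ X


class _BaseSelector(BaseEstimator):
    """Shared fit bookkeeping: ranks features by a strategy-specific score."""

    def _finalize_fit(self, scores: np.ndarray, feature_names) -> "_BaseSelector":
        n_avail = len(scores)
        n = min(self.n_features, n_avail)
        if self.n_features > n_avail:
            logger.warning("requested %d features but only %d available; returning all",
                           self.n_features, n_avail)
        self.n_features_in_ = n_avail
        self.scores_full_ = scores
        self.selected_indices_ = _rank_descending(scores, n)
        self.scores_ = scores[self.selected_indices_]
        if feature_names is not None:
            feature_names = np.asarray(feature_names, dtype=object)
            self.feature_names_in_ = feature_names
            self.selected_names_ = feature_names[self.selected_indices_]
        else:
            self.selected_names_ = self.selected_indices_.astype(str)
        return self

    def transform(self, X):
        X = sp.csr_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, selector was fit on {self.n_features_in_}")
        return X[:, self.selected_indices_]

    def fit_transform(self, X, y=None, feature_names=None):
        return self.fit(X, y, feature_names=feature_names).transform(X)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.selected_names_, dtype=object)

    def to_selection(self, modality: str) -> FeatureSelection:
        return FeatureSelection(
            modality=modality,
            strategy=self.strategy,
            n_features=self.n_features,
            selected=np.asarray(self.selected_names_, dtype=object),
            indices=self.selected_indices_.copy(),
            scores=self.scores_.copy(),
        )


class HighlyAccessibleSelector(_BaseSelector):
    """Top-n peaks by total fragment count (or by prevalence).

    Parameters
    ----------
    n_features : int
        Number of peaks to retain (default 20000).
    criterion : {"total", "prevalence"}
        "total" ranks by the column sum of fragment counts across all
        reference cells; "prevalence" ranks by the fraction of cells with a
        nonzero count.
    """

    strategy = "highly_accessible"

    def __init__(self, n_features: int = 20000, criterion: str = "total"):
        self.n_features = n_features
        self.criterion = criterion

    def fit(self, X, y=None, feature_names=None):
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        X = sp.csr_matrix(X)
        if self.criterion == "total":
            scores = np.asarray(X.sum(axis=0)).ravel().astype(float)
        elif self.criterion == "prevalence":
            scores = np.asarray((X > 0).sum(axis=0)).ravel() / X.shape[0]
        else:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        return self._finalize_fit(scores, feature_names)


class ClusterHVPSelector(_BaseSelector):
    """Top-n peaks by variance of per-cell-type mean accessibility.

    Cells are depth-normalized to the median total, log1p-transformed, and
    averaged within each predefined cluster (the cell-type labels); the
    ranking statistic is the variance of these per-type means across types.
    """

    strategy = "highly_variable_peaks"

    def __init__(self, n_features: int = 20000):
        self.n_features = n_features

    def fit(self, X, y, feature_names=None):
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        y = np.asarray(y)
        labels = np.unique(y)
        if len(labels) < 2:
            raise ValueError("cluster-HVP requires at least 2 cell types")
        Xn = _depth_normalize(X)
        Xn.data = np.log1p(Xn.data)
        group_means = np.vstack([
            np.asarray(Xn[y == t].mean(axis=0)).ravel() for t in labels
        ])
        scores = group_means.var(axis=0, ddof=1)
        return self._finalize_fit(scores, feature_names)


class SeuratHVGSelector(_BaseSelector):
    """Top-n highly variable genes, "seurat" flavor.

    Pipeline: total-count normalization to the median depth, log1p; then on
    the expm1 scale compute per-gene mean and dispersion (variance/mean),
    log-transform the dispersion, bin genes into ``n_bins`` bins of log1p
    mean, and z-score the log dispersions within each bin. Genes are ranked
    by this normalized dispersion. Matches Scanpy's
    ``highly_variable_genes(flavor="seurat")`` statistic.
    """

    strategy = "hvg_seurat"

    def __init__(self, n_features: int = 4000, n_bins: int = 20):
        self.n_features = n_features
        self.n_bins = n_bins

    def fit(self, X, y=None, feature_names=None):
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        X = sp.csr_matrix(X)
        if X.shape[1] < 2:
            raise ValueError("need at least 2 genes")
        Xn = _depth_normalize(X)  # expm1(log1p(Xn)) == Xn: stay on the normalized scale
        n_cells = Xn.shape[0]
        mean = np.asarray(Xn.mean(axis=0)).ravel()
        sq = Xn.copy()
        sq.data **= 2
        ex2 = np.asarray(sq.mean(axis=0)).ravel()
        var = (ex2 - mean**2) * n_cells / max(n_cells - 1, 1)
        mean_safe = np.where(mean == 0, 1e-12, mean)
        dispersion = var / mean_safe
        with np.errstate(divide="ignore"):
            log_disp = np.where(dispersion > 0, np.log(dispersion), np.nan)
        log_mean = np.log1p(mean)
        df = pd.DataFrame({"disp": log_disp, "bin": pd.cut(log_mean, bins=self.n_bins)})
        grouped = df.groupby("bin", observed=True)["disp"]
        disp_mean = grouped.transform("mean")
        disp_std = grouped.transform("std")
        # bins holding a single gene have undefined std; following the Seurat
        # convention their z-score uses the bin mean as the scale
        singleton = disp_std.isna() & df["disp"].notna()
        disp_std = disp_std.where(~singleton, disp_mean)
        disp_mean = disp_mean.where(~singleton, 0.0)
        scores = ((df["disp"] - disp_mean) / disp_std).to_numpy()
        scores = np.where(np.isfinite(scores), scores, -np.inf)
        return self._finalize_fit(scores, feature_names)


def select_highly_accessible(atac_counts, n: int, feature_names=None,
                             criterion: str = "total") -> FeatureSelection:
    sel = HighlyAccessibleSelector(n_features=n, criterion=criterion)
    sel.fit(atac_counts, feature_names=feature_names)
    return sel.to_selection("atac")


def select_highly_variable_peaks(atac_counts, cell_types, n: int,
                                 feature_names=None) -> FeatureSelection:
    sel = ClusterHVPSelector(n_features=n)
    sel.fit(atac_counts, cell_types, feature_names=feature_names)
    return sel.to_selection("atac")


def select_hvg_seurat(rna_counts, n: int, feature_names=None) -> FeatureSelection:
    sel = SeuratHVGSelector(n_features=n)
    sel.fit(rna_counts, feature_names=feature_names)
    return sel.to_selection("rna")


def select_features(reference: ReferenceDataset, modality: str, strategy: str,
                    n: int) -> FeatureSelection:
    """Dispatch a selection strategy on a reference dataset."""
    if strategy == "highly_accessible":
        return select_highly_accessible(reference.get_modality(modality), n,
                                        feature_names=_names(reference, modality))
    if strategy == "highly_variable_peaks":
        return select_highly_variable_peaks(reference.get_modality(modality),
                                            reference.cell_types, n,
                                            feature_names=_names(reference, modality))
    if strategy == "hvg_seurat":
        return select_hvg_seurat(reference.get_modality(modality), n,
                                 feature_names=_names(reference, modality))
    raise ValueError(f"unknown strategy {strategy!r}")


def _names(dataset, modality: str) -> np.ndarray:
    return dataset.gene_names if modality == "rna" else dataset.peak_names


def apply_selection(spatial: SpotDataset, sel: FeatureSelection) -> SpotDataset:
    """Restrict a spot dataset's modality to the selected features, in rank order."""
    names = _names(spatial, sel.modality)
    pos = {nm: i for i, nm in enumerate(names)}
    missing = [nm for nm in sel.selected if nm not in pos]
    if missing:
        raise KeyError(
            f"{len(missing)} selected features absent from spatial dataset: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}")
    cols = np.array([pos[nm] for nm in sel.selected], dtype=int)
    matrix = spatial.get_modality(sel.modality)[:, cols]
    return spatial.with_modality(sel.modality, matrix, np.asarray(sel.selected, dtype=object))
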