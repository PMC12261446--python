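"""Naive baseline and a lightweight NNLS deconvolver.

The majority baseline predicts a single cell type per spot with probability
1 — either the spot's true majority type (oracle mode) or the reference's
globally most abundant type for every spot. The NNLS deconvolver fits
nonnegative least squares against per-type mean depth-normalized signature
profiles; it exists so the full simulate → select → deconvolve → evaluate
pipeline runs end-to-end, and as a sanity check that recovers exact convex
mixtures, not as a competitor to dedicated deconvolution methods (whose
predictions can be evaluated through the proportions-TSV adapter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .datasets import ProportionMatrix, ReferenceDataset, SpotDataset
from .features import FeatureSelection, apply_selection
from .metrics import majority_labels

logger = logging.getLogger(__name__)

__all__ = ["DeconvolutionResult", "majority_baseline", "NNLSDeconvolver", "nnls_deconvolve"]


@dataclass
class DeconvolutionResult:
    """A method's predicted proportions plus provenance."""

    method: str
    proportions: ProportionMatrix
    provenance: dict = field(default_factory=dict)


def _one_hot(labels, type_labels) -> ProportionMatrix:
    type_labels = np.asarray(type_labels, dtype=object).astype(str)
    pos = {t: i for i, t in enumerate(type_labels)}
    values = np.zeros((len(labels), len(type_labels)))
    for i, lab in enumerate(labels):
        values[i, pos[str(lab)]] = 1.0
    return ProportionMatrix(values, type_labels)


def majority_baseline(true: ProportionMatrix | None = None, mode: str = "oracle_spot",
                      reference_labels=None, type_labels=None) -> DeconvolutionResult:
    """Predict a single majority type per spot with probability 1.

    ``oracle_spot`` uses each spot's true majority type (requires ``true``);
    ``global_reference`` uses the reference's most abundant type for every
    spot (requires ``reference_labels`` and, to size the output, ``true`` or
    ``type_labels``).
    """
    if mode == "oracle_spot":
        if true is None:
            raise ValueError("oracle_spot mode requires the true proportions")
        labels = majority_labels(true)
        props = _one_hot(labels, true.type_labels)
    elif mode == "global_reference":
        if reference_labels is None:
            raise ValueError("global_reference mode requires reference labels")
        if true is None and type_labels is None:
            raise ValueError("global_reference mode requires true proportions or type_labels "
                             "to define the output shape")
        uniq, counts = np.unique(np.asarray(reference_labels).astype(str), return_counts=True)
        top = uniq[np.lexsort((uniq, -counts))][0]  # ties -> lexicographically smallest
        cols = true.type_labels if true is not None else np.asarray(type_labels)
        n_spots = true.n_spots if true is not None else 0
        props = _one_hot([top] * n_spots, cols)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DeconvolutionResult(method=f"majority_{mode}", proportions=props,
                               provenance={"mode": mode})


class NNLSDeconvolver(BaseEstimator):
    """Nonnegative-least-squares proportion estimation against type signatures.

    ``fit(X, y)`` builds the signature matrix: each cell's count vector is
    normalized to sum 1 and averaged within each cell-type label. ``predict``
    normalizes each spot the same way, solves ``min ||S^T w - x||`` subject
    to ``w >= 0`` and renormalizes ``w`` to the simplex (an all-zero solution
    falls back to a uniform row).

    Attributes
    ----------
    classes_ : array of type labels (signature row order)
    signature_ : (n_types, n_features) mean normalized profiles
    """

    def __init__(self):
        pass

    def fit(self, X, y):
        X = sp.csr_matrix(X, dtype=float)
        y = np.asarray(y).astype(str)
        if X.shape[0] != len(y):
            raise ValueError("X rows and y length differ")
        self.classes_ = np.unique(y)
        totals = np.asarray(X.sum(axis=1)).ravel()
        scale = np.divide(1.0, totals, out=np.zeros_like(totals), where=totals > 0)
        Xn = sp.diags(scale) @ X
        self.signature_ = np.vstack([
            np.asarray(Xn[y == t].mean(axis=0)).ravel() for t in self.classes_
        ])
        self.n_features_in_ = X.shape[1]
        if np.linalg.matrix_rank(self.signature_) < len(self.classes_):
            logger.warning("signature matrix is rank-deficient; proportions may be unidentifiable")
        return self

    def predict_proportions(self, X) -> ProportionMatrix:
        X = sp.csr_matrix(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch with fitted signature")
        A = self.signature_.T  # features x types
        out = np.zeros((X.shape[0], len(self.classes_)))
        for i in range(X.shape[0]):
            x = np.asarray(X[i].todense()).ravel()
            total = x.sum()
            if total > 0:
                x = x / total
            w, _ = nnls(A, x)
            s = w.sum()
            if s == 0:
                logger.warning("spot %d: all-zero NNLS solution; predicting uniform", i)
                out[i] = 1.0 / len(self.classes_)
            else:
                out[i] = w / s
        return ProportionMatrix(out, self.classes_)

    def predict(self, X) -> np.ndarray:
        """Majority type per spot (argmax of predicted proportions)."""
        return majority_labels(self.predict_proportions(X))


def nnls_deconvolve(reference: ReferenceDataset, spots: SpotDataset,
                    selection: FeatureSelection | None = None) -> DeconvolutionResult:
    """Run NNLS deconvolution on a shared (optionally selected) feature space."""
    if selection is not None:
        spots = apply_selection(spots, selection)
        ref_matrix = reference.get_modality(selection.modality)[:, selection.indices]
        modality = selection.modality
    else:
        modality = "rna"
        ref_matrix = reference.rna
    model = NNLSDeconvolver().fit(ref_matrix, reference.cell_types)
    props = model.predict_proportions(spots.get_modality(modality))
    return DeconvolutionResult(
        method="nnls",
        proportions=props,
        provenance={"modality": modality,
                    "strategy": selection.strategy if selection else None},
    )
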