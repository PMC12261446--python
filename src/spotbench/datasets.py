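"""Core data containers for references, spatial datasets and proportion matrices.

Count matrices are stored as scipy CSR sparse matrices of integer dtype,
cells (or spots) in rows and features in columns. RNA and ATAC modalities of
the same dataset always share the row axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "ReferenceDataset",
    "TargetedSpatialDataset",
    "SpotDataset",
    "ProportionMatrix",
]


def _as_int_csr(matrix, name: str) -> sp.csr_matrix:
    m = sp.csr_matrix(matrix)
    if m.nnz and m.data.min() < 0:
        raise ValueError(f"{name} contains negative counts")
    if not np.issubdtype(m.dtype, np.integer):
        data = m.data
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{name} contains non-integer counts")
        m = m.astype(np.int64)
    return m


@dataclass
class ReferenceDataset:
    """Dissociated single-cell multiome reference with cell-type labels.

    Parameters
    ----------
    rna : sparse matrix, cells x genes
        UMI counts.
    atac : sparse matrix, cells x peaks
        Fragment counts.
    cell_types : array of str, length n_cells
        Cell-type label per cell.
    gene_names, peak_names : arrays of str
        Feature identifiers per modality.
    cell_names : array of str, optional
        Barcodes; generated as ``cell{i}`` when omitted.
    """

    rna: sp.csr_matrix
    atac: sp.csr_matrix
    cell_types: np.ndarray
    gene_names: np.ndarray
    peak_names: np.ndarray
    cell_names: np.ndarray | None = None

    def __post_init__(self):
        self.rna = _as_int_csr(self.rna, "rna")
        self.atac = _as_int_csr(self.atac, "atac")
        self.cell_types = np.asarray(self.cell_types, dtype=object).astype(str)
        self.gene_names = np.asarray(self.gene_names, dtype=object).astype(str)
        self.peak_names = np.asarray(self.peak_names, dtype=object).astype(str)
        if self.rna.shape[0] != self.atac.shape[0]:
            raise ValueError(
                f"modalities disagree on cell count: {self.rna.shape[0]} vs {self.atac.shape[0]}"
            )
        if len(self.cell_types) != self.rna.shape[0]:
            raise ValueError("cell_types length does not match number of cells")
        if len(self.gene_names) != self.rna.shape[1]:
            raise ValueError("gene_names length does not match rna columns")
        if len(self.peak_names) != self.atac.shape[1]:
            raise ValueError("peak_names length does not match atac columns")
        if len(np.unique(self.cell_types)) < 2:
            raise ValueError("reference requires at least 2 distinct cell-type labels")
        if self.cell_names is None:
            self.cell_names = np.array([f"cell{i}" for i in range(self.n_cells)], dtype=object)
        else:
            self.cell_names = np.asarray(self.cell_names, dtype=object).astype(str)
            if len(self.cell_names) != self.n_cells:
                raise ValueError("cell_names length does not match number of cells")

    @property
    def n_cells(self) -> int:
        return self.rna.shape[0]

    @property
    def type_labels(self) -> np.ndarray:
        """Sorted unique cell-type labels."""
        return np.unique(self.cell_types)

    def get_modality(self, modality: str) -> sp.csr_matrix:
        if modality == "rna":
            return self.rna
        if modality == "atac":
            return self.atac
        raise ValueError(f"unknown modality {modality!r}")

    def take(self, indices) -> "ReferenceDataset":
        """Row-subset the dataset (shared across modalities)."""
        indices = np.asarray(indices)
        kwargs = dict(
            rna=self.rna[indices],
            atac=self.atac[indices],
            cell_types=self.cell_types[indices],
            gene_names=self.gene_names,
            peak_names=self.peak_names,
            cell_names=self.cell_names[indices],
        )
        if isinstance(self, TargetedSpatialDataset):
            kwargs["coordinates"] = self.coordinates[indices]
        return type(self)(**kwargs)


@dataclass
class TargetedSpatialDataset(ReferenceDataset):
    """Spatially tagged single-cell multiome dataset (one x/y pair per cell)."""

    coordinates: np.ndarray = None

    def __post_init__(self):
        super().__post_init__()
        if self.coordinates is None:
            raise ValueError("coordinates are required")
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (self.n_cells, 2):
            raise ValueError("coordinates must be an (n_cells, 2) array")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")


class ProportionMatrix:
    """Spots x cell-types proportions; rows are simplex vectors.

    Stored dense; rows must sum to 1 within 1e-9 with entries in [0, 1].
    """

    def __init__(self, values, type_labels):
        self.values = np.asarray(values, dtype=float)
        self.type_labels = np.asarray(type_labels, dtype=object).astype(str)
        if self.values.ndim != 2:
            raise ValueError("proportion matrix must be 2-D")
        if self.values.shape[1] != len(self.type_labels):
            raise ValueError("number of columns does not match number of type labels")
        if self.values.min(initial=0.0) < 0 or self.values.max(initial=0.0) > 1 + 1e-9:
            raise ValueError("proportions must lie in [0, 1]")
        rowsums = self.values.sum(axis=1)
        if self.values.shape[0] and not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("proportion rows must sum to 1 within 1e-9")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    def to_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.type_labels, index=index)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProportionMatrix":
        return cls(df.to_numpy(dtype=float), np.asarray(df.columns))

    def reorder(self, type_labels) -> "ProportionMatrix":
        """Return a copy with columns permuted to the given label order."""
        type_labels = np.asarray(type_labels, dtype=object).astype(str)
        pos = {t: i for i, t in enumerate(self.type_labels)}
        missing = [t for t in type_labels if t not in pos]
        if missing or len(type_labels) != len(self.type_labels):
            raise ValueError(f"label mismatch; missing {missing}")
        idx = [pos[t] for t in type_labels]
        return ProportionMatrix(self.values[:, idx], type_labels)

    def __eq__(self, other):
        return (
            isinstance(other, ProportionMatrix)
            and np.array_equal(self.type_labels, other.type_labels)
            and np.array_equal(self.values, other.values)
        )


@dataclass
class SpotDataset:
    """Spot-resolution spatial dataset: aggregated counts plus ground truth.

    ``member_cells`` records, per spot, the reference row indices whose
    profiles were summed (with multiplicity when sampling was with
    replacement); it is ``None`` for datasets read from disk without
    provenance.
    """

    rna: sp.csr_matrix
    atac: sp.csr_matrix
    coordinates: np.ndarray
    zone: np.ndarray
    gene_names: np.ndarray
    peak_names: np.ndarray
    true_proportions: ProportionMatrix | None = None
    member_cells: list | None = None
    spot_names: np.ndarray | None = None

    def __post_init__(self):
        self.rna = _as_int_csr(self.rna, "rna")
        self.atac = _as_int_csr(self.atac, "atac")
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.zone = np.asarray(self.zone)
        self.gene_names = np.asarray(self.gene_names, dtype=object).astype(str)
        self.peak_names = np.asarray(self.peak_names, dtype=object).astype(str)
        n = self.rna.shape[0]
        if self.atac.shape[0] != n:
            raise ValueError("modalities disagree on spot count")
        if self.coordinates.shape != (n, 2):
            raise ValueError("coordinates must be an (n_spots, 2) array")
        if len(self.zone) != n:
            raise ValueError("zone length does not match number of spots")
        if self.true_proportions is not None and self.true_proportions.n_spots != n:
            raise ValueError("true_proportions row count does not match spots")
        if self.member_cells is not None and len(self.member_cells) != n:
            raise ValueError("member_cells length does not match spots")
        if self.spot_names is None:
            self.spot_names = np.array([f"spot{i}" for i in range(n)], dtype=object)
        else:
            self.spot_names = np.asarray(self.spot_names, dtype=object).astype(str)

    @property
    def n_spots(self) -> int:
        return self.rna.shape[0]

    def get_modality(self, modality: str) -> sp.csr_matrix:
        if modality == "rna":
            return self.rna
        if modality == "atac":
            return self.atac
        raise ValueError(f"unknown modality {modality!r}")

    def with_modality(self, modality: str, matrix, feature_names) -> "SpotDataset":
        """Return a copy with one modality's matrix and features replaced."""
        kwargs = dict(
            rna=self.rna,
            atac=self.atac,
            coordinates=self.coordinates,
            zone=self.zone,
            gene_names=self.gene_names,
            peak_names=self.peak_names,
            true_proportions=self.true_proportions,
            member_cells=self.member_cells,
            spot_names=self.spot_names,
        )
        if modality == "rna":
            kwargs["rna"], kwargs["gene_names"] = matrix, feature_names
        elif modality == "atac":
            kwargs["atac"], kwargs["peak_names"] = matrix, feature_names
        else:
            raise ValueError(f"unknown modality {modality!r}")
        return SpotDataset(**kwargs)
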