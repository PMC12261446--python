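"""Gold-standard pseudo-spot aggregation of spatially tagged single cells.

Cells are binned into a regular square grid (half-open squares
``[x0, x0+s) x [y0, y0+s)``) and each occupied square becomes a pseudo spot
whose counts are the exact sum of its member cells' counts; ground-truth
proportions follow from the member labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .datasets import ProportionMatrix, SpotDataset, TargetedSpatialDataset

logger = logging.getLogger(__name__)

__all__ = ["SpotGrid", "grid_assign", "aggregate_pseudo_spots"]


@dataclass(frozen=True)
class SpotGrid:
    """Assignment of cells to half-open grid squares.

    ``square_indices`` holds each cell's (column, row) square index relative
    to ``origin`` at resolution ``spot_side``.
    """

    spot_side: float
    origin: tuple
    square_indices: np.ndarray  # (n_cells, 2) int

    def square_center(self, ix: int, iy: int) -> tuple:
        ox, oy = self.origin
        s = self.spot_side
        return (ox + (ix + 0.5) * s, oy + (iy + 0.5) * s)


def grid_assign(coordinates, spot_side: float, origin=(0.0, 0.0)) -> SpotGrid:
    """Assign each cell to the unique half-open grid square containing it."""
    if spot_side <= 0:
        raise ValueError("spot_side must be positive")
    coords = np.asarray(coordinates, dtype=float)
    origin = (float(origin[0]), float(origin[1]))
    idx = np.floor((coords - np.asarray(origin)) / spot_side).astype(np.int64)
    return SpotGrid(spot_side=float(spot_side), origin=origin, square_indices=idx)


def aggregate_pseudo_spots(data: TargetedSpatialDataset, grid: SpotGrid,
                           min_cells: int = 1) -> SpotDataset:
    """Aggregate cells into pseudo spots; squares below ``min_cells`` are dropped.

    Spot coordinates are square centroids. Spot counts are the exact
    element-wise sums of member-cell counts per modality.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    if grid.square_indices.shape[0] != data.n_cells:
        raise ValueError("grid was built for a different number of cells")
    # sort squares lexicographically (ix, then iy) for a deterministic spot order
    keys = grid.square_indices
    uniq, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    keep = counts >= min_cells
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d squares with fewer than %d cells (%d cells)",
                    n_dropped, min_cells, int(counts[~keep].sum()))
    kept_squares = np.flatnonzero(keep)
    if len(kept_squares) == 0:
        raise ValueError(f"no grid square holds at least {min_cells} cells")
    new_index = -np.ones(len(uniq), dtype=np.int64)
    new_index[kept_squares] = np.arange(len(kept_squares))
    spot_of_cell = new_index[inverse]
    retained = spot_of_cell >= 0

    n_spots = len(kept_squares)
    assign = sp.coo_matrix(
        (np.ones(int(retained.sum())), (spot_of_cell[retained], np.flatnonzero(retained))),
        shape=(n_spots, data.n_cells),
    ).tocsr()
    rna = (assign @ data.rna).astype(np.int64)
    atac = (assign @ data.atac).astype(np.int64)

    labels = data.type_labels
    type_pos = {t: i for i, t in enumerate(labels)}
    proportions = np.zeros((n_spots, len(labels)))
    members = []
    for s in range(n_spots):
        idx = np.flatnonzero(spot_of_cell == s)
        members.append(idx)
        u, c = np.unique(data.cell_types[idx], return_counts=True)
        for t, cc in zip(u, c):
            proportions[s, type_pos[t]] = cc / len(idx)

    centers = np.array([grid.square_center(ix, iy) for ix, iy in uniq[kept_squares]])
    return SpotDataset(
        rna=rna,
        atac=atac,
        coordinates=centers,
        zone=np.zeros(n_spots, dtype=np.int64),
        gene_names=data.gene_names,
        peak_names=data.peak_names,
        true_proportions=ProportionMatrix(proportions, labels),
        member_cells=members,
    )
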