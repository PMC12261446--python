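"""Synthetic single-cell multiome reference generation.

Generates dissociated and spatially tagged references with a known
block-diagonal marker structure, so downstream simulation, feature selection
and deconvolution stages can be exercised and validated without external
datasets. RNA counts follow a negative binomial (mean/shape parameterization,
variance mu + mu^2/theta); ATAC counts follow a Poisson by default, matching
the common observation that accessibility fragment counts are close to
Poisson, with an optional negative-binomial mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .datasets import ReferenceDataset, TargetedSpatialDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceConfig",
    "ZoneLayout",
    "generate_reference",
    "generate_targeted",
    "expand_reference_series",
]

_CHUNK = 512  # cells per dense sampling block


@dataclass(frozen=True)
class ReferenceConfig:
    """Parameters of the synthetic multiome reference.

    ``marker_fold_change`` scales the baseline mean on each type's marker
    features; markers are block-diagonal and non-overlapping (type ``t`` owns
    features ``t*markers_per_type .. (t+1)*markers_per_type - 1`` in each
    modality). ``library_size_sigma`` is the log-normal sigma of the per-cell
    size factor (mean-1 parameterization, so baseline means are preserved in
    expectation).
    """

    n_cells: int = 2000
    n_genes: int = 1000
    n_peaks: int = 2000
    n_cell_types: int = 12
    markers_per_type: int = 20
    marker_fold_change: float = 8.0
    baseline_rna_mean: float = 0.3
    baseline_atac_mean: float = 0.1
    rna_overdispersion: float = 20.0
    atac_overdispersion: float | None = None  # None -> Poisson ATAC counts
    library_size_sigma: float = 0.3
    cell_type_proportions: tuple | None = None  # balanced when None
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cells", "n_genes", "n_peaks", "n_cell_types", "markers_per_type"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_cell_types < 2:
            raise ValueError("need at least 2 cell types")
        n_marked = self.markers_per_type * self.n_cell_types
        if n_marked > self.n_genes or n_marked > self.n_peaks:
            raise ValueError(
                f"marker allocation ({n_marked}) exceeds feature count "
                f"(genes={self.n_genes}, peaks={self.n_peaks})"
            )
        for name in ("marker_fold_change", "baseline_rna_mean", "baseline_atac_mean",
                     "rna_overdispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.library_size_sigma < 0:
            raise ValueError("library_size_sigma must be nonnegative")
        if self.cell_type_proportions is not None:
            p = np.asarray(self.cell_type_proportions, dtype=float)
            if len(p) != self.n_cell_types or p.min() < 0 or not np.isclose(p.sum(), 1.0):
                raise ValueError("cell_type_proportions must be a simplex vector of length n_cell_types")


@dataclass(frozen=True)
class ZoneLayout:
    """Spatial arrangement of cell types for targeted (spatially tagged) data.

    ``uniform`` scatters cells uniformly over the unit square. ``clustered``
    places each type's cells around a type-specific center (isotropic normal
    with standard deviation ``dispersion``, clipped to the unit square);
    centers default to a regular lattice over the square interior.
    """

    kind: str = "uniform"
    dispersion: float = 0.08
    centers: np.ndarray | None = None

    def type_centers(self, n_types: int) -> np.ndarray:
        if self.centers is not None:
            c = np.asarray(self.centers, dtype=float)
            if c.shape != (n_types, 2):
                raise ValueError("centers must be (n_types, 2)")
            return c
        side = int(np.ceil(np.sqrt(n_types)))
        grid = [( (i + 0.5) / side, (j + 0.5) / side) for j in range(side) for i in range(side)]
        return np.asarray(grid[:n_types])


def _assign_types(config: ReferenceConfig, rng: np.random.Generator) -> np.ndarray:
    """Cell-type index per cell; balanced round-robin or multinomial by proportions."""
    if config.cell_type_proportions is None:
        return np.arange(config.n_cells) % config.n_cell_types
    p = np.asarray(config.cell_type_proportions, dtype=float)
    return rng.choice(config.n_cell_types, size=config.n_cells, p=p)


def _type_means(n_features: int, n_types: int, markers_per_type: int,
                baseline: float, fold: float) -> np.ndarray:
    """(n_types, n_features) expected-count matrix with block-diagonal markers."""
    means = np.full((n_types, n_features), baseline)
    for t in range(n_types):
        lo, hi = t * markers_per_type, (t + 1) * markers_per_type
        means[t, lo:hi] = baseline * fold
    return means


def _sample_counts(type_idx, size_factors, means, theta, rng) -> sp.csr_matrix:
    """Draw a sparse cells x features count matrix, NB(theta) or Poisson (theta=None)."""
    n = len(type_idx)
    blocks = []
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        mu = means[type_idx[start:stop]] * size_factors[start:stop, None]
        if theta is None:
            block = rng.poisson(mu)
        else:
            block = rng.negative_binomial(theta, theta / (theta + mu))
        blocks.append(sp.csr_matrix(block))
    return sp.vstack(blocks, format="csr").astype(np.int64)


def generate_reference(config: ReferenceConfig) -> ReferenceDataset:
    """Generate a dissociated multiome reference; deterministic given ``config.seed``."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_assign, rng_size, rng_rna, rng_atac, rng_coord = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    type_idx = _assign_types(config, rng_assign)
    sigma = config.library_size_sigma
    # log-normal with unit mean so baseline means are preserved in expectation
    size_factors = rng_size.lognormal(-0.5 * sigma**2, sigma, size=config.n_cells)

    rna_means = _type_means(config.n_genes, config.n_cell_types,
                            config.markers_per_type, config.baseline_rna_mean,
                            config.marker_fold_change)
    atac_means = _type_means(config.n_peaks, config.n_cell_types,
                             config.markers_per_type, config.baseline_atac_mean,
                             config.marker_fold_change)
    rna = _sample_counts(type_idx, size_factors, rna_means,
                         config.rna_overdispersion, rng_rna)
    atac = _sample_counts(type_idx, size_factors, atac_means,
                          config.atac_overdispersion, rng_atac)
    return ReferenceDataset(
        rna=rna,
        atac=atac,
        cell_types=np.array([f"type{t:02d}" for t in type_idx], dtype=object),
        gene_names=np.array([f"gene{g}" for g in range(config.n_genes)], dtype=object),
        peak_names=np.array([f"peak{p}" for p in range(config.n_peaks)], dtype=object),
    )


def generate_targeted(config: ReferenceConfig, layout: ZoneLayout | str = "uniform") -> TargetedSpatialDataset:
    """Generate a spatially tagged multiome dataset on the unit square."""
    if isinstance(layout, str):
        layout = ZoneLayout(kind=layout)
    if layout.kind not in ("uniform", "clustered"):
        raise ValueError(f"unknown layout {layout.kind!r}")
    ref = generate_reference(config)
    # coordinate stream is the 5th spawn, matching generate_reference's layout
    rng_coord = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(5)[4])
    n = ref.n_cells
    if layout.kind == "uniform":
        coords = rng_coord.uniform(0.0, 1.0, size=(n, 2))
    else:
        type_idx = np.array([int(t[4:]) for t in ref.cell_types])
        centers = layout.type_centers(config.n_cell_types)
        coords = centers[type_idx] + rng_coord.normal(0.0, layout.dispersion, size=(n, 2))
        coords = np.clip(coords, 0.0, 1.0)
    return TargetedSpatialDataset(
        rna=ref.rna,
        atac=ref.atac,
        cell_types=ref.cell_types,
        gene_names=ref.gene_names,
        peak_names=ref.peak_names,
        cell_names=ref.cell_names,
        coordinates=coords,
    )


def expand_reference_series(base: ReferenceDataset, pool: ReferenceDataset,
                            factors, seed: int = 0) -> list:
    """Build a nested series of references scaled by the given factors.

    The element for factor ``f`` contains all of ``base`` plus ``(f-1)*|base|``
    extra cells drawn without replacement from ``pool`` (cells already in
    ``base``, matched by name, are excluded). Elements are nested: the output
    for a smaller factor is a prefix of the output for a larger one.
    """
    factors = list(factors)
    if any(f < 1 for f in factors):
        raise ValueError("factors must be >= 1")
    if not np.array_equal(base.gene_names, pool.gene_names) or not np.array_equal(
        base.peak_names, pool.peak_names
    ):
        raise ValueError("base and pool must share feature spaces")
    base_names = set(base.cell_names)
    extra_idx = np.array([i for i, nm in enumerate(pool.cell_names) if nm not in base_names],
                         dtype=int)
    max_extra = (max(factors) - 1) * base.n_cells
    if max_extra > len(extra_idx):
        raise ValueError(
            f"pool too small: need {max_extra} extra cells, have {len(extra_idx)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(extra_idx)
    out = []
    for f in factors:
        n_extra = (f - 1) * base.n_cells
        if n_extra == 0:
            out.append(base)
            continue
        chosen = order[:n_extra]
        merged = ReferenceDataset(
            rna=sp.vstack([base.rna, pool.rna[chosen]], format="csr"),
            atac=sp.vstack([base.atac, pool.atac[chosen]], format="csr"),
            cell_types=np.concatenate([base.cell_types, pool.cell_types[chosen]]),
            gene_names=base.gene_names,
            peak_names=base.peak_names,
            cell_names=np.concatenate([base.cell_names, pool.cell_names[chosen]]),
        )
        out.append(merged)
    return out
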