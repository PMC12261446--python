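"""Silver-standard spot simulation from a dissociated single-cell reference.

Each simulated spot aggregates the profiles of cells sampled from the
reference. Per-spot tissue heterogeneity (number of distinct cell types) and
cell density (number of cells) are drawn from a Poisson-Gamma — i.e. negative
binomial — distribution parameterized by mean mu and shape theta (variance
mu + mu^2/theta), with the shape fixed at 20 by default. Spatial zonation is
modeled by laying spots on a regular grid over the unit square and giving
each zone (vertical stripes or discs along the diagonal) its own composition
and density means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .datasets import ProportionMatrix, ReferenceDataset, SpotDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "sample_composition_size",
    "lay_spot_grid",
    "assign_zones",
    "sample_spot_members",
    "simulate_spots",
]

ZONATIONS = ("uniform", "stripes", "circles")


def _per_region(value, n_regions: int, name: str) -> tuple:
    if np.isscalar(value):
        return (float(value),) * n_regions
    vals = tuple(float(v) for v in value)
    if len(vals) != n_regions:
        raise ValueError(f"{name} must have one entry per region ({n_regions}), got {len(vals)}")
    return vals


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one silver-standard simulation run.

    ``mean_cell_types`` and ``mean_cells`` are scalars under uniform zonation
    and per-region sequences (mapped to zone labels in order) otherwise.
    """

    n_spots: int = 1000
    zonation: str = "uniform"
    n_regions: int = 1
    mean_cell_types: float | tuple = 3.0
    mean_cells: float | tuple = 5.0
    overdispersion: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.n_spots < 1:
            raise ValueError("n_spots must be >= 1")
        if self.zonation not in ZONATIONS:
            raise ValueError(f"unknown zonation {self.zonation!r}; expected one of {ZONATIONS}")
        if self.zonation == "uniform":
            if self.n_regions != 1:
                raise ValueError("uniform zonation requires n_regions = 1")
        elif self.n_regions < 2:
            raise ValueError("zonated simulations require n_regions >= 2")
        if self.overdispersion <= 0:
            raise ValueError("overdispersion must be positive")
        object.__setattr__(self, "mean_cell_types",
                           _per_region(self.mean_cell_types, self.n_regions, "mean_cell_types"))
        object.__setattr__(self, "mean_cells",
                           _per_region(self.mean_cells, self.n_regions, "mean_cells"))
        if min(self.mean_cell_types) <= 0 or min(self.mean_cells) <= 0:
            raise ValueError("per-region means must be positive")


def sample_composition_size(mean: float, overdispersion: float, lower: int = 1,
                            upper: int | None = None, n: int = 1,
                            rng=None, seed: int | None = None) -> np.ndarray:
    """Draw ``n`` clamped negative-binomial counts.

    X ~ NB(mean=mu, shape=theta) with variance mu + mu^2/theta; each draw is
    clamped to ``[lower, upper]``. Clamping (rather than rejection resampling)
    keeps the mean bias small and analytically tractable:
    E[max(lower, X)] has a closed form via the NB pmf.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if overdispersion <= 0:
        raise ValueError("overdispersion must be positive")
    if lower < 1:
        raise ValueError("lower must be >= 1")
    if upper is not None and upper < lower:
        raise ValueError("upper must be >= lower")
    if rng is None:
        rng = np.random.default_rng(seed)
    theta = overdispersion
    draws = rng.negative_binomial(theta, theta / (theta + mean), size=n)
    draws = np.maximum(draws, lower)
    if upper is not None:
        draws = np.minimum(draws, upper)
    return draws.astype(np.int64)


def lay_spot_grid(n_spots: int) -> np.ndarray:
    """Place ``n_spots`` on a near-square regular grid covering the unit square.

    The grid has ``ceil(sqrt(n))`` columns, filled row-major; the last row may
    be partial. Spots sit at grid-cell centers.
    """
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    ncols = int(np.ceil(np.sqrt(n_spots)))
    nrows = int(np.ceil(n_spots / ncols))
    idx = np.arange(n_spots)
    col = idx % ncols
    row = idx // ncols
    x = (col + 0.5) / ncols
    y = (row + 0.5) / nrows
    return np.column_stack([x, y])


def assign_zones(coordinates, zonation: str, n_regions: int) -> np.ndarray:
    """Assign a region label to each spot.

    uniform: every spot gets label 0. stripes: ``n_regions`` equal-width
    vertical bands; label = band containing the spot's x. circles:
    ``n_regions - 1`` discs of radius ``1/(2*n_regions)`` with centers equally
    spaced along the square's diagonal; labels 1..n_regions-1 by containment
    (ties to the lowest index), everything else is background label 0.
    """
    coords = np.asarray(coordinates, dtype=float)
    n = coords.shape[0]
    if zonation == "uniform":
        return np.zeros(n, dtype=np.int64)
    if zonation == "stripes":
        bands = np.minimum((coords[:, 0] * n_regions).astype(np.int64), n_regions - 1)
        return bands
    if zonation == "circles":
        radius = 1.0 / (2 * n_regions)
        labels = np.zeros(n, dtype=np.int64)
        # iterate high→low so the lowest-index disc wins ties
        for i in range(n_regions - 1, 0, -1):
            c = i / n_regions
            inside = (coords[:, 0] - c) ** 2 + (coords[:, 1] - c) ** 2 <= radius**2
            labels[inside] = i
        return labels
    raise ValueError(f"unknown zonation {zonation!r}")


def sample_spot_members(reference: ReferenceDataset, k_types: int, n_cells: int,
                        rng=None, seed: int | None = None,
                        type_indices: dict | None = None) -> np.ndarray:
    """Sample the member-cell indices of one spot.

    ``k_types`` distinct cell types are chosen uniformly without replacement;
    the ``n_cells`` cells are allocated among them by a uniform multinomial
    with each chosen type guaranteed at least one cell when ``n_cells >=
    k_types`` (otherwise a uniform subset of ``n_cells`` of the chosen types
    receives one cell each). Within a type, cells are sampled uniformly
    without replacement, falling back to with-replacement only when the
    demand exceeds that type's pool.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if type_indices is None:
        labels = reference.type_labels
        type_indices = {t: np.flatnonzero(reference.cell_types == t) for t in labels}
    labels = list(type_indices)
    if not 1 <= k_types <= len(labels):
        raise ValueError(f"k_types={k_types} outside [1, {len(labels)}]")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    chosen = rng.choice(len(labels), size=k_types, replace=False)
    if n_cells < k_types:
        counts = np.zeros(k_types, dtype=np.int64)
        counts[:n_cells] = 1  # `chosen` is already in uniformly random order
    else:
        counts = 1 + rng.multinomial(n_cells - k_types, np.full(k_types, 1.0 / k_types))
    members = []
    for type_pos, demand in zip(chosen, counts):
        if demand == 0:
            continue
        pool = type_indices[labels[type_pos]]
        replace = demand > len(pool)
        members.append(rng.choice(pool, size=demand, replace=replace))
    return np.concatenate(members)


def simulate_spots(reference: ReferenceDataset, config: SimulationConfig) -> SpotDataset:
    """Run a full silver-standard simulation; deterministic given ``config.seed``.

    Per spot: the zone fixes the composition/density means, the distinct-type
    count k and cell count n are clamped-NB draws (k clamped to [1, number of
    reference types], n clamped below at max(1, k) since k distinct types
    require at least k cells), members are sampled via
    :func:`sample_spot_members`, counts are summed exactly per modality, and
    the true proportion row is the member-type frequency vector. Four named
    RNG substreams (k draws, n draws, type choice, cell choice) keep the
    per-spot draws independent of the total spot count prefix.
    """
    labels = reference.type_labels
    n_types = len(labels)
    max_mean_k = max(config.mean_cell_types)
    if n_types < max_mean_k:
        logger.warning(
            "reference has %d cell types, fewer than configured mean of %.3g; "
            "type counts will be clamped", n_types, max_mean_k,
        )
    ss = np.random.SeedSequence(config.seed)
    rng_k, rng_n, rng_type, rng_cell = (np.random.default_rng(s) for s in ss.spawn(4))

    coords = lay_spot_grid(config.n_spots)
    zones = assign_zones(coords, config.zonation, config.n_regions)
    theta = config.overdispersion

    k_per_spot = np.empty(config.n_spots, dtype=np.int64)
    n_per_spot = np.empty(config.n_spots, dtype=np.int64)
    for z in range(config.n_regions):
        mask = zones == z
        m = int(mask.sum())
        if m == 0:
            continue
        k_per_spot[mask] = sample_composition_size(
            config.mean_cell_types[z], theta, lower=1, upper=n_types, n=m, rng=rng_k)
        n_per_spot[mask] = sample_composition_size(
            config.mean_cells[z], theta, lower=1, upper=None, n=m, rng=rng_n)
    # a spot holding k distinct types necessarily holds at least k cells, so
    # the density draw is lower-clamped at k; this keeps the realized
    # distinct-type count equal to the drawn heterogeneity value
    n_per_spot = np.maximum(n_per_spot, k_per_spot)

    type_indices = {t: np.flatnonzero(reference.cell_types == t) for t in labels}
    type_pos = {t: i for i, t in enumerate(labels)}
    members = []
    proportions = np.zeros((config.n_spots, n_types))
    rows, cols, data = [], [], []
    for s in range(config.n_spots):
        # type choice and within-type cell choice use separate named streams
        idx = _sample_one_spot(k_per_spot[s], n_per_spot[s], type_indices, rng_type, rng_cell)
        members.append(idx)
        uniq, cnt = np.unique(reference.cell_types[idx], return_counts=True)
        for t, c in zip(uniq, cnt):
            proportions[s, type_pos[t]] = c / len(idx)
        rows.append(np.full(len(idx), s))
        cols.append(idx)
    assign = sp.coo_matrix(
        (np.ones(sum(len(c) for c in cols)), (np.concatenate(rows), np.concatenate(cols))),
        shape=(config.n_spots, reference.n_cells),
    ).tocsr()  # duplicate entries sum, giving with-replacement multiplicity
    rna = (assign @ reference.rna).astype(np.int64)
    atac = (assign @ reference.atac).astype(np.int64)

    return SpotDataset(
        rna=rna,
        atac=atac,
        coordinates=coords,
        zone=zones,
        gene_names=reference.gene_names,
        peak_names=reference.peak_names,
        true_proportions=ProportionMatrix(proportions, labels),
        member_cells=members,
    )


def _sample_one_spot(k: int, n: int, type_indices: dict, rng_type, rng_cell) -> np.ndarray:
    labels = list(type_indices)
    chosen = rng_type.choice(len(labels), size=k, replace=False)
    if n < k:
        counts = np.zeros(k, dtype=np.int64)
        counts[:n] = 1
    else:
        counts = 1 + rng_type.multinomial(n - k, np.full(k, 1.0 / k))
    members = []
    for pos, demand in zip(chosen, counts):
        if demand == 0:
            continue
        pool = type_indices[labels[pos]]
        members.append(rng_cell.choice(pool, size=demand, replace=demand > len(pool)))
    return np.concatenate(members)
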