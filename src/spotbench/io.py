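"""Readers and writers: MTX+TSV bundles, h5ad containers, proportion TSVs.

A *bundle* is a directory holding one Matrix Market file per modality
(``rna.mtx``, ``atac.mtx``), feature tables (``genes.tsv``, ``peaks.tsv``,
single column ``feature_id``), and a cell or spot metadata table
(``cells.tsv`` with ``barcode``, ``cell_type`` and optional ``x``/``y``;
``spots.tsv`` with ``spot_id``, ``x``, ``y``, ``zone``). Spot bundles may
additionally carry ``proportions.tsv`` (spot_id + one column per type). All
writes are atomic (temp file + rename); integer counts round-trip exactly.

The same proportions-TSV dialect is the adapter contract for evaluating
external deconvolution tools: spots in rows, cell types in columns, tab
separated, '.' decimal.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .datasets import ProportionMatrix, ReferenceDataset, SpotDataset, TargetedSpatialDataset

__all__ = [
    "write_reference_bundle",
    "read_reference_bundle",
    "write_spot_bundle",
    "read_spot_bundle",
    "write_reference_h5ad",
    "read_reference_h5ad",
    "write_proportions_tsv",
    "read_proportions_tsv",
]

_FLOAT_FMT = "%.10g"


def _atomic_write(path: Path, writer, suffix: str = "") -> None:
    """Write via a temp file in the same directory, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=suffix)
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _write_mtx(path: Path, matrix: sp.spmatrix) -> None:
    # the .mtx suffix stops mmwrite from appending its own extension
    _atomic_write(path, lambda tmp: mmwrite(tmp, sp.coo_matrix(matrix), field="integer"),
                  suffix=".mtx")


def _read_mtx(path: Path) -> sp.csr_matrix:
    if not Path(path).exists():
        raise FileNotFoundError(f"bundle is missing {Path(path).name}: {path}")
    return sp.csr_matrix(mmread(str(path))).astype(np.int64)


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    _atomic_write(path, lambda tmp: df.to_csv(tmp, sep="\t", index=False,
                                              float_format=_FLOAT_FMT))


def _read_tsv(path: Path, required: bool = True) -> pd.DataFrame | None:
    path = Path(path)
    if not path.exists():
        if required:
            raise FileNotFoundError(f"bundle is missing {path.name}: {path}")
        return None
    return pd.read_csv(path, sep="\t")


def write_reference_bundle(dataset: ReferenceDataset, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_mtx(path / "rna.mtx", dataset.rna)
    _write_mtx(path / "atac.mtx", dataset.atac)
    _write_tsv(path / "genes.tsv", pd.DataFrame({"feature_id": dataset.gene_names}))
    _write_tsv(path / "peaks.tsv", pd.DataFrame({"feature_id": dataset.peak_names}))
    cells = pd.DataFrame({"barcode": dataset.cell_names, "cell_type": dataset.cell_types})
    if isinstance(dataset, TargetedSpatialDataset):
        cells["x"] = dataset.coordinates[:, 0]
        cells["y"] = dataset.coordinates[:, 1]
    _write_tsv(path / "cells.tsv", cells)


def read_reference_bundle(path) -> ReferenceDataset:
    """Read a reference bundle; returns a TargetedSpatialDataset when x/y are present."""
    path = Path(path)
    rna = _read_mtx(path / "rna.mtx")
    atac = _read_mtx(path / "atac.mtx")
    genes = _read_tsv(path / "genes.tsv")["feature_id"].to_numpy()
    peaks = _read_tsv(path / "peaks.tsv")["feature_id"].to_numpy()
    cells = _read_tsv(path / "cells.tsv")
    if len(cells) != rna.shape[0]:
        raise ValueError(
            f"cells.tsv has {len(cells)} rows but matrices have {rna.shape[0]} cells")
    kwargs = dict(rna=rna, atac=atac, cell_types=cells["cell_type"].to_numpy(),
                  gene_names=genes, peak_names=peaks,
                  cell_names=cells["barcode"].to_numpy())
    if {"x", "y"}.issubset(cells.columns):
        kwargs["coordinates"] = cells[["x", "y"]].to_numpy(dtype=float)
        return TargetedSpatialDataset(**kwargs)
    return ReferenceDataset(**kwargs)


def write_spot_bundle(dataset: SpotDataset, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_mtx(path / "rna.mtx", dataset.rna)
    _write_mtx(path / "atac.mtx", dataset.atac)
    _write_tsv(path / "genes.tsv", pd.DataFrame({"feature_id": dataset.gene_names}))
    _write_tsv(path / "peaks.tsv", pd.DataFrame({"feature_id": dataset.peak_names}))
    spots = pd.DataFrame({
        "spot_id": dataset.spot_names,
        "x": dataset.coordinates[:, 0],
        "y": dataset.coordinates[:, 1],
        "zone": dataset.zone,
    })
    _write_tsv(path / "spots.tsv", spots)
    if dataset.true_proportions is not None:
        write_proportions_tsv(dataset.true_proportions, path / "proportions.tsv",
                              spot_names=dataset.spot_names)


def read_spot_bundle(path) -> SpotDataset:
    path = Path(path)
    rna = _read_mtx(path / "rna.mtx")
    atac = _read_mtx(path / "atac.mtx")
    genes = _read_tsv(path / "genes.tsv")["feature_id"].to_numpy()
    peaks = _read_tsv(path / "peaks.tsv")["feature_id"].to_numpy()
    spots = _read_tsv(path / "spots.tsv")
    if len(spots) != rna.shape[0]:
        raise ValueError(
            f"spots.tsv has {len(spots)} rows but matrices have {rna.shape[0]} spots")
    props = None
    if (path / "proportions.tsv").exists():
        props = read_proportions_tsv(path / "proportions.tsv")
    return SpotDataset(
        rna=rna, atac=atac,
        coordinates=spots[["x", "y"]].to_numpy(dtype=float),
        zone=spots["zone"].to_numpy(),
        gene_names=genes, peak_names=peaks,
        true_proportions=props,
        spot_names=spots["spot_id"].to_numpy(),
    )


def write_proportions_tsv(props: ProportionMatrix, path, spot_names=None) -> None:
    df = props.to_frame()
    if spot_names is None:
        spot_names = [f"spot{i}" for i in range(props.n_spots)]
    df.insert(0, "spot_id", np.asarray(spot_names))
    _write_tsv(path, df)


def read_proportions_tsv(path) -> ProportionMatrix:
    df = _read_tsv(path)
    cols = [c for c in df.columns if c != "spot_id"]
    return ProportionMatrix(df[cols].to_numpy(dtype=float), cols)


def write_reference_h5ad(dataset: ReferenceDataset, prefix) -> tuple:
    """Write one h5ad file per modality (``<prefix>_rna.h5ad``, ``<prefix>_atac.h5ad``)."""
    import anndata as ad

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    obs = pd.DataFrame({"cell_type": pd.Categorical(dataset.cell_types)},
                       index=pd.Index(dataset.cell_names.astype(str), name="barcode"))
    if isinstance(dataset, TargetedSpatialDataset):
        obs["x"] = dataset.coordinates[:, 0]
        obs["y"] = dataset.coordinates[:, 1]
    paths = []
    for modality, matrix, names in (("rna", dataset.rna, dataset.gene_names),
                                    ("atac", dataset.atac, dataset.peak_names)):
        adata = ad.AnnData(X=matrix.astype(np.int64), obs=obs.copy(),
                           var=pd.DataFrame(index=pd.Index(names.astype(str), name="feature_id")))
        out = prefix.parent / f"{prefix.name}_{modality}.h5ad"
        _atomic_write(out, lambda tmp, a=adata: a.write_h5ad(tmp))
        paths.append(out)
    return tuple(paths)


def read_reference_h5ad(prefix) -> ReferenceDataset:
    import anndata as ad

    prefix = Path(prefix)
    paths = {m: prefix.parent / f"{prefix.name}_{m}.h5ad" for m in ("rna", "atac")}
    for m, p in paths.items():
        if not p.exists():
            raise FileNotFoundError(f"missing {m} container: {p}")
    rna = ad.read_h5ad(paths["rna"])
    atac = ad.read_h5ad(paths["atac"])
    kwargs = dict(
        rna=sp.csr_matrix(rna.X).astype(np.int64),
        atac=sp.csr_matrix(atac.X).astype(np.int64),
        cell_types=rna.obs["cell_type"].astype(str).to_numpy(),
        gene_names=rna.var_names.to_numpy(),
        peak_names=atac.var_names.to_numpy(),
        cell_names=rna.obs_names.to_numpy(),
    )
    if {"x", "y"}.issubset(rna.obs.columns):
        kwargs["coordinates"] = rna.obs[["x", "y"]].to_numpy(dtype=float)
        return TargetedSpatialDataset(**kwargs)
    return ReferenceDataset(**kwargs)
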