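"""Typed containers for paired expression data and readers/writers.

A :class:`CountDataset` holds one modality: a cells x genes integer count
matrix plus per-cell metadata.  scRNA-seq datasets (``modality = 0``) carry
no coordinates and their log-library size is treated downstream as a latent
variable; spatial datasets (``modality = 1``) carry 2-D coordinates and an
observed log-library size, the natural log of each cell's total count.

On-disk formats: matrix-market (MTX, 1-based) with one-gene-per-line and
one-cell-per-line TSVs, coordinates/labels as headed CSVs, or a single H5AD
container (via :mod:`anndata`) with coordinates in ``obsm['spatial']`` and
labels in ``obs['cell_type']``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

SC_MODALITY = 0
SPATIAL_MODALITY = 1


class DataError(ValueError):
    """Structured load/validation failure naming the offending input."""


@dataclass
class CountDataset:
    counts: np.ndarray            # cells x genes, nonnegative integers
    gene_names: np.ndarray        # ordered unique strings
    cell_ids: np.ndarray          # ordered unique strings
    modality: int                 # 0 = scRNA-seq, 1 = spatial
    coordinates: Optional[np.ndarray] = None   # cells x 2, spatial only
    cell_types: Optional[np.ndarray] = None
    log_library: np.ndarray = field(init=False)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if sparse.issparse(self.counts):  # pragma: no cover - normalized upstream
            self.counts = self.counts.toarray()
        if self.counts.ndim != 2:
            raise DataError("counts must be a 2-D matrix")
        if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
            raise DataError("counts must be nonnegative integers")
        self.counts = self.counts.astype(np.int64)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n, g = self.counts.shape
        if len(self.gene_names) != g:
            raise DataError(
                f"gene list length {len(self.gene_names)} != matrix columns {g}"
            )
        if len(self.cell_ids) != n:
            raise DataError(
                f"cell list length {len(self.cell_ids)} != matrix rows {n}"
            )
        dup = pd.Index(self.gene_names).duplicated()
        if dup.any():
            dupes = sorted(set(self.gene_names[dup]))
            raise DataError(f"duplicate gene names: {dupes}")
        if self.modality not in (SC_MODALITY, SPATIAL_MODALITY):
            raise DataError("modality must be 0 (scRNA-seq) or 1 (spatial)")
        if self.modality == SPATIAL_MODALITY:
            if self.coordinates is None:
                raise DataError("spatial dataset requires coordinates")
            self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
            if self.coordinates.shape != (n, 2):
                raise DataError(
                    f"coordinates shape {self.coordinates.shape} != ({n}, 2)"
                )
        elif self.coordinates is not None:
            raise DataError("scRNA-seq dataset must not carry coordinates")
        if self.cell_types is not None:
            self.cell_types = np.asarray(self.cell_types, dtype=object)
            if len(self.cell_types) != n:
                raise DataError("cell_types length mismatch")
        totals = self.counts.sum(axis=1)
        if np.any(totals <= 0):
            raise DataError(
                "dataset contains zero-count cells; filter at load time"
            )
        self.log_library = np.log(totals.astype(np.float64))

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes: Sequence[str]) -> "CountDataset":
        """Restrict to (and reorder as) ``genes``; log-library is unchanged
        in spirit but recomputed from the retained columns by the
        constructor, so the caller keeps the original when that matters."""
        idx = index_genes(self, genes)
        ds = CountDataset(
            counts=self.counts[:, idx],
            gene_names=np.asarray(genes, dtype=object),
            cell_ids=self.cell_ids,
            modality=self.modality,
            coordinates=None if self.coordinates is None else self.coordinates,
            cell_types=self.cell_types,
        )
        return ds


def index_genes(ds: CountDataset, genes: Sequence[str]) -> np.ndarray:
    lookup = {g: i for i, g in enumerate(ds.gene_names)}
    missing = [g for g in genes if g not in lookup]
    if missing:
        raise DataError(f"genes not in dataset: {missing}")
    return np.asarray([lookup[g] for g in genes], dtype=np.int64)


@dataclass
class PairedDataset:
    """A scRNA-seq reference paired with a spatial panel dataset.

    ``shared_genes`` maps each spatial gene (column index in ``sp``) to its
    column index in ``sc``; every spatial gene name must occur in the
    reference (the panel is a subset of the reference gene set).
    """

    sc: CountDataset
    sp: CountDataset
    shared_genes: np.ndarray      # (n_shared, 2): [sp_index, sc_index]

    @property
    def shared_gene_names(self) -> np.ndarray:
        return self.sp.gene_names[self.shared_genes[:, 0]]

    @property
    def missing_gene_names(self) -> np.ndarray:
        shared = set(self.shared_gene_names)
        return np.asarray(
            [g for g in self.sc.gene_names if g not in shared], dtype=object
        )


def pair_datasets(sc: CountDataset, sp: CountDataset) -> PairedDataset:
    """Match spatial genes into the reference gene list by exact name.

    Spatial genes absent from the reference are dropped with a warning;
    an empty intersection is an error.
    """
    if sc.modality != SC_MODALITY or sp.modality != SPATIAL_MODALITY:
        raise DataError("pair_datasets expects (scRNA-seq, spatial)")
    sc_lookup = {g: i for i, g in enumerate(sc.gene_names)}
    pairs = []
    dropped = []
    for j, g in enumerate(sp.gene_names):
        if g in sc_lookup:
            pairs.append((j, sc_lookup[g]))
        else:
            dropped.append(g)
    if not pairs:
        raise DataError("no shared genes between reference and spatial data")
    if dropped:
        logger.warning(
            "%d spatial genes absent from the reference were dropped: %s",
            len(dropped), dropped,
        )
        keep = [j for j, _ in pairs]
        sp = CountDataset(
            counts=sp.counts[:, keep],
            gene_names=sp.gene_names[keep],
            cell_ids=sp.cell_ids,
            modality=SPATIAL_MODALITY,
            coordinates=sp.coordinates,
            cell_types=sp.cell_types,
        )
        pairs = [(new_j, sc_lookup[g]) for new_j, g in enumerate(sp.gene_names)]
    return PairedDataset(sc=sc, sp=sp,
                         shared_genes=np.asarray(pairs, dtype=np.int64))


# ---------------------------------------------------------------------------
# loaders / writers
# ---------------------------------------------------------------------------

def _read_matrix(matrix_path: Path) -> np.ndarray:
    if matrix_path.suffix == ".mtx":
        mat = spio.mmread(str(matrix_path))
        return np.asarray(sparse.coo_matrix(mat).todense())
    return np.loadtxt(matrix_path, ndmin=2)


def _read_lines(path: Path) -> np.ndarray:
    with open(path) as fh:
        return np.asarray([ln.strip() for ln in fh if ln.strip()], dtype=object)


def load_dataset(
    matrix_path,
    genes_path,
    cells_path,
    coords_path=None,
    labels_path=None,
) -> CountDataset:
    """Load one modality from MTX (or dense delimited) plus metadata tables.

    Cells with zero total count are dropped and logged.  The modality is
    spatial iff ``coords_path`` is given.
    """
    matrix_path = Path(matrix_path)
    counts = _read_matrix(matrix_path)
    genes = _read_lines(Path(genes_path))
    cells = _read_lines(Path(cells_path))
    if counts.shape[1] != len(genes):
        raise DataError(
            f"{matrix_path}: {counts.shape[1]} columns but "
            f"{genes_path} lists {len(genes)} genes"
        )
    if counts.shape[0] != len(cells):
        raise DataError(
            f"{matrix_path}: {counts.shape[0]} rows but "
            f"{cells_path} lists {len(cells)} cells"
        )
    coords = None
    if coords_path is not None:
        cdf = pd.read_csv(coords_path).set_index("cell_id")
        try:
            coords = cdf.loc[cells, ["x", "y"]].to_numpy(dtype=np.float64)
        except KeyError as exc:
            raise DataError(f"{coords_path}: missing coordinates for cells ({exc})")
    labels = None
    if labels_path is not None:
        ldf = pd.read_csv(labels_path).set_index("cell_id")
        labels = ldf.loc[cells, "cell_type"].to_numpy(dtype=object)

    keep = counts.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "dropped %d zero-count cells: %s",
            n_dropped, list(cells[~keep]),
        )
    return CountDataset(
        counts=counts[keep],
        gene_names=genes,
        cell_ids=cells[keep],
        modality=SPATIAL_MODALITY if coords is not None else SC_MODALITY,
        coordinates=None if coords is None else coords[keep],
        cell_types=None if labels is None else labels[keep],
    )


def save_dataset(ds: CountDataset, out_dir) -> dict:
    """Write a dataset in the MTX + TSV/CSV layout; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "genes": out_dir / "genes.tsv",
        "cells": out_dir / "cells.tsv",
    }
    spio.mmwrite(str(paths["matrix"]), sparse.coo_matrix(ds.counts))
    paths["genes"].write_text("\n".join(map(str, ds.gene_names)) + "\n")
    paths["cells"].write_text("\n".join(map(str, ds.cell_ids)) + "\n")
    if ds.coordinates is not None:
        paths["coords"] = out_dir / "coordinates.csv"
        pd.DataFrame(
            {"cell_id": ds.cell_ids,
             "x": ds.coordinates[:, 0], "y": ds.coordinates[:, 1]}
        ).to_csv(paths["coords"], index=False)
    if ds.cell_types is not None:
        paths["labels"] = out_dir / "cell_types.csv"
        pd.DataFrame(
            {"cell_id": ds.cell_ids, "cell_type": ds.cell_types}
        ).to_csv(paths["labels"], index=False)
    return paths


def to_anndata(ds: CountDataset):
    """Convert to an :class:`anndata.AnnData` (counts in X)."""
    import anndata as adn

    obs = pd.DataFrame(index=pd.Index(ds.cell_ids.astype(str), name="cell_id"))
    if ds.cell_types is not None:
        obs["cell_type"] = pd.Categorical(ds.cell_types.astype(str))
    adata = adn.AnnData(
        X=sparse.csr_matrix(ds.counts.astype(np.float32)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(ds.gene_names.astype(str), name="gene")),
    )
    if ds.coordinates is not None:
        adata.obsm["spatial"] = ds.coordinates.copy()
    return adata


def from_anndata(adata, modality: Optional[int] = None) -> CountDataset:
    """Build a dataset from an AnnData: counts in X, coordinates in
    ``obsm['spatial']``, labels in ``obs['cell_type']``."""
    X = adata.X
    counts = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)
    coords = adata.obsm.get("spatial") if adata.obsm else None
    if modality is None:
        modality = SPATIAL_MODALITY if coords is not None else SC_MODALITY
    if modality == SC_MODALITY:
        coords = None
    labels = None
    if "cell_type" in adata.obs:
        labels = adata.obs["cell_type"].to_numpy(dtype=object)
    keep = counts.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d zero-count cells from AnnData", n_dropped)
    return CountDataset(
        counts=counts[keep],
        gene_names=adata.var_names.to_numpy(dtype=object),
        cell_ids=adata.obs_names.to_numpy(dtype=object)[keep],
        modality=modality,
        coordinates=None if coords is None else np.asarray(coords)[keep],
        cell_types=None if labels is None else labels[keep],
    )


def load_h5ad(path, modality: Optional[int] = None) -> CountDataset:
    import anndata as adn

    return from_anndata(adn.read_h5ad(path), modality=modality)
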