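"""Anchor-gene selection by pseudo-bulk correlation between modalities.

Shared genes whose per-cell-type mean profiles correlate strongly across
the scRNA-seq reference and the spatial panel (Pearson r > 0.5 at p < 0.05
over the shared cell types) are kept as "anchor" genes for training; the
rest are filtered out.  When either dataset lacks cell-type labels the
filter is skipped and every shared gene is kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import CountDataset, PairedDataset

logger = logging.getLogger(__name__)

__all__ = ["AnchorReport", "pseudobulk", "select_anchor_genes"]


@dataclass
class AnchorReport:
    table: pd.DataFrame   # index: gene; columns: r, p, kept
    r_min: float
    p_max: float
    skipped: bool = False

    @property
    def kept_genes(self) -> np.ndarray:
        return self.table.index[self.table["kept"]].to_numpy(dtype=object)

    def to_csv(self, path) -> None:
        out = self.table.reset_index().rename(columns={"index": "gene"})
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, r_min: float = 0.5, p_max: float = 0.05) -> "AnchorReport":
        df = pd.read_csv(path).set_index("gene")
        df["kept"] = df["kept"].astype(bool)
        return cls(table=df, r_min=r_min, p_max=p_max,
                   skipped=bool(df["r"].isna().all()))


def pseudobulk(ds: CountDataset, shared_types: Sequence[str],
               normalize: bool = True) -> np.ndarray:
    """Per-cell-type mean expression, one row per requested type.

    ``normalize`` scales each cell's counts to total 1 before averaging so
    library depth does not dominate the correlation; pass ``False`` for
    raw-count averaging.
    """
    if ds.cell_types is None:
        raise ValueError("dataset has no cell-type labels")
    expr = ds.counts.astype(np.float64)
    if normalize:
        expr = expr / expr.sum(axis=1, keepdims=True)
    rows = []
    for t in shared_types:
        mask = ds.cell_types == t
        if not mask.any():
            raise ValueError(f"cell type {t!r} has no cells in this dataset")
        rows.append(expr[mask].mean(axis=0))
    return np.vstack(rows)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple:
    """Pearson r with its two-sided t-test p; constant input gives (0, 1)."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def select_anchor_genes(
    paired: PairedDataset,
    r_min: float = 0.5,
    p_max: float = 0.05,
    normalize: bool = True,
    method: str = "pearson",
) -> AnchorReport:
    """Score every shared gene by cross-modality pseudo-bulk correlation.

    ``method='spearman'`` is available but discouraged: rank correlations
    over a handful of cell types are rarely significant, which starves the
    training gene set.
    """
    genes = paired.shared_gene_names
    sc, sp = paired.sc, paired.sp
    if sc.cell_types is None or sp.cell_types is None:
        logger.info("cell-type labels missing; anchor filter skipped, "
                    "all %d shared genes kept", len(genes))
        table = pd.DataFrame(
            {"r": np.nan, "p": np.nan, "kept": True},
            index=pd.Index(genes, name="gene"),
        )
        return AnchorReport(table=table, r_min=r_min, p_max=p_max, skipped=True)

    shared_types = sorted(set(sc.cell_types) & set(sp.cell_types))
    if len(shared_types) < 3:
        raise ValueError(
            f"only {len(shared_types)} shared cell types; the correlation "
            "p-value needs at least 3 — drop the labels to skip this step"
        )
    pb_sc = pseudobulk(sc, shared_types, normalize=normalize)
    pb_sp = pseudobulk(sp, shared_types, normalize=normalize)

    sp_idx = paired.shared_genes[:, 0]
    sc_idx = paired.shared_genes[:, 1]
    rs, ps = [], []
    for j_sp, j_sc in zip(sp_idx, sc_idx):
        x, y = pb_sc[:, j_sc], pb_sp[:, j_sp]
        if method == "spearman":
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                r, p = 0.0, 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, p = stats.spearmanr(x, y)
        else:
            r, p = _pearson(x, y)
        rs.append(r)
        ps.append(p)
    rs = np.asarray(rs, dtype=np.float64)
    ps = np.asarray(ps, dtype=np.float64)
    kept = (rs > r_min) & (ps < p_max)
    table = pd.DataFrame(
        {"r": rs, "p": ps, "kept": kept},
        index=pd.Index(genes, name="gene"),
    )
    logger.info("anchor filter kept %d / %d shared genes", kept.sum(), len(genes))
    return AnchorReport(table=table, r_min=r_min, p_max=p_max)
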