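"""QC filtering and log-normalization.

Nuclei are retained when they have more than ``min_genes`` detected genes and
fewer than ``max_mito_frac`` of their reads from mitochondrial genes (both
inequalities strict).  Normalization is the standard depth-scaled natural-log
transform: ``ln(1 + count / total * scale)``.
"""

from __future__ import annotations

import logging

import numpy as np

from .dataset import CellDataset
from .errors import DrgpnError

log = logging.getLogger(__name__)


def qc_filter(
    ds: CellDataset, min_genes: int = 1000, max_mito_frac: float = 0.10
) -> CellDataset:
    """Restrict to cells passing the detected-gene and mito-fraction filters.

    A cell is kept iff ``detected_genes > min_genes`` and
    ``mito_counts / total_counts < max_mito_frac``.  Cells with zero total
    counts have an undefined mito fraction and are removed (counted under the
    gene-number criterion).  The gene axis is unchanged.
    """
    if min_genes < 0 or max_mito_frac <= 0:
        raise DrgpnError("qc thresholds must be positive")
    detected = ds.detected_genes()
    total = ds.total_counts()
    mito = ds.mito_counts()
    pass_genes = detected > min_genes
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), np.nan)
    pass_mito = (total > 0) & (mito_frac < max_mito_frac)
    keep = pass_genes & pass_mito
    log.info(
        "qc_filter: %d/%d cells kept (%d failed gene-number, %d failed "
        "mito-fraction)",
        int(keep.sum()),
        ds.n_cells,
        int((~pass_genes).sum()),
        int((pass_genes & ~pass_mito).sum()),
    )
    if not keep.any():
        log.warning("qc_filter removed every cell")
    return ds.subset_cells(keep)


def log_normalize(ds: CellDataset, scale: float = 1e4) -> CellDataset:
    """Attach the log-normalized layer: ``ln(1 + count / total * scale)``.

    Counts are untouched.  Raises if any cell has zero total counts (run
    :func:`qc_filter` first).
    """
    total = ds.total_counts()
    if (total <= 0).any():
        raise DrgpnError(
            "cells with zero total counts present; run qc_filter before "
            "log_normalize"
        )
    # scale entries in place: CSR over genes x cells has cell ids in .indices
    scaled = ds.counts.astype(np.float64)
    scaled.data = np.log1p(scaled.data * (scale / total)[scaled.indices])
    return CellDataset(
        counts=ds.counts,
        cells=ds.cells.copy(),
        genes=ds.genes.copy(),
        lognorm=scaled,
    )


def pct_expressed(ds: CellDataset, gene: str, cell_mask: np.ndarray) -> float:
    """Fraction of masked cells with a nonzero count for ``gene``."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.sum() == 0:
        raise ValueError("cell mask selects no cells")
    row = ds.counts[ds.gene_index(gene), :]
    expressed = np.zeros(ds.n_cells, dtype=bool)
    expressed[row.indices] = True
    return float(expressed[cell_mask].sum() / cell_mask.sum())


def pct_expressed_matrix(ds: CellDataset, cell_mask: np.ndarray) -> np.ndarray:
    """Per-gene fraction of masked cells with nonzero count (vectorized)."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.sum() == 0:
        raise ValueError("cell mask selects no cells")
    sub = ds.counts[:, cell_mask]
    return sub.getnnz(axis=1) / cell_mask.sum()
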