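"""The universal data carrier: a genes x cells count matrix plus annotations.

Counts are kept genes x cells (the 10x triplet orientation) in CSR sparse
form.  Cell annotations live in a pandas DataFrame indexed by barcode, gene
annotations in a DataFrame indexed by gene symbol; row/column order of the
matrices and the tables is kept in lock-step by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import IntegrityError

CONDITIONS = ("Control", "Diabetic", "DPN")

#: cell annotation columns the pipeline understands (all but donor/condition
#: may be missing or null)
CELL_FIELDS = (
    "donor_id",
    "condition",
    "major_type",
    "neuron_subtype",
    "nageotte_score",
    "nodule_adjacent",
)


@dataclass
class CellDataset:
    """Sparse gene x cell counts with per-cell and per-gene annotation tables.

    Parameters
    ----------
    counts
        Non-negative integer matrix, genes x cells (any scipy sparse or dense
        array; stored as CSR).
    cells
        DataFrame indexed by barcode, one row per matrix column.
    genes
        DataFrame indexed by gene symbol, one row per matrix row; must carry
        a boolean ``is_mito`` column.
    lognorm
        Optional log-normalized layer with the same shape as ``counts``.
    """

    counts: sp.csr_matrix
    cells: pd.DataFrame
    genes: pd.DataFrame
    lognorm: Optional[sp.csr_matrix] = field(default=None)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.counts.eliminate_zeros()
        if self.counts.nnz and self.counts.data.min() < 0:
            raise IntegrityError("count matrix has negative entries")
        if self.counts.nnz and not np.allclose(
            self.counts.data, np.round(self.counts.data)
        ):
            raise IntegrityError("count matrix has non-integral entries")
        n_genes, n_cells = self.counts.shape
        if len(self.genes) != n_genes:
            raise IntegrityError(
                f"gene table has {len(self.genes)} rows but matrix has "
                f"{n_genes} gene rows"
            )
        if len(self.cells) != n_cells:
            raise IntegrityError(
                f"cell table has {len(self.cells)} rows but matrix has "
                f"{n_cells} cell columns"
            )
        if "is_mito" not in self.genes.columns:
            self.genes = self.genes.assign(is_mito=False)
        if "condition" in self.cells.columns:
            bad = set(self.cells["condition"].dropna()) - set(CONDITIONS)
            if bad:
                raise IntegrityError(f"unknown condition labels: {sorted(bad)}")
        if self.lognorm is not None:
            self.lognorm = sp.csr_matrix(self.lognorm)
            if self.lognorm.shape != self.counts.shape:
                raise IntegrityError("lognorm layer shape differs from counts")

    # ------------------------------------------------------------------ views
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_names(self) -> pd.Index:
        return self.genes.index

    @property
    def barcodes(self) -> pd.Index:
        return self.cells.index

    def gene_index(self, symbol: str) -> int:
        try:
            return int(self.genes.index.get_loc(symbol))
        except KeyError:
            raise KeyError(f"gene {symbol!r} not in dataset") from None

    # -------------------------------------------------------------- subsetting
    def subset_cells(self, mask: np.ndarray) -> "CellDataset":
        """Restrict to cells selected by a boolean mask or integer index."""
        mask = np.asarray(mask)
        if mask.dtype == bool and mask.shape[0] != self.n_cells:
            raise IntegrityError("cell mask length mismatch")
        counts = self.counts[:, mask]
        lognorm = self.lognorm[:, mask] if self.lognorm is not None else None
        return CellDataset(
            counts=counts,
            cells=self.cells.loc[np.asarray(self.barcodes)[mask]].copy()
            if mask.dtype == bool
            else self.cells.iloc[mask].copy(),
            genes=self.genes.copy(),
            lognorm=lognorm,
        )

    def subset_genes(self, symbols: Sequence[str]) -> "CellDataset":
        idx = [self.gene_index(s) for s in symbols]
        return CellDataset(
            counts=self.counts[idx, :],
            cells=self.cells.copy(),
            genes=self.genes.iloc[idx].copy(),
            lognorm=self.lognorm[idx, :] if self.lognorm is not None else None,
        )

    # --------------------------------------------------------------- summaries
    def total_counts(self) -> np.ndarray:
        """Total counts per cell (length n_cells)."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def detected_genes(self) -> np.ndarray:
        """Number of genes with count > 0 per cell."""
        return self.counts.getnnz(axis=0)

    def mito_counts(self) -> np.ndarray:
        """Total mitochondrial counts per cell."""
        mito = np.asarray(self.genes["is_mito"], dtype=bool)
        if not mito.any():
            return np.zeros(self.n_cells)
        return np.asarray(self.counts[mito, :].sum(axis=0)).ravel()
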