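"""Shared fixtures: small programmatically built datasets and cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from drgpn.dataset import CellDataset
from drgpn.preprocess import log_normalize, qc_filter
from drgpn.simulate import SyntheticConfig, generate_cohort


def make_dataset(
    counts: np.ndarray,
    gene_names=None,
    barcodes=None,
    lognorm: np.ndarray | None = None,
    **cell_columns,
) -> CellDataset:
    """Build a CellDataset from a dense genes x cells array."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    if gene_names is None:
        gene_names = [f"g{i}" for i in range(n_genes)]
    if barcodes is None:
        barcodes = [f"c{i}" for i in range(n_cells)]
    genes = pd.DataFrame(
        {"is_mito": [g.startswith("MT-") for g in gene_names]},
        index=pd.Index(gene_names, name="gene"),
    )
    cells = pd.DataFrame(cell_columns, index=pd.Index(barcodes, name="barcode"))
    return CellDataset(
        counts=sp.csr_matrix(counts),
        cells=cells,
        genes=genes,
        lognorm=sp.csr_matrix(lognorm) if lognorm is not None else None,
    )


def random_lognorm_dataset(
    n_genes: int, n_cells: int, seed: int, **cell_columns
) -> CellDataset:
    """Dataset with strictly positive random lognorm values (tie-free)."""
    rng = np.random.default_rng(seed)
    counts = rng.poisson(3.0, size=(n_genes, n_cells)) + 1
    lognorm = rng.gamma(2.0, 1.0, size=(n_genes, n_cells)) + 0.01
    return make_dataset(counts, lognorm=lognorm, **cell_columns)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort shared by read-only tests."""
    cfg = SyntheticConfig(
        n_donors=(3, 2, 2), cells_per_donor=200, n_genes=400, seed=11
    )
    ds, truth = generate_cohort(cfg)
    return ds, truth, cfg


@pytest.fixture(scope="session")
def small_cohort_normed(small_cohort):
    ds, truth, cfg = small_cohort
    # thresholds rescaled to the reduced 400-gene universe
    return log_normalize(qc_filter(ds, min_genes=150)), truth, cfg
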