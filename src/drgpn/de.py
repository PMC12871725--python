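"""Minimal differential-expression engines.

Two transparent engines sharing one output schema:

* ``de_rank_sum`` — per-cell Wilcoxon rank-sum on log-normalized expression
  (tie-corrected normal approximation with continuity correction, vectorized
  over genes; the exact-enumeration kernel is used when both groups are tiny).
* ``de_pseudobulk_nb`` — negative-binomial Wald test on pseudobulk profiles
  with median-ratio size factors and moment-estimated, trend-shrunk gene
  dispersions.

Output columns: gene, log2FC, p, p_adj, pct_a, pct_b, class; positive log2FC
means higher expression in the second-named condition.
"""

from __future__ import annotations

import logging
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata

from .dataset import CellDataset
from .errors import DrgpnError
from .preprocess import pct_expressed_matrix
from .stats import benjamini_hochberg, wilcoxon_rank_sum

log = logging.getLogger(__name__)

#: default |log2FC| significance threshold: log2(1.33)
DEFAULT_LFC = float(np.log2(1.33))

DE_COLUMNS = ["gene", "log2FC", "p", "p_adj", "pct_a", "pct_b", "class"]


def pseudobulk_aggregate(
    ds: CellDataset, keys: Sequence[str]
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Sum counts over every combination of the annotation ``keys``.

    Returns a dense genes x groups matrix and a group table recording the key
    values and cell counts of each group (zero-cell groups cannot occur).
    """
    for k in keys:
        if k not in ds.cells.columns:
            raise ValueError(f"annotation key {k!r} not in cell table")
    labels = ds.cells[list(keys)].astype(str).agg("\x1f".join, axis=1)
    cats = pd.Categorical(labels)
    n_groups = len(cats.categories)
    indicator = sp.csr_matrix(
        (
            np.ones(ds.n_cells),
            (np.arange(ds.n_cells), cats.codes),
        ),
        shape=(ds.n_cells, n_groups),
    )
    agg = np.asarray((ds.counts @ indicator).todense())
    parts = [c.split("\x1f") for c in cats.categories]
    group_table = pd.DataFrame(parts, columns=list(keys))
    group_table["n_cells"] = np.bincount(cats.codes, minlength=n_groups)
    return agg, group_table


def size_factors_median_ratio(pseudobulk: np.ndarray) -> np.ndarray:
    """DESeq-style median-of-ratios size factors, rescaled to geometric mean 1.

    Falls back to library-size factors (with a warning) when no gene is
    nonzero in every group.
    """
    pb = np.asarray(pseudobulk, dtype=float)
    if pb.shape[1] < 2:
        raise ValueError("need at least 2 groups")
    all_nonzero = (pb > 0).all(axis=1)
    if not all_nonzero.any():
        log.warning(
            "no gene expressed in every group; using library-size factors"
        )
        factors = pb.sum(axis=0)
        if (factors <= 0).any():
            raise DrgpnError("a pseudobulk group has zero total counts")
    else:
        ref = np.exp(np.log(pb[all_nonzero]).mean(axis=1, keepdims=True))
        factors = np.median(pb[all_nonzero] / ref, axis=0)
    factors = factors / np.exp(np.log(factors).mean())
    return factors


def _ranksum_p_matrix(values: np.ndarray, n_a: int) -> np.ndarray:
    """Vectorized tie-corrected normal-approximation rank-sum p per gene.

    ``values`` is genes x (cells of a then cells of b).  Mirrors the
    approximation branch of :func:`drgpn.stats.wilcoxon_rank_sum` exactly.
    """
    n_genes, total = values.shape
    n_b = total - n_a
    ranks = rankdata(values, axis=1)
    w = ranks[:, :n_a].sum(axis=1)
    mean_w = n_a * (total + 1) / 2.0
    # tie term per gene: sum over tied groups of t^3 - t
    sorted_vals = np.sort(values, axis=1)
    tie_term = np.zeros(n_genes)
    for g in range(n_genes):
        _, counts = np.unique(sorted_vals[g], return_counts=True)
        tie_term[g] = float((counts**3 - counts).sum())
    var_w = n_a * n_b / 12.0 * ((total + 1) - tie_term / (total * (total - 1)))
    p = np.ones(n_genes)
    ok = var_w > 0
    z = np.zeros(n_genes)
    z[ok] = (np.abs(w[ok] - mean_w) - 0.5) / np.sqrt(var_w[ok])
    z = np.maximum(z, 0.0)
    p[ok] = 2.0 * norm.sf(z[ok])
    return np.minimum(p, 1.0)


def de_rank_sum(
    ds: CellDataset,
    cell_mask_a: np.ndarray,
    cell_mask_b: np.ndarray,
    pseudocount: float = 1e-9,
    comparison: str = "a_vs_b",
) -> pd.DataFrame:
    """Per-cell rank-sum DE between two cell masks on log-normalized values.

    log2FC = log2((mean expm1(lognorm) in b + pc) / (mean in a + pc)); genes
    all-zero in both groups get p = 1, log2FC = 0 and are retained.
    """
    if ds.lognorm is None:
        raise DrgpnError("log-normalized layer absent; run log_normalize first")
    mask_a = np.asarray(cell_mask_a, dtype=bool)
    mask_b = np.asarray(cell_mask_b, dtype=bool)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both cell masks must select at least one cell")

    a = ds.lognorm[:, mask_a].toarray()
    b = ds.lognorm[:, mask_b].toarray()
    mean_a = np.expm1(a).mean(axis=1)
    mean_b = np.expm1(b).mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    n_a = a.shape[1]
    if n_a <= 10 and b.shape[1] <= 10:
        # tiny groups: reuse the scalar kernel (exact path when tie-free)
        p = np.array(
            [
                wilcoxon_rank_sum(a[g], b[g]).p_value
                for g in range(ds.n_genes)
            ]
        )
    else:
        p = _ranksum_p_matrix(np.hstack([a, b]), n_a)

    zero_both = (mean_a == 0) & (mean_b == 0)
    p[zero_both] = 1.0
    log2fc[zero_both] = 0.0

    out = pd.DataFrame(
        {
            "gene": ds.gene_names,
            "log2FC": log2fc,
            "p": p,
            "pct_a": pct_expressed_matrix(ds, mask_a),
            "pct_b": pct_expressed_matrix(ds, mask_b),
        }
    )
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    out["comparison"] = comparison
    return classify_deg(out)


def de_pseudobulk_nb(
    pseudobulk: np.ndarray,
    conditions: Sequence[str],
    cond_a: str,
    cond_b: str,
    gene_names: Sequence[str],
    comparison: str = "a_vs_b",
) -> pd.DataFrame:
    """Negative-binomial Wald test on pseudobulk replicate profiles.

    Model: counts ~ NB(mu = s_j * m_{g,cond}, dispersion alpha_g) with
    median-ratio size factors s_j.  Per-gene dispersion is estimated by the
    method of moments from within-condition residuals and shrunk toward the
    across-gene mean with weight n/(n+4).  The Wald statistic tests
    beta = log(m_b / m_a) with a delta-method variance.
    """
    pb = np.asarray(pseudobulk, dtype=float)
    conditions = np.asarray([str(c) for c in conditions])
    sel = np.isin(conditions, [cond_a, cond_b])
    pb = pb[:, sel]
    conditions = conditions[sel]
    in_b = conditions == cond_b
    n_a, n_b = int((~in_b).sum()), int(in_b.sum())
    if n_a < 2 or n_b < 2:
        raise DrgpnError(
            "de_pseudobulk_nb needs >= 2 replicates per condition; use "
            "de_rank_sum for unreplicated designs"
        )
    n = n_a + n_b
    s = size_factors_median_ratio(pb)
    s_a, s_b = s[~in_b], s[in_b]
    y_a, y_b = pb[:, ~in_b], pb[:, in_b]

    # offset-weighted group means (0.5-count continuity guard for empty groups)
    sum_a, sum_b = y_a.sum(axis=1), y_b.sum(axis=1)
    m_a = np.maximum(sum_a, 0.5) / s_a.sum()
    m_b = np.maximum(sum_b, 0.5) / s_b.sum()

    # moment dispersion from within-group residuals, pooled over both groups
    mu_a = s_a[np.newaxis, :] * (sum_a / s_a.sum())[:, np.newaxis]
    mu_b = s_b[np.newaxis, :] * (sum_b / s_b.sum())[:, np.newaxis]
    num = ((y_a - mu_a) ** 2 - mu_a).sum(axis=1) + (
        (y_b - mu_b) ** 2 - mu_b
    ).sum(axis=1)
    den = (mu_a**2).sum(axis=1) + (mu_b**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.where(den > 0, num / den, 0.0) * n / max(n - 2, 1)
    alpha_hat = np.maximum(alpha_hat, 0.0)
    expressed = (sum_a + sum_b) > 0
    trend = float(alpha_hat[expressed].mean()) if expressed.any() else 0.0
    alpha = (n * alpha_hat + 4.0 * trend) / (n + 4.0)

    beta = np.log(m_b) - np.log(m_a)  # natural-log condition coefficient
    mu_a_hat = s_a[np.newaxis, :] * m_a[:, np.newaxis]
    mu_b_hat = s_b[np.newaxis, :] * m_b[:, np.newaxis]
    var_a = (mu_a_hat + alpha[:, np.newaxis] * mu_a_hat**2).sum(axis=1) / (
        mu_a_hat.sum(axis=1) ** 2
    )
    var_b = (mu_b_hat + alpha[:, np.newaxis] * mu_b_hat**2).sum(axis=1) / (
        mu_b_hat.sum(axis=1) ** 2
    )
    se = np.sqrt(var_a + var_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    p[~expressed] = 1.0
    log2fc = beta / np.log(2.0)
    log2fc[~expressed] = 0.0

    frac_a = (y_a > 0).mean(axis=1)
    frac_b = (y_b > 0).mean(axis=1)
    out = pd.DataFrame(
        {
            "gene": list(gene_names),
            "log2FC": log2fc,
            "p": np.minimum(p, 1.0),
            "pct_a": frac_a,
            "pct_b": frac_b,
        }
    )
    out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    out["comparison"] = comparison
    return classify_deg(out)


def classify_deg(
    rows: pd.DataFrame, fdr: float = 0.05, lfc_threshold: float = DEFAULT_LFC
) -> pd.DataFrame:
    """Three-way up / down / ns classification at the given thresholds."""
    if "p_adj" not in rows.columns:
        raise ValueError("rows need a p_adj column (run BH first)")
    out = rows.copy()
    sig = out["p_adj"] < fdr
    up = sig & (out["log2FC"] > lfc_threshold)
    down = sig & (out["log2FC"] < -lfc_threshold)
    out["class"] = np.where(up, "up", np.where(down, "down", "ns"))
    cols = DE_COLUMNS + [c for c in out.columns if c not in DE_COLUMNS]
    return out[cols]
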