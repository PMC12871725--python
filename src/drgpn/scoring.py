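"""Per-nucleus gene-module scoring with expression-binned control genes, the
composite apoptosis trigger score, ApopHigh classification, and donor/subtype
summaries.

The module score of a cell is the mean log-normalized expression of the set
genes minus the mean over a pool of control genes drawn, per set gene, from
the expression bin of that gene (genes binned by mean expression across all
cells).  The composite trigger score is

    apoptosis + p53 + dna_repair + upr - survival,

and a nucleus is ApopHigh when its trigger score is at or above the 90th
percentile of the pooled score distribution.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import CellDataset
from .errors import DrgpnError
from .io import GeneSetCollection
from .simulate import MODULE_NAMES
from .stats import benjamini_hochberg, kruskal_wallis, wilcoxon_rank_sum

log = logging.getLogger(__name__)

APOP_HIGH = "ApopHigh"
APOP_LOW = "ApopLow"


def _row_means(lognorm, rows: np.ndarray, n_cells: int) -> np.ndarray:
    """Mean lognorm over the given gene rows, per cell."""
    sub = lognorm[rows, :]
    return np.asarray(sub.sum(axis=0)).ravel() / len(rows)


def score_gene_module(
    ds: CellDataset,
    gene_set: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Expression-bin-matched module score, one value per cell.

    Algorithm (deterministic given ``seed``):

    1. Rank all genes by mean log-normalized expression across cells
       (stable argsort) and split the ranked list into ``n_bins``
       near-equal-size bins (``np.array_split`` convention: earlier bins get
       the extra gene when sizes differ).
    2. Keep the set genes present in the dataset, in ``gene_set`` order,
       deduplicated; absent genes are dropped with a warning.
    3. With ``rng = np.random.default_rng(seed)``, for each retained set gene
       in that order draw ``n_ctrl`` control genes from its bin excluding all
       set genes: without replacement when the pool has at least ``n_ctrl``
       genes, with replacement otherwise.  An empty pool falls back to the
       bin without exclusion (warning).
    4. score(cell) = mean lognorm over set genes - mean lognorm over the
       pooled control draw (a multiset).
    """
    if ds.lognorm is None:
        raise DrgpnError("log-normalized layer absent; run log_normalize first")
    if n_bins > ds.n_genes:
        raise ValueError(f"n_bins={n_bins} exceeds number of genes {ds.n_genes}")
    present = []
    seen = set()
    for g in gene_set:
        if g in seen:
            continue
        seen.add(g)
        if g in ds.genes.index:
            present.append(g)
    dropped = len(seen) - len(present)
    if dropped:
        log.warning("score_gene_module: %d set genes absent, dropped", dropped)
    if not present:
        raise DrgpnError(f"no gene of the set is present in the dataset: {list(gene_set)[:5]}")

    gene_means = np.asarray(ds.lognorm.mean(axis=1)).ravel()
    order = np.argsort(gene_means, kind="stable")
    bins = np.array_split(order, n_bins)
    bin_of = np.empty(ds.n_genes, dtype=int)
    for b, members in enumerate(bins):
        bin_of[members] = b

    set_idx = np.array([ds.gene_index(g) for g in present])
    set_lookup = set(set_idx.tolist())
    rng = np.random.default_rng(seed)
    control_idx: List[np.ndarray] = []
    for gi in set_idx:
        members = bins[bin_of[gi]]
        pool = members[np.array([m not in set_lookup for m in members])]
        if pool.size == 0:
            log.warning(
                "control bin for gene %s contains only set genes; sampling "
                "from the full bin",
                ds.gene_names[gi],
            )
            pool = members
        if pool.size >= n_ctrl:
            draw = rng.choice(pool, size=n_ctrl, replace=False)
        else:
            draw = rng.choice(pool, size=n_ctrl, replace=True)
        control_idx.append(draw)
    controls = np.concatenate(control_idx)

    set_mean = _row_means(ds.lognorm, set_idx, ds.n_cells)
    ctrl_mean = _row_means(ds.lognorm, controls, ds.n_cells)
    return set_mean - ctrl_mean


def score_modules(
    ds: CellDataset,
    modules: GeneSetCollection,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every module of a collection; one seeded rng stream per module
    (seed offset by module position, keeping modules independent and the
    whole table reproducible)."""
    out = {}
    for k, name in enumerate(modules.names()):
        out[name] = score_gene_module(
            ds, modules[name], n_bins=n_bins, n_ctrl=n_ctrl, seed=seed + k
        )
    return pd.DataFrame(out, index=ds.barcodes)


def apoptosis_trigger_score(scores: Mapping[str, np.ndarray]) -> np.ndarray:
    """Composite score: apoptosis + p53 + dna_repair + upr - survival."""
    missing = [m for m in MODULE_NAMES if m not in scores]
    if missing:
        raise DrgpnError(f"missing module scores: {missing}")
    lengths = {m: len(np.asarray(scores[m])) for m in MODULE_NAMES}
    if len(set(lengths.values())) != 1:
        raise DrgpnError(f"module score vectors differ in length: {lengths}")
    return (
        np.asarray(scores["apoptosis"], dtype=float)
        + np.asarray(scores["p53"], dtype=float)
        + np.asarray(scores["dna_repair"], dtype=float)
        + np.asarray(scores["upr"], dtype=float)
        - np.asarray(scores["survival"], dtype=float)
    )


def classify_apop_high(trigger: np.ndarray, quantile: float = 0.90) -> np.ndarray:
    """Label each cell ApopHigh iff its score is at or above the pooled
    linear-interpolation quantile threshold."""
    trigger = np.asarray(trigger, dtype=float)
    if trigger.size == 0:
        raise ValueError("empty score vector")
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    threshold = float(np.quantile(trigger, quantile))
    labels = np.where(trigger >= threshold, APOP_HIGH, APOP_LOW)
    if (labels == APOP_HIGH).all():
        log.warning("every cell classified ApopHigh (constant scores?)")
    return labels


def build_score_table(
    ds: CellDataset,
    modules: GeneSetCollection,
    n_bins: int = 24,
    n_ctrl: int = 100,
    quantile: float = 0.90,
    seed: int = 0,
) -> pd.DataFrame:
    """Full per-cell score table: five module scores, trigger score, ApopHigh
    class, and carried annotations."""
    table = score_modules(ds, modules, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    table["trigger_score"] = apoptosis_trigger_score(
        {m: table[m].to_numpy() for m in MODULE_NAMES}
    )
    table["apop_class"] = classify_apop_high(
        table["trigger_score"].to_numpy(), quantile=quantile
    )
    for col in ("donor_id", "condition", "neuron_subtype", "major_type"):
        if col in ds.cells.columns:
            table[col] = ds.cells[col].to_numpy()
    return table


_GROUPINGS = {
    "condition": ["condition"],
    "subtype_condition": ["neuron_subtype", "condition"],
    "donor_condition": ["donor_id", "condition"],
}


def apop_high_summary(table: pd.DataFrame, by: str = "condition") -> pd.DataFrame:
    """Counts and proportion of ApopHigh cells per group.

    ``by`` is one of ``condition``, ``subtype_condition``, ``donor_condition``.
    Groups with zero cells are omitted (they never appear in a groupby).
    """
    if by not in _GROUPINGS:
        raise ValueError(f"unknown grouping {by!r}; pick from {sorted(_GROUPINGS)}")
    keys = _GROUPINGS[by]
    df = table.dropna(subset=[k for k in keys if k != "condition"])
    grouped = df.groupby(keys, observed=True, dropna=True)
    out = grouped["apop_class"].agg(
        total="size", n_high=lambda s: int((s == APOP_HIGH).sum())
    )
    out["prop_high"] = out["n_high"] / out["total"]
    return out.reset_index()


def donor_condition_test(summary: pd.DataFrame) -> Dict[str, object]:
    """Kruskal-Wallis across the three conditions on donor-level ApopHigh
    proportions, plus pairwise rank-sum tests with BH adjustment.

    Expects the ``donor_condition`` summary (one row per donor x condition).
    Conditions with fewer than 2 donors are dropped from the omnibus with a
    warning.
    """
    groups = {}
    for cond, sub in summary.groupby("condition", observed=True):
        vals = sub["prop_high"].to_numpy(dtype=float)
        if len(vals) < 2:
            log.warning(
                "condition %s has %d donor(s); excluded from omnibus", cond, len(vals)
            )
            continue
        groups[cond] = vals
    if len(groups) < 2:
        raise DrgpnError("need at least 2 conditions with >= 2 donors")
    omnibus = kruskal_wallis(list(groups.values()))
    conds = list(groups)
    pairs = [
        (conds[i], conds[j])
        for i in range(len(conds))
        for j in range(i + 1, len(conds))
    ]
    raw = [wilcoxon_rank_sum(groups[a], groups[b]) for a, b in pairs]
    adj = benjamini_hochberg([t.p_value for t in raw])
    pairwise = pd.DataFrame(
        {
            "cond_a": [a for a, _ in pairs],
            "cond_b": [b for _, b in pairs],
            "statistic": [t.statistic for t in raw],
            "p": [t.p_value for t in raw],
            "p_adj": adj,
        }
    )
    return {"omnibus": omnibus, "pairwise": pairwise}
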