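"""Ligand -> receptor interactome: eligibility filtering, scoring, ranking.

Ligands originate in non-neuronal DRG cells, receptors in neurons.  A
(pair, comparison) record is eligible when all of the following hold:

* C1   — ligand OR receptor differentially expressed (p_adj < alpha) in that
         comparison;
* C2   — NOT both significant with opposite log2FC signs in that comparison;
* C3a  — receptor pseudobulk log-normalized expression >= 0.01 in at least
         one neuronal population;
* C3b  — receptor expressed in >= 5% of all neurons in at least one condition;
* C3c  — ligand expressed in >= 0.1% of all DRG cells in at least one
         condition.

Eligible records are scored with s(gene) = |log2FC| * (-log10 p_adj) * pct
summed over ligand and receptor, and pairs are ranked by their best record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dataset import CellDataset
from .errors import FormatError
from .preprocess import pct_expressed_matrix

log = logging.getLogger(__name__)

P_ADJ_FLOOR = 1e-300
RECEPTOR_POP_MIN = 0.01
RECEPTOR_PCT_MIN = 0.05
LIGAND_PCT_MIN = 0.001

COMPARISONS = ("control_vs_diabetic", "diabetic_vs_dpn", "control_vs_dpn")


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str
    source: str = ""


def load_lr_pairs(path: str) -> List[LRPair]:
    """Read a ligand-receptor pair table (TSV, header with columns ``ligand``
    and ``receptor``); symbols upper-cased, duplicates dropped."""
    df = pd.read_csv(path, sep="\t")
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    seen = set()
    pairs = []
    source_col = "source" if "source" in df.columns else None
    for _, row in df.iterrows():
        lig = str(row["ligand"]).strip().upper()
        rec = str(row["receptor"]).strip().upper()
        if (lig, rec) in seen:
            continue
        seen.add((lig, rec))
        pairs.append(
            LRPair(lig, rec, str(row[source_col]) if source_col else "")
        )
    return pairs


def receptor_population_expression(
    ds: CellDataset, populations: Optional[Sequence[str]] = None, scale: float = 1e4
) -> pd.DataFrame:
    """Pseudobulk log-normalized expression per neuronal population.

    Counts are summed over the cells of each population, the pseudobulk
    column is depth-normalized to ``scale`` and natural-log transformed
    (ln(1 + count/total * scale)).  Returns populations x genes.  Populations
    with zero cells are dropped with a warning.
    """
    subtypes = ds.cells["neuron_subtype"]
    if populations is None:
        populations = sorted(subtypes.dropna().astype(str).unique())
    rows = {}
    for pop in populations:
        mask = (subtypes == pop).to_numpy()
        if mask.sum() == 0:
            log.warning("population %r has no cells; dropped", pop)
            continue
        col = np.asarray(ds.counts[:, mask].sum(axis=1)).ravel()
        total = col.sum()
        if total == 0:
            log.warning("population %r has zero counts; dropped", pop)
            continue
        rows[pop] = np.log1p(col / total * scale)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=ds.gene_names
    )


def pct_by_condition(
    ds: CellDataset, cell_mask: np.ndarray
) -> pd.DataFrame:
    """Per-gene expressed-cell fraction within the masked cells, split by
    condition (genes x conditions)."""
    cell_mask = np.asarray(cell_mask, dtype=bool)
    out = {}
    for cond in ds.cells["condition"].dropna().unique():
        m = cell_mask & (ds.cells["condition"] == cond).to_numpy()
        if m.sum() == 0:
            continue
        out[str(cond)] = pct_expressed_matrix(ds, m)
    return pd.DataFrame(out, index=ds.gene_names)


def filter_interactions(
    pairs: Sequence[LRPair],
    de_nonneuronal: Mapping[str, pd.DataFrame],
    de_neuronal: Mapping[str, pd.DataFrame],
    pop_expr: pd.DataFrame,
    pct_ligand_by_condition: pd.DataFrame,
    pct_receptor_by_condition: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Evaluate eligibility flags for every (pair, comparison) record.

    ``de_nonneuronal``/``de_neuronal`` map each of the three comparison labels
    to a DE table.  Returns one row per (pair, comparison) with per-criterion
    flags and an ``eligible`` conjunction.
    """
    missing = [c for c in COMPARISONS if c not in de_nonneuronal or c not in de_neuronal]
    if missing:
        raise ValueError(f"missing DE tables for comparisons: {missing}")

    de_l = {c: de_nonneuronal[c].set_index("gene") for c in COMPARISONS}
    de_r = {c: de_neuronal[c].set_index("gene") for c in COMPARISONS}

    def stats(table: pd.DataFrame, gene: str) -> Tuple[float, float, bool]:
        if gene in table.index:
            row = table.loc[gene]
            return float(row["log2FC"]), float(row["p_adj"]), True
        return 0.0, 1.0, False

    records = []
    for pair in pairs:
        lig, rec = pair.ligand, pair.receptor
        if rec in pop_expr.columns:
            max_pop = float(pop_expr[rec].max())
        else:
            max_pop = 0.0
        c3a = max_pop >= RECEPTOR_POP_MIN
        rec_pct = (
            float(pct_receptor_by_condition.loc[rec].max())
            if rec in pct_receptor_by_condition.index
            else 0.0
        )
        c3b = rec_pct >= RECEPTOR_PCT_MIN
        lig_pct = (
            float(pct_ligand_by_condition.loc[lig].max())
            if lig in pct_ligand_by_condition.index
            else 0.0
        )
        c3c = lig_pct >= LIGAND_PCT_MIN
        for comp in COMPARISONS:
            l_fc, l_padj, l_present = stats(de_l[comp], lig)
            r_fc, r_padj, r_present = stats(de_r[comp], rec)
            c1 = (l_padj < alpha) or (r_padj < alpha)
            opposite = (
                l_padj < alpha
                and r_padj < alpha
                and np.sign(l_fc) * np.sign(r_fc) < 0
            )
            c2 = not opposite
            eligible = c1 and c2 and c3a and c3b and c3c
            records.append(
                {
                    "ligand": lig,
                    "receptor": rec,
                    "source": pair.source,
                    "comparison": comp,
                    "ligand_log2FC": l_fc,
                    "ligand_p_adj": l_padj,
                    "ligand_pct": lig_pct,
                    "ligand_in_de": l_present,
                    "receptor_log2FC": r_fc,
                    "receptor_p_adj": r_padj,
                    "receptor_pct": rec_pct,
                    "receptor_in_de": r_present,
                    "receptor_max_pop_lognorm": max_pop,
                    "c1_de": c1,
                    "c2_not_opposite": c2,
                    "c3a_pop_expr": c3a,
                    "c3b_receptor_pct": c3b,
                    "c3c_ligand_pct": c3c,
                    "eligible": eligible,
                }
            )
    return pd.DataFrame(records)


def _gene_score(log2fc: float, p_adj: float, pct: float) -> float:
    return abs(log2fc) * (-np.log10(max(p_adj, P_ADJ_FLOOR))) * pct


def score_and_rank(records: pd.DataFrame, k: int = 50) -> pd.DataFrame:
    """Score eligible records, rank pairs by their best record, export top-k.

    Record score = s(ligand) + s(receptor) with
    s(g) = |log2FC| * (-log10 max(p_adj, 1e-300)) * pct.  A pair's overall
    score is the max over its eligible records; ranking is by descending
    score with lexicographic (ligand, receptor) tie-break.  Returns the
    records table with ``score`` and per-pair ``rank`` (rank only on eligible
    records); the top-k unique pairs are the rows with rank <= k.
    """
    out = records.copy()
    if not out["eligible"].any():
        raise ValueError("no eligible interaction record")
    score = np.full(len(out), np.nan)
    elig = out["eligible"].to_numpy()
    score[elig] = [
        _gene_score(r.ligand_log2FC, r.ligand_p_adj, r.ligand_pct)
        + _gene_score(r.receptor_log2FC, r.receptor_p_adj, r.receptor_pct)
        for r in out[elig].itertuples()
    ]
    out["score"] = score

    pair_best = (
        out[elig]
        .groupby(["ligand", "receptor"], as_index=False)["score"]
        .max()
        .sort_values(
            ["score", "ligand", "receptor"], ascending=[False, True, True]
        )
        .reset_index(drop=True)
    )
    pair_best["rank"] = np.arange(1, len(pair_best) + 1)
    if k > len(pair_best):
        log.warning(
            "requested top %d but only %d eligible pairs", k, len(pair_best)
        )
    rank_map = {
        (r.ligand, r.receptor): int(r.rank) for r in pair_best.itertuples()
    }
    out["rank"] = [
        rank_map.get((l, r)) if e else None
        for l, r, e in zip(out["ligand"], out["receptor"], out["eligible"])
    ]
    out["rank"] = out["rank"].astype("Int64")
    return out


def top_k_pairs(records: pd.DataFrame, k: int = 50) -> pd.DataFrame:
    """Unique top-k pair table (one row per pair, best comparison kept)."""
    elig = records[records["eligible"] & records["rank"].notna()].copy()
    elig = elig.sort_values(
        ["rank", "score"], ascending=[True, False]
    ).drop_duplicates(["ligand", "receptor"], keep="first")
    return elig[elig["rank"] <= k].reset_index(drop=True)


def best_ligand_source(
    ds: CellDataset, ligand: str, scale: float = 1e4
) -> Optional[str]:
    """Non-neuronal major type with the highest mean log-normalized ligand
    expression (the presumed cellular source of the ligand)."""
    if ds.lognorm is None or ligand not in ds.genes.index:
        return None
    gi = ds.gene_index(ligand)
    row = ds.lognorm[gi, :].toarray().ravel()
    best, best_val = None, -np.inf
    for mt, sub in ds.cells.groupby("major_type", observed=True):
        if mt == "Neurons":
            continue
        mask = (ds.cells["major_type"] == mt).to_numpy()
        val = row[mask].mean() if mask.any() else -np.inf
        if val > best_val:
            best, best_val = mt, val
    return best


def sankey_edges(
    ds: CellDataset, top: pd.DataFrame
) -> pd.DataFrame:
    """Sankey-ready edges: source cell type, ligand, receptor, score."""
    rows = []
    for r in top.itertuples():
        rows.append(
            {
                "source_cell_type": best_ligand_source(ds, r.ligand) or "unknown",
                "ligand": r.ligand,
                "receptor": r.receptor,
                "score": r.score,
            }
        )
    return pd.DataFrame(rows, columns=["source_cell_type", "ligand", "receptor", "score"])
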