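"""Configuration-driven orchestration of the full analysis:

simulate -> QC -> log-normalize -> module scoring -> proportion tests ->
differential expression -> interactome, with per-stage TSV outputs, a manifest
(config hash + seeds + versions) and deterministic reruns.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import CellDataset
from .de import DEFAULT_LFC, de_pseudobulk_nb, de_rank_sum, pseudobulk_aggregate
from .errors import ConfigError
from .interactome import (
    COMPARISONS,
    LRPair,
    filter_interactions,
    pct_by_condition,
    receptor_population_expression,
    sankey_edges,
    score_and_rank,
    top_k_pairs,
)
from .io import write_cells_tsv, write_counts_10x, write_table
from .preprocess import log_normalize, qc_filter
from .scoring import apop_high_summary, build_score_table, donor_condition_test
from .proportions import proportion_test
from .simulate import (
    PlantedEffect,
    SyntheticConfig,
    default_modules,
    dpn_apoptosis_effects,
    gene_names,
    generate_cohort,
)

log = logging.getLogger(__name__)

#: comparison label -> (condition a, condition b)
COMPARISON_CONDITIONS: Dict[str, Tuple[str, str]] = {
    "control_vs_diabetic": ("Control", "Diabetic"),
    "diabetic_vs_dpn": ("Diabetic", "DPN"),
    "control_vs_dpn": ("Control", "DPN"),
}

#: default Nageotte burden strata; the printed bins overlap at 4 and the
#: overlap is resolved High-wins (a score-4 ganglion counts as High)
DEFAULT_NAGEOTTE_STRATA = {"low_max": 2.0, "high_min": 4.0}


def stratify_nageotte(
    score: Optional[float],
    low_max: float = 2.0,
    high_min: float = 4.0,
) -> str:
    """Map a 0-5 Nageotte nodule score to a burden stratum.

    Default mapping: score <= 2 -> Low; 2 < score < 4 -> Moderate-High;
    score >= 4 -> High; missing -> Unscored.  The boundaries are overridable
    because the source bins (1-2 / 3-4 / 4-5) overlap at 4.
    """
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return "Unscored"
    score = float(score)
    if not (0.0 <= score <= 5.0):
        raise ValueError(f"Nageotte score {score} outside [0, 5]")
    if score <= low_max:
        return "Low"
    if score >= high_min:
        return "High"
    return "Moderate-High"


@dataclass
class RunConfig:
    """All knobs of a full pipeline run (YAML round-trippable)."""

    seed: int = 0
    # cohort
    n_donors: Tuple[int, int, int] = (14, 10, 6)
    cells_per_donor: int = 1000
    n_genes: int = 2000
    plant_default_effects: bool = True
    n_decoy_pairs: int = 200
    # QC / normalization
    min_genes: int = 1000
    max_mito_frac: float = 0.10
    scale: float = 1e4
    # scoring
    n_bins: int = 24
    n_ctrl: int = 100
    quantile: float = 0.90
    # testing thresholds
    fdr: float = 0.05
    lfc_proportions: float = 0.585
    lfc_de: float = DEFAULT_LFC
    n_perm: int = 1000
    n_boot: int = 1000
    top_k: int = 50
    comparisons: Tuple[str, ...] = ("control_vs_diabetic", "diabetic_vs_dpn")
    nageotte_strata: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NAGEOTTE_STRATA)
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.quantile < 1.0):
            raise ConfigError("quantile must be in (0, 1)")
        if not (0.0 < self.fdr < 1.0):
            raise ConfigError("fdr must be in (0, 1)")
        for comp in self.comparisons:
            if comp not in COMPARISON_CONDITIONS:
                raise ConfigError(
                    f"unknown comparison {comp!r}; valid: "
                    f"{sorted(COMPARISON_CONDITIONS)}"
                )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("n_donors", "comparisons"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        data["n_donors"] = list(data["n_donors"])
        data["comparisons"] = list(data["comparisons"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def canonical_hash(self) -> str:
        data = asdict(self)
        data["n_donors"] = list(data["n_donors"])
        data["comparisons"] = list(data["comparisons"])
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# planted ligand/receptor genes for the synthetic interactome stage
PLANTED_LIGAND = "G0500"
PLANTED_RECEPTOR = "G0600"


def default_planted_effects(n_genes: int) -> Tuple[PlantedEffect, ...]:
    """The canonical synthetic ground truth: apoptosis-module upregulation in
    three Ab-LTMR subtypes under DPN, an ATF3 proportion increase and a
    fibroblast increase in DPN, and one ligand/receptor pair upregulated in
    DPN (ligand in fibroblasts, receptor in neurons)."""
    effects = list(dpn_apoptosis_effects(n_genes=n_genes))
    effects.append(
        PlantedEffect(
            kind="proportion_shift",
            condition="DPN",
            target_type="ATF3",
            log2_fold_change=1.5,
        )
    )
    effects.append(
        PlantedEffect(
            kind="proportion_shift",
            condition="DPN",
            target_type="Fibroblasts",
            log2_fold_change=0.7,
        )
    )
    effects.append(
        PlantedEffect(
            kind="expression_shift",
            condition="DPN",
            target_genes=(PLANTED_LIGAND,),
            log2_fold_change=2.0,
            cell_selector={"major_type": "Fibroblasts"},
        )
    )
    effects.append(
        PlantedEffect(
            kind="expression_shift",
            condition="DPN",
            target_genes=(PLANTED_RECEPTOR,),
            log2_fold_change=1.0,
            cell_selector={"major_type": "Neurons"},
        )
    )
    return tuple(effects)


def make_lr_pairs(
    n_genes: int, n_decoys: int = 200, seed: int = 0
) -> List[LRPair]:
    """The planted ligand-receptor pair plus seeded random decoy pairs drawn
    from the synthetic gene names (module and mito genes excluded)."""
    names = gene_names(n_genes)
    modules = default_modules(n_genes)
    member = set(g for gs in modules.sets.values() for g in gs)
    member |= {PLANTED_LIGAND, PLANTED_RECEPTOR}
    pool = [n for n in names if n not in member and not n.startswith("MT-")]
    rng = np.random.default_rng(seed + 77)
    pairs = [LRPair(PLANTED_LIGAND, PLANTED_RECEPTOR, "planted")]
    seen = {(PLANTED_LIGAND, PLANTED_RECEPTOR)}
    while len(pairs) <= n_decoys:
        lig, rec = rng.choice(pool, size=2, replace=False)
        if (lig, rec) in seen:
            continue
        seen.add((lig, rec))
        pairs.append(LRPair(str(lig), str(rec), "decoy"))
    return pairs


def _neuron_mask(ds: CellDataset) -> np.ndarray:
    return (ds.cells["major_type"] == "Neurons").to_numpy()


def compute_de_tables(
    ds: CellDataset, comparisons=COMPARISONS
) -> Tuple[Dict[str, pd.DataFrame], Dict[str, pd.DataFrame]]:
    """Rank-sum DE tables per comparison for non-neuronal cells and neurons
    (the inputs of the interactome filter)."""
    neurons = _neuron_mask(ds)
    conds = ds.cells["condition"].to_numpy()
    de_nonneuronal, de_neuronal = {}, {}
    for comp in comparisons:
        a, b = COMPARISON_CONDITIONS[comp]
        in_a, in_b = conds == a, conds == b
        de_nonneuronal[comp] = de_rank_sum(
            ds, in_a & ~neurons, in_b & ~neurons, comparison=comp
        )
        de_neuronal[comp] = de_rank_sum(
            ds, in_a & neurons, in_b & neurons, comparison=comp
        )
    return de_nonneuronal, de_neuronal


def run_all(config: RunConfig, outdir: str) -> str:
    """Execute the full stage graph; returns the run directory.

    Rerunning with an identical config writes byte-identical tables.
    """
    os.makedirs(outdir, exist_ok=True)
    log.info("run_all: outdir=%s seed=%d", outdir, config.seed)

    # --- simulate -----------------------------------------------------------
    planted = (
        default_planted_effects(config.n_genes)
        if config.plant_default_effects
        else ()
    )
    cohort_cfg = SyntheticConfig(
        n_donors=config.n_donors,
        cells_per_donor=config.cells_per_donor,
        n_genes=config.n_genes,
        planted_effects=planted,
        seed=config.seed,
    )
    ds_raw, truth = generate_cohort(cohort_cfg)
    write_counts_10x(ds_raw, os.path.join(outdir, "counts_10x"))
    write_cells_tsv(ds_raw.cells, os.path.join(outdir, "cells.tsv"))
    write_table(truth, os.path.join(outdir, "truth.tsv"))

    # --- QC + normalize -----------------------------------------------------
    ds = qc_filter(ds_raw, min_genes=config.min_genes, max_mito_frac=config.max_mito_frac)
    if ds.n_cells == 0:
        raise ConfigError("QC removed every cell; check cohort parameters")
    ds = log_normalize(ds, scale=config.scale)

    # --- module scoring (neurons) ------------------------------------------
    modules = default_modules(config.n_genes)
    neurons = ds.subset_cells(_neuron_mask(ds))
    score_table = build_score_table(
        neurons,
        modules,
        n_bins=config.n_bins,
        n_ctrl=config.n_ctrl,
        quantile=config.quantile,
        seed=config.seed,
    )
    write_table(
        score_table.reset_index().rename(columns={"index": "barcode"}),
        os.path.join(outdir, "scores.tsv"),
    )
    for by in ("condition", "subtype_condition", "donor_condition"):
        write_table(
            apop_high_summary(score_table, by=by),
            os.path.join(outdir, f"apop_summary_{by}.tsv"),
        )
    donor_summary = apop_high_summary(score_table, by="donor_condition")
    tests = donor_condition_test(donor_summary)
    donor_tests = tests["pairwise"].copy()
    donor_tests.insert(0, "test", "pairwise_wilcoxon")
    omnibus_row = pd.DataFrame(
        {
            "test": ["kruskal_wallis"],
            "cond_a": ["all"],
            "cond_b": ["all"],
            "statistic": [tests["omnibus"].statistic],
            "p": [tests["omnibus"].p_value],
            "p_adj": [np.nan],
        }
    )
    write_table(
        pd.concat([omnibus_row, donor_tests], ignore_index=True),
        os.path.join(outdir, "donor_tests.tsv"),
    )

    # --- proportion tests ---------------------------------------------------
    for comp in config.comparisons:
        a, b = COMPARISON_CONDITIONS[comp]
        major = proportion_test(
            ds.cells, a, b, "major_type",
            n_perm=config.n_perm, n_boot=config.n_boot,
            fdr=config.fdr, lfc_threshold=config.lfc_proportions,
            seed=config.seed,
        )
        write_table(major, os.path.join(outdir, f"props_major_{comp}.tsv"))
        sub = proportion_test(
            ds.cells[_neuron_mask(ds)], a, b, "neuron_subtype",
            n_perm=config.n_perm, n_boot=config.n_boot,
            fdr=config.fdr, lfc_threshold=config.lfc_proportions,
            seed=config.seed,
        )
        write_table(sub, os.path.join(outdir, f"props_subtype_{comp}.tsv"))

    # --- differential expression -------------------------------------------
    de_nonneuronal, de_neuronal = compute_de_tables(ds)
    for comp in COMPARISONS:
        write_table(
            de_nonneuronal[comp], os.path.join(outdir, f"de_nonneuronal_{comp}.tsv")
        )
        write_table(
            de_neuronal[comp], os.path.join(outdir, f"de_neuronal_{comp}.tsv")
        )
    pb, groups = pseudobulk_aggregate(ds, ["donor_id", "condition"])
    for comp in COMPARISONS:
        a, b = COMPARISON_CONDITIONS[comp]
        nb = de_pseudobulk_nb(
            pb, groups["condition"], a, b, ds.gene_names, comparison=comp
        )
        write_table(nb, os.path.join(outdir, f"de_pseudobulk_{comp}.tsv"))

    # --- interactome --------------------------------------------------------
    pairs = make_lr_pairs(
        config.n_genes, n_decoys=config.n_decoy_pairs, seed=config.seed
    )
    neurons_mask = _neuron_mask(ds)
    pop_expr = receptor_population_expression(ds)
    records = filter_interactions(
        pairs,
        de_nonneuronal,
        de_neuronal,
        pop_expr,
        pct_ligand_by_condition=pct_by_condition(ds, np.ones(ds.n_cells, bool)),
        pct_receptor_by_condition=pct_by_condition(ds, neurons_mask),
        alpha=config.fdr,
    )
    records = score_and_rank(records, k=config.top_k)
    write_table(records, os.path.join(outdir, "interactome.tsv"))
    top = top_k_pairs(records, k=config.top_k)
    write_table(top, os.path.join(outdir, "interactome_top.tsv"))
    write_table(sankey_edges(ds, top), os.path.join(outdir, "sankey_edges.tsv"))

    # --- Nageotte strata (annotation-driven; synthetic cohorts are unscored)
    strata = ds.cells["nageotte_score"].map(
        lambda s: stratify_nageotte(
            s,
            low_max=config.nageotte_strata["low_max"],
            high_min=config.nageotte_strata["high_min"],
        )
    )
    write_table(
        pd.DataFrame(
            {"barcode": ds.barcodes, "nageotte_stratum": strata.to_numpy()}
        ),
        os.path.join(outdir, "nageotte_strata.tsv"),
    )

    # --- manifest -----------------------------------------------------------
    manifest = {
        "config_sha256": config.canonical_hash(),
        "seed": config.seed,
        "drgpn_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_cells_raw": int(ds_raw.n_cells),
        "n_cells_qc": int(ds.n_cells),
    }
    with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    return outdir
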