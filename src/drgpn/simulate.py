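"""Seeded synthetic single-nucleus cohort generator with planted ground truth.

The generator emulates the statistical structure of a three-condition human
DRG cohort (Control / Diabetic / DPN organ donors): 8 major cell classes, 22
neuronal subtypes, negative-binomial counts with log-normal gene abundances
and per-cell depths, a small fraction of deliberately low-quality nuclei, and
optional planted effects (expression fold changes in selected cell groups,
cell-type proportion shifts).  Everything is drawn from a single seeded
generator in a fixed documented order, so identical configs reproduce
byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import CONDITIONS, CellDataset
from .errors import ConfigError
from .io import GeneSetCollection

MAJOR_TYPES = (
    "Neurons",
    "Satellite glia",
    "Schwann",
    "Fibroblasts",
    "Endothelial",
    "Immune",
    "Smooth muscle",
    "Adipocytes",
)

#: baseline major-class composition (neurons are a small minority of nuclei
#: in human DRG, glia and connective classes dominate)
MAJOR_BASELINE = (0.08, 0.30, 0.18, 0.18, 0.12, 0.06, 0.05, 0.03)

#: 22 neuronal subtype labels following the harmonized human DRG atlas naming
NEURON_SUBTYPES = (
    "ATF3",
    "Ab-LTMR.ETV1",
    "Ab-LTMR.NSG2",
    "Ab-LTMR.LGI2",
    "Ab-LTMR.CCKR",
    "Ad-LTMR",
    "A-LTMR.TAC3",
    "A-Propr.EPHA3",
    "A-PEP.SCGN/ADRA2C",
    "A-NOC",
    "C-LTMR",
    "C-COLD.TRPM8",
    "C-NP.SST",
    "C-NP.MRGPRX1/MRGPRX4",
    "C-NP.MRGPRX1/GFRA2",
    "C-PEP.TAC1/CACNG5",
    "C-PEP.TAC1/CHRNA3",
    "C-PEP.ADORA2B",
    "C-PEP.TRPV1/SSTR2",
    "C-PEP.NTRK3",
    "C-PEP.KIT",
    "Putative-silent",
)

#: baseline neuronal subtype composition (LTMR/proprioceptor and peptidergic
#: classes moderately abundant, injury-state ATF3 rare at baseline)
NEURON_SUBTYPE_BASELINE = (
    0.02,  # ATF3
    0.07,  # Ab-LTMR.ETV1
    0.06,  # Ab-LTMR.NSG2
    0.06,  # Ab-LTMR.LGI2
    0.05,  # Ab-LTMR.CCKR
    0.04,  # Ad-LTMR
    0.03,  # A-LTMR.TAC3
    0.05,  # A-Propr.EPHA3
    0.04,  # A-PEP.SCGN/ADRA2C
    0.05,  # A-NOC
    0.05,  # C-LTMR
    0.03,  # C-COLD.TRPM8
    0.04,  # C-NP.SST
    0.05,  # C-NP.MRGPRX1/MRGPRX4
    0.04,  # C-NP.MRGPRX1/GFRA2
    0.06,  # C-PEP.TAC1/CACNG5
    0.05,  # C-PEP.TAC1/CHRNA3
    0.05,  # C-PEP.ADORA2B
    0.05,  # C-PEP.TRPV1/SSTR2
    0.05,  # C-PEP.NTRK3
    0.04,  # C-PEP.KIT
    0.02,  # Putative-silent
)

#: human mitochondrial protein-coding gene symbols
MITO_GENES = (
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB",
)

#: canonical anti-apoptotic / inhibitor-of-apoptosis genes forming the
#: pro-survival module template (BCL2 family and IAP-related factors)
SURVIVAL_TEMPLATE = (
    "BCL2", "BCL2L1", "BCL2L2", "BCL2A1", "MCL1", "XIAP",
    "BIRC2", "BIRC3", "BIRC5", "BIRC6", "CFLAR",
)

MODULE_NAMES = ("apoptosis", "p53", "dna_repair", "upr", "survival")
MODULE_SIZE = 20


@dataclass(frozen=True)
class PlantedEffect:
    """A ground-truth perturbation planted into the cohort.

    ``expression_shift`` multiplies the negative-binomial means of
    ``target_genes`` by ``2**log2_fold_change`` in cells matching
    ``condition`` and ``cell_selector``.  ``proportion_shift`` multiplies the
    baseline probability of ``target_type`` by the same factor within
    ``condition`` (other classes renormalized).
    """

    kind: str  # "expression_shift" | "proportion_shift"
    condition: str
    log2_fold_change: float
    target_genes: Tuple[str, ...] = ()
    target_type: Optional[str] = None
    cell_selector: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("expression_shift", "proportion_shift"):
            raise ConfigError(f"unknown planted effect kind {self.kind!r}")
        if self.condition not in CONDITIONS:
            raise ConfigError(f"unknown condition {self.condition!r}")
        if self.kind == "expression_shift" and not self.target_genes:
            raise ConfigError("expression_shift requires non-empty target_genes")
        if self.kind == "proportion_shift" and not self.target_type:
            raise ConfigError("proportion_shift requires target_type")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults follow the emulated cohort: 14 Control / 10 Diabetic / 6 DPN
    donors, ~1,000 nuclei per donor, 2,000 genes.
    """

    n_donors: Tuple[int, int, int] = (14, 10, 6)  # Control, Diabetic, DPN
    cells_per_donor: int = 1000
    n_genes: int = 2000
    major_type_baseline: Tuple[float, ...] = MAJOR_BASELINE
    neuron_subtype_baseline: Tuple[float, ...] = NEURON_SUBTYPE_BASELINE
    nb_dispersion: float = 0.5
    depth_lognormal: Tuple[float, float] = (np.log(8000.0), 0.3)
    abundance_sigma: float = 1.0
    mito_fraction: float = 0.05
    low_quality_fraction: float = 0.02
    low_quality_depth_factor: float = 0.1
    low_quality_mito_fraction: float = 0.15
    planted_effects: Tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_donors):
            raise ConfigError("every condition needs at least 1 donor")
        if self.cells_per_donor < 10:
            raise ConfigError("need at least 10 cells per donor")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        for name, vec in (
            ("major_type_baseline", self.major_type_baseline),
            ("neuron_subtype_baseline", self.neuron_subtype_baseline),
        ):
            vec = np.asarray(vec, dtype=float)
            if abs(vec.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {vec.sum()})")
        if len(self.major_type_baseline) != len(MAJOR_TYPES):
            raise ConfigError("major_type_baseline needs 8 entries")
        if len(self.neuron_subtype_baseline) != len(NEURON_SUBTYPES):
            raise ConfigError("neuron_subtype_baseline needs 22 entries")


def gene_names(n_genes: int) -> List[str]:
    """Deterministic gene name layout: 13 mito genes, the 11 survival-template
    symbols, then synthetic symbols G0001, G0002, ..."""
    reserved = len(MITO_GENES) + len(SURVIVAL_TEMPLATE)
    if n_genes < reserved:
        raise ConfigError(f"n_genes must be >= {reserved}")
    synth = [f"G{i:04d}" for i in range(1, n_genes - reserved + 1)]
    return list(MITO_GENES) + list(SURVIVAL_TEMPLATE) + synth


def default_modules(n_genes: int = 2000) -> GeneSetCollection:
    """Five disjoint 20-gene modules laid out over the generated gene names.

    The pro-survival module starts from the 11-gene anti-apoptotic template
    (BCL2, BCL2L1, BCL2L2, BCL2A1, MCL1, XIAP, BIRC2, BIRC3, BIRC5, BIRC6,
    CFLAR) padded with synthetic genes; apoptosis, p53, dna_repair and upr
    are synthetic blocks.  Raises when ``n_genes`` cannot host five disjoint
    modules.
    """
    names = gene_names(n_genes)
    reserved = len(MITO_GENES) + len(SURVIVAL_TEMPLATE)
    need = reserved + (MODULE_SIZE - len(SURVIVAL_TEMPLATE)) + 4 * MODULE_SIZE
    if n_genes < need:
        raise ConfigError(
            f"n_genes={n_genes} too small for five disjoint {MODULE_SIZE}-gene "
            f"modules (need >= {need})"
        )
    coll = GeneSetCollection()
    cursor = reserved
    pad = MODULE_SIZE - len(SURVIVAL_TEMPLATE)
    coll.add("survival", list(SURVIVAL_TEMPLATE) + names[cursor : cursor + pad])
    cursor += pad
    for mod in ("apoptosis", "p53", "dna_repair", "upr"):
        coll.add(mod, names[cursor : cursor + MODULE_SIZE])
        cursor += MODULE_SIZE
    return coll


def _module_gene_mask(names: Sequence[str], n_genes: int) -> np.ndarray:
    """Boolean mask of genes belonging to any default module."""
    try:
        modules = default_modules(n_genes)
    except ConfigError:
        return np.zeros(len(names), dtype=bool)
    member = set(g for genes in modules.sets.values() for g in genes)
    return np.array([n in member for n in names])


def _shifted_probs(
    base: np.ndarray, labels: Sequence[str], effects: List[PlantedEffect]
) -> np.ndarray:
    """Apply proportion_shift effects to a baseline probability vector."""
    probs = base.copy()
    for eff in effects:
        idx = list(labels).index(eff.target_type)
        shifted = probs[idx] * 2.0**eff.log2_fold_change
        if not (0.0 < shifted < 1.0):
            raise ConfigError(
                f"proportion shift for {eff.target_type!r} leaves no valid "
                f"probability ({shifted})"
            )
        rest = 1.0 - probs[idx]
        probs = probs * (1.0 - shifted) / rest
        probs[idx] = shifted
        if (probs <= 0).any() or (probs >= 1).any():
            raise ConfigError("proportion shift drives a class out of (0,1)")
    return probs


def _matches(cells: pd.DataFrame, selector: Dict[str, object]) -> np.ndarray:
    mask = np.ones(len(cells), dtype=bool)
    for key, value in selector.items():
        col = cells[key]
        if isinstance(value, (list, tuple, set)):
            mask &= col.isin(list(value)).to_numpy()
        else:
            mask &= (col == value).to_numpy()
    return mask


def generate_cohort(config: SyntheticConfig) -> Tuple[CellDataset, pd.DataFrame]:
    """Draw a full synthetic cohort and its realized ground-truth table.

    Sampling order (fixed for reproducibility): gene abundances, per-donor
    cell labels (condition by condition, donor by donor), low-quality flags,
    depths, then counts donor-block by donor-block.

    Returns the dataset (counts only; run qc_filter / log_normalize next) and
    a truth table with one row per planted effect recording its realized
    scope (number of affected cells / realized proportions).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    names = gene_names(cfg.n_genes)

    for eff in cfg.planted_effects:
        if eff.kind == "expression_shift":
            missing = [g for g in eff.target_genes if g not in names]
            if missing:
                raise ConfigError(f"target genes not in cohort: {missing[:5]}")
        else:
            if eff.target_type not in MAJOR_TYPES + NEURON_SUBTYPES:
                raise ConfigError(f"unknown target type {eff.target_type!r}")

    # --- gene relative abundances -----------------------------------------
    abund = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=cfg.n_genes)
    mito_mask = np.array([n in MITO_GENES for n in names])
    module_mask = _module_gene_mask(names, cfg.n_genes)
    # signature genes placed on a fixed moderate abundance ladder (log-spaced,
    # interleaved across the five modules) so every module spans the same
    # expression range, planted fold changes act on well-detected genes, and
    # the module genes spread over several expression-matching bins instead of
    # stacking into one
    n_mod = int(module_mask.sum())
    if n_mod:
        ladder = np.geomspace(0.7, 5.0, n_mod)
        rungs = np.arange(n_mod).reshape(-1, len(MODULE_NAMES)).T.ravel()
        abund[module_mask] = ladder[rungs]
    abund[~mito_mask] *= (1.0 - cfg.mito_fraction) / abund[~mito_mask].sum()
    abund[mito_mask] = cfg.mito_fraction / mito_mask.sum()

    # low-quality profile: same non-mito composition, inflated mito share
    lq_abund = abund.copy()
    lq_abund[~mito_mask] *= (1.0 - cfg.low_quality_mito_fraction) / (
        1.0 - cfg.mito_fraction
    )
    lq_abund[mito_mask] = cfg.low_quality_mito_fraction / mito_mask.sum()

    # --- per-condition label probabilities --------------------------------
    prop_effects = {
        c: [
            e
            for e in cfg.planted_effects
            if e.kind == "proportion_shift" and e.condition == c
        ]
        for c in CONDITIONS
    }
    major_probs = {}
    subtype_probs = {}
    for cond in CONDITIONS:
        major_effs = [
            e for e in prop_effects[cond] if e.target_type in MAJOR_TYPES
        ]
        sub_effs = [
            e for e in prop_effects[cond] if e.target_type in NEURON_SUBTYPES
        ]
        major_probs[cond] = _shifted_probs(
            np.asarray(cfg.major_type_baseline, dtype=float), MAJOR_TYPES, major_effs
        )
        subtype_probs[cond] = _shifted_probs(
            np.asarray(cfg.neuron_subtype_baseline, dtype=float),
            NEURON_SUBTYPES,
            sub_effs,
        )

    # --- cell labels -------------------------------------------------------
    frames = []
    donor_counter = 0
    for cond, n_donors in zip(CONDITIONS, cfg.n_donors):
        for _ in range(n_donors):
            donor_counter += 1
            donor = f"D{donor_counter:03d}"
            n = cfg.cells_per_donor
            major = rng.choice(
                len(MAJOR_TYPES), size=n, p=major_probs[cond]
            )
            subtype = np.full(n, -1)
            is_neuron = major == 0
            subtype[is_neuron] = rng.choice(
                len(NEURON_SUBTYPES), size=int(is_neuron.sum()), p=subtype_probs[cond]
            )
            frames.append(
                pd.DataFrame(
                    {
                        "donor_id": donor,
                        "condition": cond,
                        "major_type": np.array(MAJOR_TYPES)[major],
                        "neuron_subtype": [
                            NEURON_SUBTYPES[s] if s >= 0 else None for s in subtype
                        ],
                    }
                )
            )
    cells = pd.concat(frames, ignore_index=True)
    cells.index = pd.Index(
        [f"CELL{i:06d}" for i in range(len(cells))], name="barcode"
    )
    cells["nageotte_score"] = np.nan
    cells["nodule_adjacent"] = pd.array([pd.NA] * len(cells), dtype="boolean")

    n_cells = len(cells)
    low_quality = rng.random(n_cells) < cfg.low_quality_fraction
    depth = rng.lognormal(
        mean=cfg.depth_lognormal[0], sigma=cfg.depth_lognormal[1], size=n_cells
    )
    depth = np.where(low_quality, depth * cfg.low_quality_depth_factor, depth)

    # --- expression effect multipliers per cell ---------------------------
    expr_effects = [
        e for e in cfg.planted_effects if e.kind == "expression_shift"
    ]
    effect_masks = []
    gene_idx_lookup = {g: i for i, g in enumerate(names)}
    for eff in expr_effects:
        mask = (cells["condition"] == eff.condition).to_numpy()
        mask &= _matches(cells, eff.cell_selector)
        effect_masks.append(
            (np.array([gene_idx_lookup[g] for g in eff.target_genes]), mask,
             2.0**eff.log2_fold_change)
        )

    # --- counts, donor-block chunks ----------------------------------------
    r = 1.0 / cfg.nb_dispersion  # gamma shape for the gamma-Poisson mixture
    blocks = []
    chunk = 2000
    for start in range(0, n_cells, chunk):
        stop = min(start + chunk, n_cells)
        idx = np.arange(start, stop)
        base = np.where(
            low_quality[idx][np.newaxis, :],
            lq_abund[:, np.newaxis],
            abund[:, np.newaxis],
        )
        mu = base * depth[idx][np.newaxis, :]
        for gene_rows, cell_mask, factor in effect_masks:
            sub = cell_mask[idx]
            if sub.any():
                mu[np.ix_(gene_rows, np.where(sub)[0])] *= factor
        counts = rng.negative_binomial(n=r, p=r / (r + mu))
        blocks.append(sp.csr_matrix(counts.astype(np.int32)))
    counts = sp.hstack(blocks, format="csr")

    genes = pd.DataFrame(
        {"is_mito": mito_mask}, index=pd.Index(names, name="gene")
    )
    ds = CellDataset(counts=counts, cells=cells, genes=genes)

    # --- truth table --------------------------------------------------------
    rows = []
    for eff in cfg.planted_effects:
        if eff.kind == "expression_shift":
            mask = (cells["condition"] == eff.condition).to_numpy()
            mask &= _matches(cells, eff.cell_selector)
            rows.append(
                {
                    "kind": eff.kind,
                    "condition": eff.condition,
                    "target": ";".join(eff.target_genes),
                    "selector": repr(eff.cell_selector),
                    "log2_fold_change": eff.log2_fold_change,
                    "n_cells_affected": int(mask.sum()),
                    "realized_value": np.nan,
                }
            )
        else:
            if eff.target_type in MAJOR_TYPES:
                realized = float(
                    (
                        cells.loc[
                            cells["condition"] == eff.condition, "major_type"
                        ]
                        == eff.target_type
                    ).mean()
                )
            else:
                neurons = cells[
                    (cells["condition"] == eff.condition)
                    & (cells["major_type"] == "Neurons")
                ]
                realized = float(
                    (neurons["neuron_subtype"] == eff.target_type).mean()
                )
            rows.append(
                {
                    "kind": eff.kind,
                    "condition": eff.condition,
                    "target": eff.target_type,
                    "selector": "",
                    "log2_fold_change": eff.log2_fold_change,
                    "n_cells_affected": np.nan,
                    "realized_value": realized,
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "kind",
            "condition",
            "target",
            "selector",
            "log2_fold_change",
            "n_cells_affected",
            "realized_value",
        ],
    )
    return ds, truth


def small_config(**overrides) -> SyntheticConfig:
    """Convenience reduced-size config for fast exploratory runs."""
    defaults = dict(n_donors=(3, 2, 2), cells_per_donor=150, n_genes=400)
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def dpn_apoptosis_effects(
    log2_fold_change: float = 1.0,
    subtypes: Tuple[str, ...] = ("Ab-LTMR.ETV1", "Ab-LTMR.NSG2", "Ab-LTMR.LGI2"),
    n_genes: int = 2000,
) -> Tuple[PlantedEffect, ...]:
    """The canonical planted effect: apoptosis-module upregulation in selected
    Ab-LTMR subtypes under DPN."""
    modules = default_modules(n_genes)
    return (
        PlantedEffect(
            kind="expression_shift",
            condition="DPN",
            log2_fold_change=log2_fold_change,
            target_genes=tuple(modules["apoptosis"]),
            cell_selector={"neuron_subtype": list(subtypes)},
        ),
    )
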