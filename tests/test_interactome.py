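"""Interactome: LR pair loading, eligibility criteria, scoring and ranking."""

import numpy as np
import pandas as pd
import pytest

from drgpn.errors import FormatError
from drgpn.interactome import (
    COMPARISONS,
    LRPair,
    filter_interactions,
    load_lr_pairs,
    receptor_population_expression,
    score_and_rank,
    top_k_pairs,
)

from conftest import make_dataset


def test_load_lr_pairs(tmp_path):
    p = tmp_path / "lr.tsv"
    p.write_text("ligand\treceptor\nngf\tNTRK1\nNGF\tntrk1\nBDNF\tNTRK2\n")
    pairs = load_lr_pairs(str(p))
    assert pairs == [LRPair("NGF", "NTRK1"), LRPair("BDNF", "NTRK2")]
    empty = tmp_path / "empty.tsv"
    empty.write_text("ligand\treceptor\n")
    assert load_lr_pairs(str(empty)) == []
    bad = tmp_path / "bad.tsv"
    bad.write_text("ligand\tother\nA\tB\n")
    with pytest.raises(FormatError, match="receptor"):
        load_lr_pairs(str(bad))


def test_receptor_population_expression():
    counts = np.zeros((2, 6), dtype=int)
    counts[0, :] = 99  # housekeeping bulk
    counts[1, 3:] = 1  # receptor: 1% of pseudobulk mass in population B
    ds = make_dataset(
        counts,
        gene_names=["bulk", "REC"],
        major_type=["Neurons"] * 6,
        neuron_subtype=["A"] * 3 + ["B"] * 3,
    )
    expr = receptor_population_expression(ds)
    assert expr.loc["A", "REC"] == 0.0  # absent -> fails the 0.01 criterion
    assert expr.loc["B", "REC"] == pytest.approx(np.log1p(100), rel=1e-6)
    # duplicating every cell of a population leaves values unchanged
    dup = make_dataset(
        np.hstack([counts, counts[:, 3:]]),
        gene_names=["bulk", "REC"],
        major_type=["Neurons"] * 9,
        neuron_subtype=["A"] * 3 + ["B"] * 6,
    )
    expr2 = receptor_population_expression(dup)
    assert expr2.loc["B", "REC"] == pytest.approx(expr.loc["B", "REC"])


def _de_tables(lig_stats, rec_stats):
    """Build the three-comparison DE-table mappings from per-comparison
    (log2FC, p_adj) tuples for the single ligand/receptor gene pair."""
    de_l, de_r = {}, {}
    for comp in COMPARISONS:
        lfc, padj = lig_stats.get(comp, (0.0, 1.0))
        de_l[comp] = pd.DataFrame(
            {"gene": ["LIG"], "log2FC": [lfc], "p_adj": [padj]}
        )
        lfc, padj = rec_stats.get(comp, (0.0, 1.0))
        de_r[comp] = pd.DataFrame(
            {"gene": ["REC"], "log2FC": [lfc], "p_adj": [padj]}
        )
    return de_l, de_r


def _inputs(
    lig_stats=None,
    rec_stats=None,
    pop=0.5,
    rec_pct=0.10,
    lig_pct=0.01,
):
    de_l, de_r = _de_tables(lig_stats or {}, rec_stats or {})
    pop_expr = pd.DataFrame({"LIG": [0.0], "REC": [pop]}, index=["popA"])
    pct_l = pd.DataFrame({"Control": [lig_pct]}, index=["LIG"])
    pct_r = pd.DataFrame({"Control": [rec_pct]}, index=["REC"])
    return dict(
        pairs=[LRPair("LIG", "REC")],
        de_nonneuronal=de_l,
        de_neuronal=de_r,
        pop_expr=pop_expr,
        pct_ligand_by_condition=pct_l,
        pct_receptor_by_condition=pct_r,
    )


SIG_UP = {"diabetic_vs_dpn": (1.0, 0.01)}


def test_eligible_record():
    rec = filter_interactions(**_inputs(lig_stats=SIG_UP))
    row = rec[rec["comparison"] == "diabetic_vs_dpn"].iloc[0]
    assert row["eligible"]
    # the same pair in a comparison without DE fails C1 only
    other = rec[rec["comparison"] == "control_vs_dpn"].iloc[0]
    assert not other["c1_de"]
    assert other[["c2_not_opposite", "c3a_pop_expr", "c3b_receptor_pct",
                  "c3c_ligand_pct"]].all()


def test_opposite_direction_rule_excludes():
    rec = filter_interactions(
        **_inputs(
            lig_stats={"diabetic_vs_dpn": (1.0, 0.01)},
            rec_stats={"diabetic_vs_dpn": (-1.0, 0.01)},
        )
    )
    row = rec[rec["comparison"] == "diabetic_vs_dpn"].iloc[0]
    assert row["c1_de"]
    assert not row["c2_not_opposite"]
    assert not row["eligible"]


@pytest.mark.parametrize(
    "kwargs, flag",
    [
        (dict(lig_stats=SIG_UP, rec_pct=0.04), "c3b_receptor_pct"),
        (dict(lig_stats=SIG_UP, lig_pct=0.0009), "c3c_ligand_pct"),
        (dict(lig_stats=SIG_UP, pop=0.009), "c3a_pop_expr"),
    ],
)
def test_expression_criteria_exclude_individually(kwargs, flag):
    rec = filter_interactions(**_inputs(**kwargs))
    row = rec[rec["comparison"] == "diabetic_vs_dpn"].iloc[0]
    assert not row[flag]
    assert not row["eligible"]
    others = [
        f
        for f in ("c1_de", "c2_not_opposite", "c3a_pop_expr",
                  "c3b_receptor_pct", "c3c_ligand_pct")
        if f != flag
    ]
    assert row[others].all()  # exactly one criterion flipped


def test_gene_absent_from_de_treated_as_not_de():
    inputs = _inputs(lig_stats=SIG_UP)
    inputs["pairs"] = [LRPair("LIG", "UNKNOWN_REC")]
    inputs["pop_expr"]["UNKNOWN_REC"] = 0.5
    inputs["pct_receptor_by_condition"].loc["UNKNOWN_REC"] = 0.5
    rec = filter_interactions(**inputs)
    row = rec[rec["comparison"] == "diabetic_vs_dpn"].iloc[0]
    assert not row["receptor_in_de"]
    assert row["receptor_p_adj"] == 1.0
    assert row["eligible"]  # C1 satisfied by the ligand


def test_score_and_rank():
    inputs = _inputs(lig_stats=SIG_UP)
    records = filter_interactions(**inputs)
    ranked = score_and_rank(records, k=10)
    elig = ranked[ranked["eligible"]]
    assert (elig["rank"] == 1).all()  # single eligible pair
    # score monotone in |log2FC|: double the ligand fold change
    inputs2 = _inputs(lig_stats={"diabetic_vs_dpn": (2.0, 0.01)})
    stronger = score_and_rank(filter_interactions(**inputs2), k=10)
    assert (
        stronger[stronger["eligible"]]["score"].max()
        > elig["score"].max()
    )


def test_top_k_unique_pairs_and_tie_break():
    rows = []
    for name, lfc in (("AAA", 1.0), ("BBB", 1.0), ("CCC", 2.0)):
        for comp in ("diabetic_vs_dpn", "control_vs_dpn"):
            rows.append(
                {
                    "ligand": name, "receptor": "R", "source": "",
                    "comparison": comp,
                    "ligand_log2FC": lfc, "ligand_p_adj": 0.01, "ligand_pct": 0.5,
                    "receptor_log2FC": 0.0, "receptor_p_adj": 1.0,
                    "receptor_pct": 0.5, "receptor_max_pop_lognorm": 1.0,
                    "c1_de": True, "c2_not_opposite": True, "c3a_pop_expr": True,
                    "c3b_receptor_pct": True, "c3c_ligand_pct": True,
                    "eligible": True,
                }
            )
    ranked = score_and_rank(pd.DataFrame(rows), k=2)
    top = top_k_pairs(ranked, k=2)
    assert len(top) == 2
    assert not top.duplicated(["ligand", "receptor"]).any()
    assert top.iloc[0]["ligand"] == "CCC"  # highest score first
    assert top.iloc[1]["ligand"] == "AAA"  # tie broken lexicographically


def test_no_eligible_records_raises():
    records = filter_interactions(**_inputs())  # no DE anywhere -> C1 fails
    assert not records["eligible"].any()
    with pytest.raises(ValueError, match="eligible"):
        score_and_rank(records)
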