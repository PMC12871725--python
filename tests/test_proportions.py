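"""Proportion permutation test, bootstrap CI, classification, nodule arithmetic."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from drgpn.proportions import (
    bootstrap_ci,
    classify_shift,
    nodule_adjacency_fold_change,
    permutation_test,
    proportion_estimates,
    proportion_test,
)


def label_table(types_a, types_b, cond_a="Control", cond_b="Diabetic"):
    return pd.DataFrame(
        {
            "condition": [cond_a] * len(types_a) + [cond_b] * len(types_b),
            "major_type": list(types_a) + list(types_b),
        }
    )


def exhaustive_permutation_p(types_a, types_b):
    """Exact permutation distribution by complete enumeration of which cells
    receive the b label (totals fixed); per-type two-sided p on |log2FD|."""
    pooled = np.array(list(types_a) + list(types_b))
    n, n_b = len(pooled), len(types_b)
    labels = sorted(set(pooled))
    eps = 1.0 / (2.0 * min(n - n_b, n_b))

    def fd(b_mask):
        fds = []
        for t in labels:
            pa = (pooled[~b_mask] == t).mean()
            pb = (pooled[b_mask] == t).mean()
            fds.append(np.log2((pb + eps) / (pa + eps)))
        return np.array(fds)

    obs_mask = np.zeros(n, dtype=bool)
    obs_mask[len(types_a):] = True
    obs = fd(obs_mask)
    exceed = np.zeros(len(labels))
    count = 0
    for combo in combinations(range(n), n_b):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        exceed += np.abs(fd(mask)) >= np.abs(obs) - 1e-12
        count += 1
    return labels, obs, exceed / count


def test_proportion_estimates_examples():
    a = ["X"] * 30 + ["Y"] * 70
    b = ["X"] * 60 + ["Y"] * 40
    est = proportion_estimates(label_table(a, b), "Control", "Diabetic", "major_type")
    row = est[est["cell_type"] == "X"].iloc[0]
    assert row["prop_a"] == pytest.approx(0.3)
    assert row["prop_b"] == pytest.approx(0.6)
    assert row["obs_log2FD"] == pytest.approx(1.0, abs=0.02)
    # equal proportions give exactly zero
    est2 = proportion_estimates(label_table(a, a), "Control", "Diabetic", "major_type")
    assert (est2["obs_log2FD"] == 0).all()


def test_absent_type_stays_finite():
    a = ["X"] * 50
    b = ["X"] * 40 + ["Z"] * 10
    est = proportion_estimates(label_table(a, b), "Control", "Diabetic", "major_type")
    z = est[est["cell_type"] == "Z"].iloc[0]
    assert np.isfinite(z["obs_log2FD"])
    assert z["obs_log2FD"] > 0


def test_unknown_cluster_field_raises():
    with pytest.raises(ValueError, match="cluster field"):
        proportion_estimates(label_table(["X"], ["X"]), "Control", "Diabetic", "nope")


def test_permutation_matches_exhaustive_enumeration():
    """12-cell instances: Monte Carlo p within 0.02 of complete enumeration."""
    instances = [
        (["X"] * 5 + ["Y"], ["X"] + ["Y"] * 5),
        (["X"] * 3 + ["Y"] * 3, ["X"] * 2 + ["Y"] * 4),
        (["X", "Y", "Z"] * 2, ["X"] * 4 + ["Z"] * 2),
        (["X"] * 6, ["X"] * 4 + ["Y"] * 2),
    ]
    for types_a, types_b in instances:
        labels, obs, exact = exhaustive_permutation_p(types_a, types_b)
        res = permutation_test(
            label_table(types_a, types_b), "Control", "Diabetic", "major_type",
            n_perm=4000, seed=3,
        )
        for t, o, e in zip(labels, obs, exact):
            row = res[res["cell_type"] == t].iloc[0]
            assert row["obs_log2FD"] == pytest.approx(o, abs=1e-12)
            assert row["p_perm"] == pytest.approx(e, abs=0.02)


def test_self_comparison_is_null():
    types = ["X"] * 30 + ["Y"] * 20
    cells = label_table(types, types)
    res = permutation_test(cells, "Control", "Diabetic", "major_type", n_perm=500, seed=0)
    assert (res["p_perm"] == 1.0).all()  # obs log2FD is exactly 0


def test_p_perm_never_zero_and_swap_negates_obs():
    rng = np.random.default_rng(0)
    a = [f"T{t}" for t in rng.integers(0, 4, 80)]
    b = [f"T{t}" for t in rng.integers(0, 4, 120)]
    cells = label_table(a, b)
    fwd = permutation_test(cells, "Control", "Diabetic", "major_type", n_perm=200, seed=1)
    rev = permutation_test(cells, "Diabetic", "Control", "major_type", n_perm=200, seed=1)
    assert (fwd["p_perm"] > 0).all()
    np.testing.assert_allclose(
        fwd["obs_log2FD"].to_numpy(), -rev["obs_log2FD"].to_numpy(), atol=1e-12
    )


def test_bootstrap_degenerate_single_type():
    cells = label_table(["X"] * 20, ["X"] * 30)
    ci = bootstrap_ci(cells, "Control", "Diabetic", "major_type", n_boot=50, seed=0)
    assert ci.loc[0, "ci_low"] == 0.0
    assert ci.loc[0, "ci_high"] == 0.0


def test_bootstrap_width_shrinks_with_n():
    rng = np.random.default_rng(5)

    def width(n):
        a = [f"T{t}" for t in rng.choice(3, n, p=[0.5, 0.3, 0.2])]
        b = [f"T{t}" for t in rng.choice(3, n, p=[0.5, 0.3, 0.2])]
        ci = bootstrap_ci(
            label_table(a, b), "Control", "Diabetic", "major_type",
            n_boot=400, seed=1,
        )
        return (ci["ci_high"] - ci["ci_low"]).mean()

    w1 = np.mean([width(500) for _ in range(3)])
    w4 = np.mean([width(2000) for _ in range(3)])
    assert 0.4 <= w4 / w1 <= 0.6


def test_bootstrap_covers_planted_shift():
    rng = np.random.default_rng(8)
    hits = 0
    for trial in range(10):
        a = ["X"] * 100 + ["Y"] * 900
        nb_x = rng.binomial(1000, 0.2)
        b = ["X"] * nb_x + ["Y"] * (1000 - nb_x)
        ci = bootstrap_ci(
            label_table(a, b), "Control", "Diabetic", "major_type",
            n_boot=300, seed=trial,
        )
        x = ci[ci["cell_type"] == "X"].iloc[0]
        hits += bool(x["ci_low"] > 0)
    assert hits >= 9


def test_classify_shift_thresholds():
    base = pd.DataFrame(
        {
            "cell_type": ["a", "b", "c"],
            "obs_log2FD": [0.3, 2.0, 0.5],
            "p_perm": [0.001, 0.2, 0.001],
        }
    )
    strict = classify_shift(base, fdr=0.05, lfc_threshold=0.585)
    assert not strict.loc[0, "significant"]  # fails magnitude
    assert not strict.loc[1, "significant"]  # fails FDR
    assert not strict.loc[2, "significant"]  # 0.5 < 0.585
    lax = classify_shift(base, fdr=0.05, lfc_threshold=0.42)
    assert lax.loc[2, "significant"]  # the laxer magnitude rule admits 0.5


def test_nodule_fold_changes():
    rng = np.random.default_rng(2)
    def draw(n, p):
        return [f"N{t}" for t in rng.choice(2, n, p=p)]
    neurons = pd.DataFrame(
        {
            "group": ["control"] * 200 + ["dpn_adjacent"] * 200
            + ["dpn_nonadjacent"] * 200,
            "neuron_type": draw(200, [0.1, 0.9])
            + draw(200, [0.3, 0.7])
            + draw(200, [0.1, 0.9]),
        }
    )
    fc = nodule_adjacency_fold_change(neurons)
    n0 = fc[fc["neuron_type"] == "N0"].iloc[0]
    assert 2.0 <= n0["fc_adjacent"] <= 4.0
    assert 0.6 <= n0["fc_nonadjacent"] <= 1.5

    # identical composition in all groups -> fold changes exactly 1
    same = pd.DataFrame(
        {
            "group": ["control"] * 4 + ["dpn_adjacent"] * 4 + ["dpn_nonadjacent"] * 4,
            "neuron_type": ["A", "A", "B", "B"] * 3,
        }
    )
    fc2 = nodule_adjacency_fold_change(same)
    np.testing.assert_allclose(fc2["fc_adjacent"], 1.0)
    np.testing.assert_allclose(fc2["fc_nonadjacent"], 1.0)

    with pytest.raises(ValueError, match="no neurons"):
        nodule_adjacency_fold_change(same[same["group"] != "control"])


def test_full_proportion_test_table_invariants():
    rng = np.random.default_rng(4)
    a = [f"T{t}" for t in rng.choice(4, 400, p=[0.4, 0.3, 0.2, 0.1])]
    b = [f"T{t}" for t in rng.choice(4, 400, p=[0.1, 0.3, 0.2, 0.4])]
    res = proportion_test(
        label_table(a, b), "Control", "Diabetic", "major_type",
        n_perm=300, n_boot=300, seed=0,
    )
    assert (res["ci_low"] <= res["obs_log2FD"] + 1e-9).all()
    assert (res["obs_log2FD"] <= res["ci_high"] + 1e-9).all()
    assert res["p_adj"].between(0, 1).all()
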