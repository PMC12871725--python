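"""Permutation-based cell-type proportion comparison between two conditions,
with percentile-bootstrap confidence intervals and BH adjustment, plus the
nodule-adjacency fold-change arithmetic.

The statistic is the log2 fold difference of per-type proportions,
``log2((prop_b + eps) / (prop_a + eps))`` with the Haldane-style guard
``eps = 1 / (2 * min(condition totals))``.  Cells are the permutation unit
(condition labels shuffled holding totals fixed); p-values use the add-one
estimator ``(1 + #{|perm| >= |obs|}) / (1 + n_perm)``.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .stats import benjamini_hochberg

log = logging.getLogger(__name__)


def _prepare(
    cells: pd.DataFrame, cond_a: str, cond_b: str, cluster_field: str
) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Type codes, boolean b-membership, and the type labels, for the cells of
    the two conditions (cells with a null cluster value dropped)."""
    if cluster_field not in cells.columns:
        raise ValueError(f"cluster field {cluster_field!r} not in cell table")
    sub = cells[cells["condition"].isin([cond_a, cond_b])]
    sub = sub.dropna(subset=[cluster_field])
    if (sub["condition"] == cond_a).sum() == 0 or (
        sub["condition"] == cond_b
    ).sum() == 0:
        raise ValueError("both conditions must have at least one cell")
    types = sorted(sub[cluster_field].astype(str).unique())
    codes = pd.Categorical(
        sub[cluster_field].astype(str), categories=types
    ).codes.astype(np.int64)
    in_b = (sub["condition"] == cond_b).to_numpy()
    return codes, in_b, types


def _log2fd(
    codes: np.ndarray, in_b: np.ndarray, n_types: int, eps: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    counts_b = np.bincount(codes[in_b], minlength=n_types)
    counts_a = np.bincount(codes[~in_b], minlength=n_types)
    prop_a = counts_a / counts_a.sum()
    prop_b = counts_b / counts_b.sum()
    return prop_a, prop_b, np.log2((prop_b + eps) / (prop_a + eps))


def proportion_estimates(
    cells: pd.DataFrame, cond_a: str, cond_b: str, cluster_field: str
) -> pd.DataFrame:
    """Per-type proportions in each condition and the observed log2 fold
    difference (b vs a)."""
    codes, in_b, types = _prepare(cells, cond_a, cond_b, cluster_field)
    eps = 1.0 / (2.0 * min(int((~in_b).sum()), int(in_b.sum())))
    prop_a, prop_b, fd = _log2fd(codes, in_b, len(types), eps)
    return pd.DataFrame(
        {
            "cell_type": types,
            "prop_a": prop_a,
            "prop_b": prop_b,
            "obs_log2FD": fd,
        }
    )


def permutation_test(
    cells: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    cluster_field: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-sided permutation p-value per type for |log2FD|.

    Condition labels are shuffled over cells holding the condition totals
    fixed; the add-one estimator keeps p strictly positive.
    """
    if n_perm < 100:
        log.warning("n_perm=%d gives poor p-value resolution", n_perm)
    codes, in_b, types = _prepare(cells, cond_a, cond_b, cluster_field)
    n_types = len(types)
    n_b = int(in_b.sum())
    eps = 1.0 / (2.0 * min(len(codes) - n_b, n_b))
    _, _, obs = _log2fd(codes, in_b, n_types, eps)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_types, dtype=np.int64)
    perm_b = np.zeros(len(codes), dtype=bool)
    for _ in range(n_perm):
        perm = rng.permutation(len(codes))
        perm_b[:] = False
        perm_b[perm[:n_b]] = True
        _, _, fd = _log2fd(codes, perm_b, n_types, eps)
        exceed += np.abs(fd) >= np.abs(obs) - 1e-12
    p = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame({"cell_type": types, "obs_log2FD": obs, "p_perm": p})


def bootstrap_ci(
    cells: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    cluster_field: str,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile bootstrap interval for the per-type log2FD: cells resampled
    with replacement within each condition."""
    codes, in_b, types = _prepare(cells, cond_a, cond_b, cluster_field)
    n_types = len(types)
    codes_a, codes_b = codes[~in_b], codes[in_b]
    eps = 1.0 / (2.0 * min(codes_a.size, codes_b.size))
    rng = np.random.default_rng(seed)
    fds = np.empty((n_boot, n_types))
    for i in range(n_boot):
        ra = codes_a[rng.integers(0, codes_a.size, codes_a.size)]
        rb = codes_b[rng.integers(0, codes_b.size, codes_b.size)]
        prop_a = np.bincount(ra, minlength=n_types) / ra.size
        prop_b = np.bincount(rb, minlength=n_types) / rb.size
        fds[i] = np.log2((prop_b + eps) / (prop_a + eps))
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(fds, alpha, axis=0)
    hi = np.quantile(fds, 1.0 - alpha, axis=0)
    return pd.DataFrame({"cell_type": types, "ci_low": lo, "ci_high": hi})


def proportion_test(
    cells: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    cluster_field: str,
    n_perm: int = 1000,
    n_boot: int = 1000,
    level: float = 0.95,
    fdr: float = 0.05,
    lfc_threshold: float = 0.585,
    seed: int = 0,
) -> pd.DataFrame:
    """Full proportion comparison: estimates, permutation p, bootstrap CI,
    BH adjustment and significance classification in one table."""
    est = proportion_estimates(cells, cond_a, cond_b, cluster_field)
    perm = permutation_test(
        cells, cond_a, cond_b, cluster_field, n_perm=n_perm, seed=seed
    )
    ci = bootstrap_ci(
        cells, cond_a, cond_b, cluster_field, n_boot=n_boot, level=level,
        seed=seed + 1,
    )
    out = est.merge(perm[["cell_type", "p_perm"]], on="cell_type").merge(
        ci, on="cell_type"
    )
    return classify_shift(out, fdr=fdr, lfc_threshold=lfc_threshold)


def classify_shift(
    results: pd.DataFrame, fdr: float = 0.05, lfc_threshold: float = 0.585
) -> pd.DataFrame:
    """BH-adjust the permutation p-values of one run and flag significance:
    ``p_adj < fdr`` AND ``|obs_log2FD| > lfc_threshold``."""
    if len(results) == 0:
        raise ValueError("empty result table")
    out = results.copy()
    out["p_adj"] = benjamini_hochberg(out["p_perm"].to_numpy())
    out["significant"] = (out["p_adj"] < fdr) & (
        out["obs_log2FD"].abs() > lfc_threshold
    )
    return out


NODULE_GROUPS = ("control", "dpn_adjacent", "dpn_nonadjacent")


def nodule_adjacency_fold_change(
    neurons: pd.DataFrame,
    group_field: str = "group",
    type_field: str = "neuron_type",
    sample_field: Optional[str] = "sample_id",
) -> pd.DataFrame:
    """Per-type composition fold changes of nodule-adjacent and non-adjacent
    DPN neurons relative to control neurons.

    Per group the proportion of each neuron type is the mean of within-sample
    proportions when a sample column exists, else the pooled proportion.  Fold
    changes use the same Haldane-style eps guard as the proportion tests.
    Types absent from every group are dropped with a warning.
    """
    for g in NODULE_GROUPS:
        if (neurons[group_field] == g).sum() == 0:
            raise ValueError(f"group {g!r} has no neurons")
    types = sorted(neurons[type_field].dropna().astype(str).unique())
    use_samples = sample_field is not None and sample_field in neurons.columns

    props = {}
    for g in NODULE_GROUPS:
        sub = neurons[neurons[group_field] == g]
        if use_samples:
            per_sample = (
                sub.groupby(sample_field, observed=True)[type_field]
                .value_counts(normalize=True)
                .unstack(fill_value=0.0)
                .reindex(columns=types, fill_value=0.0)
            )
            props[g] = per_sample.mean(axis=0).to_numpy()
        else:
            vc = sub[type_field].value_counts(normalize=True)
            props[g] = vc.reindex(types, fill_value=0.0).to_numpy()

    present = np.zeros(len(types), dtype=bool)
    for g in NODULE_GROUPS:
        present |= props[g] > 0
    if (~present).any():
        dropped = [t for t, keep in zip(types, present) if not keep]
        log.warning("neuron types absent everywhere dropped: %s", dropped)

    totals = [int((neurons[group_field] == g).sum()) for g in NODULE_GROUPS]
    eps = 1.0 / (2.0 * min(totals))
    ctrl = props["control"]
    out = pd.DataFrame(
        {
            "neuron_type": np.array(types)[present],
            "prop_control": ctrl[present],
            "prop_adjacent": props["dpn_adjacent"][present],
            "prop_nonadjacent": props["dpn_nonadjacent"][present],
            "fc_adjacent": (props["dpn_adjacent"][present] + eps)
            / (ctrl[present] + eps),
            "fc_nonadjacent": (props["dpn_nonadjacent"][present] + eps)
            / (ctrl[present] + eps),
        }
    )
    return out
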