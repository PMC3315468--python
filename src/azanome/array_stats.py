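"""Genome-scale statistics: beta-value demethylation calls, SAM-style
permutation testing, and the demethylation-linked reactivation comparison.

The differential-expression statistic follows Significance Analysis of
Microarrays (SAM, Tusher et al.): a per-transcript moderated score

    d_i = (mean_2 - mean_1) / (s_i + s0)

where ``s_i`` is the pooled two-sample standard error and the
exchangeability offset ``s0`` is chosen among quantiles of the ``s_i`` to
minimise the coefficient of variation of the score's spread across windows
of ``s_i`` — damping the inflated scores of low-variance transcripts.  The
null distribution comes from group-label permutations (all distinct
assignments when there are no more than ``n_perm`` of them, otherwise
``n_perm`` random draws).  The false-discovery rate at a symmetric cut
``|d| >= t`` is estimated as the median permuted exceedance count, scaled by
an estimate of the true-null proportion ``pi0``, divided by the observed
count; per-transcript q-values are the minimum FDR over all cuts that
include the transcript, enforced monotone in ``|d|``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import wilcoxon


def classify_beta(beta: float) -> str:
    """hypo (<0.2) / hyper (>0.8) / intermediate, per the bimodal split."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta={beta} outside [0, 1]")
    if beta < 0.2:
        return "hypo"
    if beta > 0.8:
        return "hyper"
    return "intermediate"


@dataclass
class DemethylationCall:
    probes: list[str]
    genes: list[str]
    n_missing: int


def call_demethylated(
    beta_control: pd.Series,
    beta_treated: pd.Series,
    gene_map: pd.Series | None = None,
    hyper_threshold: float = 0.8,
    delta: float = 0.25,
) -> DemethylationCall:
    """Probes hypermethylated in control (beta > ``hyper_threshold``) that
    lose at least ``delta`` beta under treatment; genes collapse by "any
    probe selected".  Probes missing in either sample are excluded and
    counted."""
    shared = beta_control.index.intersection(beta_treated.index)
    if len(shared) == 0:
        raise ValueError("no shared probes between the two samples")
    c = beta_control.loc[shared]
    t = beta_treated.loc[shared]
    ok = c.notna() & t.notna()
    n_missing = int((~ok).sum())
    c, t = c[ok], t[ok]
    sel = (c > hyper_threshold) & ((c - t) >= delta)
    probes = list(c.index[sel])
    if gene_map is not None:
        genes = sorted(set(gene_map.reindex(probes).dropna()))
    else:
        genes = []
    return DemethylationCall(probes, genes, n_missing)


@dataclass
class SamResult:
    scores: pd.Series  # d per transcript
    q_values: pd.Series
    significant: list[str]  # transcript ids with q <= cutoff
    s0: float
    pi0: float
    n_permutations: int
    q_cutoff: float
    seed: int | None


def _pooled_se(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    n1, n2 = x1.shape[1], x2.shape[1]
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    a = (1.0 / n1 + 1.0 / n2) / (n1 + n2 - 2)
    return np.sqrt(a * ss)


def _choose_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Tusher et al. fudge factor: the s-quantile minimising the coefficient
    of variation of the windowed MAD of d across the range of s."""
    alphas = np.arange(0.0, 1.0001, 0.05)
    candidates = np.quantile(s, alphas)
    # ~100 windows of s (fewer when there are few transcripts)
    n_bins = min(100, max(2, len(s) // 20))
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, n_bins)
    best, best_cv = candidates[0], np.inf
    for cand in candidates:
        d = r / (s + cand)
        v = np.array(
            [1.4826 * np.median(np.abs(d[b] - np.median(d[b]))) for b in bins]
        )
        mean_v = v.mean()
        if mean_v == 0:
            continue
        cv = v.std() / mean_v
        if cv < best_cv:
            best_cv, best = cv, float(cand)
    return best


def _label_assignments(
    n: int, n1: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Group-1 index sets: all distinct assignments if few enough, else
    ``n_perm`` random draws (the observed labelling is always included)."""
    from math import comb

    if comb(n, n1) <= n_perm:
        return np.array(list(combinations(range(n), n1)), dtype=int)
    picks = [tuple(range(n1))]
    for _ in range(n_perm - 1):
        picks.append(tuple(np.sort(rng.choice(n, size=n1, replace=False))))
    return np.array(picks, dtype=int)


def sam_two_class(
    expr: pd.DataFrame,
    labels: Sequence[str],
    n_perm: int = 1000,
    q_cutoff: float = 0.05,
    seed: int | None = None,
    s0: float | None = None,
    group_order: tuple[str, str] | None = None,
) -> SamResult:
    """Two-class unpaired SAM on a transcripts x samples matrix.

    ``labels`` assigns each column to one of two groups; scores are oriented
    as group2 minus group1, with groups taken in ``group_order``
    (reference first) or sorted label order when not given.
    """
    labels = np.asarray(labels)
    names = list(group_order) if group_order else sorted(set(labels))
    if len(names) != 2 or set(names) != set(labels):
        raise ValueError(f"group names {names} do not match labels")
    g1 = np.where(labels == names[0])[0]
    g2 = np.where(labels == names[1])[0]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 samples per group")
    x = expr.to_numpy(dtype=float)
    n1 = len(g1)
    cols = np.concatenate([g1, g2])
    x = x[:, cols]  # group1 first, group2 last
    n = x.shape[1]

    rng = np.random.default_rng(seed)
    assignments = _label_assignments(n, n1, n_perm, rng)
    if len(assignments) < 2:
        raise ValueError("fewer than 2 distinct label permutations")

    def score(idx1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mask = np.zeros(n, dtype=bool)
        mask[idx1] = True
        x1, x2 = x[:, mask], x[:, ~mask]
        r = x2.mean(axis=1) - x1.mean(axis=1)
        return r, _pooled_se(x1, x2)

    r_obs, s_obs = score(np.arange(n1))
    if s0 is None:
        s0 = _choose_s0(r_obs, s_obs)
    d_obs = r_obs / (s_obs + s0)

    perm_d = np.empty((len(assignments), len(d_obs)))
    for k, idx1 in enumerate(assignments):
        r, s = score(np.asarray(idx1))
        perm_d[k] = r / (s + s0)

    # pi0: fraction of permuted-score interquartile mass among observed d
    q25, q75 = np.quantile(perm_d, [0.25, 0.75])
    pi0 = min(1.0, ((d_obs >= q25) & (d_obs <= q75)).sum() / (0.5 * len(d_obs)))

    abs_obs = np.abs(d_obs)
    abs_perm = np.abs(perm_d)
    order = np.argsort(abs_obs, kind="stable")  # ascending |d|
    thresholds = abs_obs[order]
    # observed exceedances R(t) and median permuted exceedances V(t)
    m = len(d_obs)
    R = m - np.arange(m)  # count of |d_obs| >= each ascending threshold
    # counts per permutation via searchsorted on each sorted permutation row
    perm_sorted = np.sort(abs_perm, axis=1)
    counts = np.empty((abs_perm.shape[0], m))
    for k in range(abs_perm.shape[0]):
        counts[k] = abs_perm.shape[1] - np.searchsorted(
            perm_sorted[k], thresholds, side="left"
        )
    V = np.median(counts, axis=0)
    raw = np.clip(pi0 * V / R, 0.0, 1.0)
    q_asc = np.minimum.accumulate(raw)  # monotone in |d|
    q = np.empty(m)
    q[order] = q_asc

    scores = pd.Series(d_obs, index=expr.index, name="d")
    q_values = pd.Series(q, index=expr.index, name="q")
    significant = list(expr.index[q <= q_cutoff])
    return SamResult(
        scores, q_values, significant, float(s0), float(pi0),
        len(assignments), q_cutoff, seed,
    )


def overlap_fraction(
    set_a: set[str],
    set_b: set[str],
    denominator: Literal["A", "B", "smaller"] = "A",
) -> dict:
    """|A ∩ B| over the chosen denominator set; convention recorded in the
    output."""
    denom = {
        "A": set_a,
        "B": set_b,
        "smaller": set_a if len(set_a) <= len(set_b) else set_b,
    }[denominator]
    if not denom:
        raise ValueError("empty denominator set")
    return {
        "fraction": len(set_a & set_b) / len(denom),
        "n_intersection": len(set_a & set_b),
        "n_denominator": len(denom),
        "denominator": denominator,
    }


@dataclass
class ReactivationComparison:
    statistic: float
    p_value: float
    median_difference: float
    n_genes: int
    degenerate: bool
    summary: pd.DataFrame  # quartiles for both fold-change vectors
    table: pd.DataFrame  # per-gene fold changes and differences


def reactivation_comparison(
    fc_nc: pd.Series, fc_kd: pd.Series
) -> ReactivationComparison:
    """Paired comparison of per-gene log2 reactivation fold changes between
    control-siRNA and remodeler-knockdown conditions.

    Two-sided Wilcoxon signed-rank test on the paired differences
    (NC minus KD), with the median difference and box-plot quartiles for
    both vectors.
    """
    shared = fc_nc.index.intersection(fc_kd.index)
    if len(shared) < 5:
        raise ValueError("need >= 5 matched genes")
    a = fc_nc.loc[shared].astype(float)
    b = fc_kd.loc[shared].astype(float)
    diff = a - b
    degenerate = bool((diff == 0).all())
    if degenerate:
        stat, p = float("nan"), 1.0
    else:
        stat, p = wilcoxon(a, b, alternative="two-sided")
    qs = [0.0, 0.25, 0.5, 0.75, 1.0]
    summary = pd.DataFrame(
        {
            "NC": np.quantile(a, qs),
            "KD": np.quantile(b, qs),
        },
        index=pd.Index(["min", "q1", "median", "q3", "max"], name="quartile"),
    )
    table = pd.DataFrame({"fc_nc": a, "fc_kd": b, "difference": diff})
    return ReactivationComparison(
        float(stat), float(p), float(diff.median()), len(shared), degenerate,
        summary, table,
    )


def cluster_rows(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "average",
) -> tuple[list, np.ndarray]:
    """One-dimensional hierarchical clustering of rows (columns fixed).

    Missing values are imputed by the row mean for distance computation
    only; an all-missing row is rejected.  Returns (row ids in leaf order,
    linkage matrix).  Two rows cluster trivially in input order.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    values = matrix.to_numpy(dtype=float)
    all_missing = np.isnan(values).all(axis=1)
    if all_missing.any():
        bad = matrix.index[all_missing][0]
        raise ValueError(f"row {bad!r} is entirely missing")
    row_means = np.nanmean(values, axis=1, keepdims=True)
    filled = np.where(np.isnan(values), row_means, values)
    if matrix.shape[0] == 2:
        return list(matrix.index), linkage(filled, method=method, metric=metric)
    Z = linkage(filled, method=method, metric=metric)
    order = leaves_list(Z)
    return [matrix.index[i] for i in order], Z


__all__ = [
    "classify_beta",
    "DemethylationCall",
    "call_demethylated",
    "SamResult",
    "sam_two_class",
    "overlap_fraction",
    "ReactivationComparison",
    "reactivation_comparison",
    "cluster_rows",
]
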