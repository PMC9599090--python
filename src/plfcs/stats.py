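"""Region-wise group comparisons and cross-modal / clinical correlations.

Node selection compares the normal-control group against the pooled
cognitive-impairment (CI = MCI + AD) group region by region, either with a
two-sample t-test or a label-permutation test on the absolute difference of
group means. Selection is at uncorrected p < alpha (the convention of the
literature this implements); Benjamini-Hochberg q-values are reported
alongside as a clearly-labelled extension, not used for selection.

Degenerate cases (zero variance) never produce a silent NaN: results carry
an explicit ``degenerate`` flag, and a t-test on identical group means with
zero pooled variance reports t = 0, p = 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .connectivity import StrengthVector
from .proportional_loss import PLFCSVector

__all__ = [
    "GroupComparison",
    "region_ttest",
    "region_permutation_test",
    "crossmodal_correlation",
    "hub_vulnerability",
    "clinical_correlation",
    "global_group_comparison",
    "stack_vectors",
]


def stack_vectors(vectors: Sequence) -> pd.DataFrame:
    """Stack per-subject vectors (PLFCS, SUVR, strength) into a
    subjects x regions DataFrame in canonical region order."""
    if len(vectors) == 0:
        raise ValueError("no vectors to stack")
    labels = vectors[0].region_labels
    for v in vectors[1:]:
        if not np.array_equal(v.region_labels, labels):
            raise ValueError("vectors have mismatched region labels")
    return pd.DataFrame(
        [v.values for v in vectors],
        index=[getattr(v, "subject_id", None) or f"s{i}" for i, v in enumerate(vectors)],
        columns=labels,
    )


def _as_matrix(x) -> Tuple[np.ndarray, np.ndarray]:
    """Accept a DataFrame (subjects x regions) or a list of vectors."""
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(dtype=float), x.columns.to_numpy()
    if isinstance(x, np.ndarray):
        return np.asarray(x, dtype=float), np.arange(1, x.shape[1] + 1)
    df = stack_vectors(list(x))
    return df.to_numpy(dtype=float), df.columns.to_numpy()


def region_ttest(
    group_a,
    group_b,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per region (pooled variance by default).

    Returns a DataFrame indexed by region label with columns ``t``, ``p``,
    ``q`` (Benjamini-Hochberg adjusted, reported as an extension),
    ``significant`` (p < alpha) and ``degenerate``.
    """
    a, labels_a = _as_matrix(group_a)
    b, labels_b = _as_matrix(group_b)
    if not np.array_equal(labels_a, labels_b):
        raise ValueError("group tables have mismatched region labels")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    t, p = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = np.zeros(a.shape[1], dtype=bool)
    zero_var = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    if zero_var.any():
        same_mean = np.isclose(a.mean(axis=0), b.mean(axis=0))
        fix = zero_var & same_mean
        t[fix] = 0.0
        p[fix] = 1.0
        degenerate[zero_var & ~same_mean] = True
        p[zero_var & ~same_mean] = np.nan
        t[zero_var & ~same_mean] = np.nan
    finite = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if finite.any():
        q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    significant = np.where(finite, p < alpha, False)
    return pd.DataFrame(
        {
            "t": t,
            "p": p,
            "q": q,
            "significant": significant,
            "degenerate": degenerate,
        },
        index=pd.Index(labels_a, name="label_id"),
    )


def region_permutation_test(
    group_a,
    group_b,
    n_permutations: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Label-permutation test per region on |difference of group means|.

    Monte-Carlo mode uses the add-one estimator
    ``p = (1 + #{permuted |d| >= observed |d|}) / (1 + n_permutations)``;
    when the number of distinct relabelings C(n_a + n_b, n_a) does not
    exceed ``n_permutations``, all of them are enumerated and the exact
    enumeration p (ties count as exceedances) is returned instead. The
    ``exhaustive`` column records which mode was used.
    """
    if n_permutations < 100:
        raise ValueError("use at least 100 permutations")
    a, labels_a = _as_matrix(group_a)
    b, labels_b = _as_matrix(group_b)
    if not np.array_equal(labels_a, labels_b):
        raise ValueError("group tables have mismatched region labels")
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    pooled = np.vstack([a, b])
    n = n_a + n_b
    observed = np.abs(a.mean(axis=0) - b.mean(axis=0))
    tie_eps = 1e-12

    n_exhaustive = math.comb(n, n_a)
    if n_exhaustive <= n_permutations:
        count = np.zeros(a.shape[1], dtype=np.int64)
        idx_all = np.arange(n)
        for combo in itertools.combinations(range(n), n_a):
            sel = np.asarray(combo)
            rest = np.setdiff1d(idx_all, sel, assume_unique=True)
            d = np.abs(pooled[sel].mean(axis=0) - pooled[rest].mean(axis=0))
            count += d >= observed - tie_eps
        perm_p = count / n_exhaustive
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(a.shape[1], dtype=np.int64)
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            d = np.abs(
                pooled[perm[:n_a]].mean(axis=0) - pooled[perm[n_a:]].mean(axis=0)
            )
            count += d >= observed - tie_eps
        perm_p = (1 + count) / (1 + n_permutations)
        exhaustive = False
    return pd.DataFrame(
        {
            "abs_mean_diff": observed,
            "permutation_p": perm_p,
            "significant": perm_p < alpha,
            "exhaustive": exhaustive,
        },
        index=pd.Index(labels_a, name="label_id"),
    )


def _pearson_by_region(
    x: pd.DataFrame, y: pd.DataFrame, regions
) -> pd.DataFrame:
    rows = []
    for region in regions:
        xv = x[region].to_numpy(dtype=float)
        yv = y[region].to_numpy(dtype=float)
        if xv.std() == 0 or yv.std() == 0:
            rows.append((region, np.nan, np.nan, True))
            continue
        r, p = sps.pearsonr(xv, yv)
        rows.append((region, float(r), float(p), False))
    return pd.DataFrame(
        rows, columns=["label_id", "r", "p", "degenerate"]
    ).set_index("label_id")


def crossmodal_correlation(
    metric_table: pd.DataFrame,
    suvr_table: pd.DataFrame,
    regions: Optional[Sequence] = None,
    group: str = "",
) -> pd.DataFrame:
    """Per-region Pearson correlation across subjects between a connectivity
    metric (FCs or PLFCS) and tau SUVR, within one diagnostic group.

    Both tables are subjects x regions with identical subject order.
    """
    if list(metric_table.index) != list(suvr_table.index):
        raise ValueError("metric and SUVR tables must cover identical subjects")
    if metric_table.shape[0] < 3:
        raise ValueError("need at least 3 subjects for a correlation")
    if regions is None:
        regions = list(metric_table.columns)
    unknown = [r for r in regions if r not in metric_table.columns]
    if unknown:
        raise ValueError(f"selected regions absent from tables: {unknown}")
    out = _pearson_by_region(metric_table, suvr_table, regions)
    out["group"] = group
    out["n_subjects"] = metric_table.shape[0]
    return out


def hub_vulnerability(
    nc_strength: StrengthVector, disease_plfcs: PLFCSVector
) -> Tuple[float, float]:
    """Pearson r and p across regions between normal-control group-mean
    strength and a disease group's mean proportional loss.

    A negative r is the hub-vulnerability signature: nodes with higher
    baseline strength lose the larger proportion of connectivity.
    """
    if not np.array_equal(nc_strength.region_labels, disease_plfcs.region_labels):
        raise ValueError("strength and PLFCS region labels do not match")
    if len(nc_strength.values) < 3:
        raise ValueError("need at least 3 regions")
    r, p = sps.pearsonr(nc_strength.values, disease_plfcs.values)
    return float(r), float(p)


def clinical_correlation(
    metrics: pd.DataFrame, scores: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r, p for every (metric column, score column) pair.

    ``metrics``: per-subject summary measures (e.g. global PLFCS, mean hub
    loss, global SUVR); ``scores``: per-subject clinical scales (MMSE-like,
    CDR-SB-like). Subject order must match.
    """
    if list(metrics.index) != list(scores.index):
        raise ValueError("metric and score tables must cover identical subjects")
    if metrics.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValueError("clinical scores must be finite")
    rows = []
    for m in metrics.columns:
        for s in scores.columns:
            x = metrics[m].to_numpy(dtype=float)
            y = scores[s].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                rows.append((m, s, np.nan, np.nan, True))
                continue
            r, p = sps.pearsonr(x, y)
            rows.append((m, s, float(r), float(p), False))
    return pd.DataFrame(
        rows, columns=["metric", "score", "r", "p", "degenerate"]
    )


@dataclass
class GroupComparison:
    """One-way ANOVA across groups plus Bonferroni pairwise post hocs."""

    f_statistic: float
    p_value: float
    group_means: Dict[str, float]
    pairwise_p: Dict[Tuple[str, str], float]  # Bonferroni-adjusted, capped at 1

    def significant_pairs(self, alpha: float = 0.05):
        return [pair for pair, p in self.pairwise_p.items() if p < alpha]


def global_group_comparison(
    groups: Mapping[str, Sequence[float]], equal_var: bool = True
) -> GroupComparison:
    """One-way ANOVA over diagnostic groups with Bonferroni post hoc t-tests.

    Each pairwise two-sided p is multiplied by the number of pairs and
    capped at 1.
    """
    names = list(groups.keys())
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {g} needs at least 2 subjects")
    f, p = sps.f_oneway(*arrays)
    pairs = list(itertools.combinations(range(len(names)), 2))
    n_pairs = len(pairs)
    pairwise: Dict[Tuple[str, str], float] = {}
    for i, j in pairs:
        _, p_raw = sps.ttest_ind(arrays[i], arrays[j], equal_var=equal_var)
        pairwise[(names[i], names[j])] = min(1.0, float(p_raw) * n_pairs)
    return GroupComparison(
        f_statistic=float(f),
        p_value=float(p),
        group_means={g: float(arr.mean()) for g, arr in zip(names, arrays)},
        pairwise_p=pairwise,
    )
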