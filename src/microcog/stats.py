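"""Cohort-level statistics: NPZ-6 scoring and small-sample group tests.

The NPZ-6 composite is the arithmetic mean of six standardized cognitive
domain scores; participants at or below the -0.5 threshold form the Lower
(impaired) group. Group comparisons follow the conventions usual for tiny
unbalanced cohorts: Pearson chi-square without continuity correction for
categorical variables and the exact two-sided Wilcoxon rank-sum (Mann-Whitney)
test for continuous ones, with the exact branch computed by enumeration of
all group assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

NPZ6_THRESHOLD = -0.5
EXACT_MAX_N = 20


def npz6_score(domains) -> float:
    """Arithmetic mean of the six cognitive-domain z-scores."""
    arr = np.asarray(domains, dtype=float)
    if arr.shape != (6,):
        raise ValueError(f"expected exactly 6 domain scores, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite domain score")
    return float(arr.mean())


def classify_group(score: float, threshold: float = NPZ6_THRESHOLD) -> str:
    """'Lower' iff score <= threshold (boundary closed on the impaired side)."""
    if not np.isfinite(score):
        raise ValueError("non-finite NPZ-6 score")
    return "Lower" if score <= threshold else "Higher"


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square on a 2 x k contingency table, no continuity correction.

    All-zero columns are dropped with a warning; df = (#columns kept) - 1.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be non-negative integers")
    if obs.sum() == 0:
        raise ValueError("all-zero contingency table")
    if (obs.sum(axis=1) == 0).any():
        raise ValueError("both row sums must be positive")
    zero_cols = obs.sum(axis=0) == 0
    if zero_cols.any():
        warnings.warn(
            f"dropping {int(zero_cols.sum())} all-zero column(s) from contingency table",
            stacklevel=2,
        )
        obs = obs[:, ~zero_cols]
    if obs.shape[1] < 2:
        raise ValueError("need at least two non-empty columns")
    stat, p, df, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), int(df), float(p)


@lru_cache(maxsize=64)
def _rank_sum_counts(n1: int, n2: int) -> tuple[np.ndarray, int]:
    """Null counts of W = sum of ranks of the first group, ties absent.

    Dynamic programming over which of the ranks 1..n1+n2 land in group 1;
    equivalent to enumerating all C(n1+n2, n1) assignments.
    """
    n = n1 + n2
    max_w = n1 * n + 1
    # counts[k, w] = number of ways to pick k ranks so far with sum w
    counts = np.zeros((n1 + 1, max_w), dtype=np.int64)
    counts[0, 0] = 1
    for r in range(1, n + 1):
        kmax = min(r, n1)
        for k in range(kmax, 0, -1):
            counts[k, r:] += counts[k - 1, :-r] if r else counts[k - 1, :]
    w_counts = counts[n1]
    return w_counts, int(w_counts.sum())


def _exact_rank_sum_p(w: int, n1: int, n2: int) -> float:
    w_counts, total = _rank_sum_counts(n1, n2)
    lo = int(w_counts[: w + 1].sum())
    hi = int(w_counts[w:].sum())
    return min(1.0, 2.0 * min(lo, hi) / total)


def _normal_rank_sum(x, y, continuity: bool = True) -> tuple[float, float]:
    """Normal approximation with midranks, tie correction, optional cc."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = sps.rankdata(np.concatenate([x, y]))
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    u = w - n1 * (n1 + 1) / 2.0
    if var <= 0:  # all observations identical
        return u, 1.0
    num = w - mu
    if continuity:
        num = np.sign(num) * max(abs(num) - 0.5, 0.0)
    z = num / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return u, float(p)


def exact_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of the first
    sample. The p-value is exact — two-sided as twice the smaller tail of
    the enumeration null of all C(n1+n2, n1) assignments, capped at 1 —
    whenever n1+n2 <= 20 and there are no ties; otherwise the normal
    approximation with tie and continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2
    if n1 + n2 <= EXACT_MAX_N and not has_ties:
        ranks = sps.rankdata(pooled)
        w = int(round(ranks[:n1].sum()))
        u = w - n1 * (n1 + 1) / 2.0
        return float(u), _exact_rank_sum_p(w, n1, n2)
    return _normal_rank_sum(x, y, continuity=True)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (df = g - 1)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


@dataclass
class GroupComparison:
    """One Table-1-style row: a variable compared between the two groups."""

    variable: str
    var_type: str  # "categorical" | "continuous"
    statistic: float
    p_value: float
    summaries: dict


def _median_iqr(values: np.ndarray) -> str:
    med = np.median(values)
    q1, q3 = np.percentile(values, [25, 75])  # linear-interpolation quartiles
    return f"{med:g} ({q1:g} - {q3:g})"


def group_descriptives(metadata_frame, variables: dict[str, str],
                       group_col: str = "npz6_group") -> list[GroupComparison]:
    """Compare each variable between groups.

    ``variables`` maps column name to ``"categorical"`` or ``"continuous"``.
    Categorical variables go through the chi-square test on the group-by-level
    count table; continuous ones through the exact rank-sum test, summarized
    as median (IQR).
    """
    frame = metadata_frame
    labels = sorted(frame[group_col].unique())
    if len(labels) != 2:
        raise ValueError("group descriptives require exactly two groups")
    out: list[GroupComparison] = []
    for var, var_type in variables.items():
        col = frame[var]
        if var_type == "categorical":
            tab = (
                frame.groupby([group_col, var]).size().unstack(fill_value=0)
                .reindex(labels, fill_value=0)
            )
            counts = tab.to_numpy()
            stat, _, p = chi_square_test(counts)
            summaries = {
                lab: {str(lev): int(c) for lev, c in zip(tab.columns, row)}
                for lab, row in zip(labels, counts)
            }
        elif var_type == "continuous":
            vals = {lab: col[frame[group_col] == lab].to_numpy(dtype=float)
                    for lab in labels}
            if np.all(col.to_numpy() == col.iloc[0]):
                warnings.warn(f"variable {var!r} is constant", stacklevel=2)
            stat, p = exact_rank_sum(vals[labels[0]], vals[labels[1]])
            summaries = {lab: _median_iqr(v) for lab, v in vals.items()}
        else:
            raise ValueError(f"unknown variable type {var_type!r} for {var!r}")
        out.append(GroupComparison(var, var_type, float(stat), float(p), summaries))
    return out
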