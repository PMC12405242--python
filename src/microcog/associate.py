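"""Associations of the indices with outcomes, networks, diversity and pathways.

Per-timepoint exact rank-sum comparisons of the index values, Spearman
correlations with Benjamini-Hochberg adjustment inside declared families,
|rho|-thresholded correlation networks, Bray-Curtis PERMANOVA for
community-level group structure, and hypergeometric over-representation of
metabolite sets against a user-supplied GMT library.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .containers import FeatureTable, PathwayLibrary, TIMEPOINTS
from .stats import exact_rank_sum

def bh_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if n == 0:
        return p.copy()
    m = n if m is None else int(m)
    if m < n:
        raise ValueError("family size m cannot be smaller than len(pvalues)")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out


def _spearman(x: np.ndarray, y: np.ndarray, exact: bool = False) -> tuple[float, float]:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan
    rho, p = sps.spearmanr(x, y)
    if exact and len(x) <= 8:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(rho)
        hits = total = 0
        for perm in iter_permutations(ry):
            r, _ = sps.pearsonr(rx, np.asarray(perm))
            hits += abs(r) >= obs - 1e-12
            total += 1
        p = hits / total
    return float(rho), float(p)


def spearman_bh(a: pd.DataFrame, b: pd.DataFrame,
                family: str = "all", exact: bool = False) -> pd.DataFrame:
    """All-pairs Spearman correlations between columns of two frames.

    Rows must be shared samples (aligned on the index). ``family`` names the
    BH family the whole result forms; adjustment is applied across all pairs
    of the call. Returns a tidy frame with ``var_a, var_b, rho, p, p_adj,
    family``.
    """
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    av = a.loc[common]
    bv = b.loc[common]
    rows = []
    for ca in av.columns:
        for cb in bv.columns:
            rho, p = _spearman(av[ca].to_numpy(dtype=float),
                               bv[cb].to_numpy(dtype=float), exact=exact)
            rows.append((ca, cb, rho, p))
    out = pd.DataFrame(rows, columns=["var_a", "var_b", "rho", "p"])
    mask = out["p"].notna()
    out["p_adj"] = np.nan
    if mask.any():
        out.loc[mask, "p_adj"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    out["family"] = family
    return out


def correlation_network(associations: pd.DataFrame, cutoff: float = 0.6) -> pd.DataFrame:
    """Edges with |rho| >= cutoff; sign retained."""
    keep = associations["rho"].abs() >= cutoff
    edges = associations.loc[keep, ["var_a", "var_b", "rho"]].copy()
    edges["sign"] = np.sign(edges["rho"]).astype(int)
    return edges.reset_index(drop=True)


def longitudinal_index_comparison(index_values: pd.DataFrame,
                                  metadata) -> pd.DataFrame:
    """Per-timepoint Lower-vs-Higher rank-sum tests of each index.

    ``index_values`` is sample-indexed with one column per index.
    When both bsl and final are present, the within-group change summary
    (sign counts of final - bsl and an exact signed-rank p, exploratory at
    these group sizes) is appended with ``test == 'change'``.
    """
    meta = metadata.frame if hasattr(metadata, "frame") else metadata
    merged = index_values.join(meta[["participant", "timepoint", "npz6_group"]])
    rows = []
    present = [t for t in TIMEPOINTS if (merged["timepoint"] == t).any()]
    for tp in present:
        sub = merged[merged["timepoint"] == tp]
        lo = sub[sub["npz6_group"] == "Lower"]
        hi = sub[sub["npz6_group"] == "Higher"]
        for idx_name in index_values.columns:
            u, p = exact_rank_sum(lo[idx_name], hi[idx_name])
            rows.append({
                "index": idx_name, "timepoint": tp, "test": "group",
                "statistic": u, "p": p,
                "median_lower": float(lo[idx_name].median()),
                "median_higher": float(hi[idx_name].median()),
            })
    if {"bsl", "final"} <= set(present):
        for group in ("Lower", "Higher"):
            sub = merged[merged["npz6_group"] == group]
            piv = sub.pivot(index="participant", columns="timepoint")
            for idx_name in index_values.columns:
                delta = (piv[(idx_name, "final")] - piv[(idx_name, "bsl")]).dropna()
                try:
                    stat, p = sps.wilcoxon(delta, method="exact")
                except ValueError:
                    stat, p = np.nan, np.nan
                rows.append({
                    "index": idx_name, "timepoint": f"final-bsl ({group})",
                    "test": "change", "statistic": float(stat), "p": float(p),
                    "median_lower": float((delta < 0).sum()),
                    "median_higher": float((delta > 0).sum()),
                })
    return pd.DataFrame(rows)


def delta_correlation(index_values_final: pd.DataFrame,
                      npz6_delta: pd.Series) -> pd.DataFrame:
    """Spearman correlation of each index (final) with delta NPZ-6.

    A constant delta vector yields missing rho, not an error.
    """
    common = index_values_final.index.intersection(npz6_delta.index)
    d = npz6_delta.loc[common].to_numpy(dtype=float)
    rows = []
    for idx_name in index_values_final.columns:
        x = index_values_final.loc[common, idx_name].to_numpy(dtype=float)
        rho, p = _spearman(x, d)
        rows.append({"index": idx_name, "rho": rho, "p": p})
    return pd.DataFrame(rows)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("R^2 must lie in [0, 1]")


def bray_curtis(values: np.ndarray) -> np.ndarray:
    """Condensed Bray-Curtis dissimilarities between rows."""
    return pdist(np.asarray(values, dtype=float), metric="braycurtis")


def _permanova_ss(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    n = d2.shape[0]
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        ssw += d2[np.ix_(idx, idx)][np.triu_indices(idx.size, 1)].sum() / idx.size
    return sst, ssw


def bray_curtis_permanova(table, classes, n_perm: int = 999,
                          seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA on Bray-Curtis dissimilarities, free permutations.

    p = (1 + #{permuted F >= observed F}) / (1 + n_perm).
    """
    values = table.values if isinstance(table, FeatureTable) else pd.DataFrame(table)
    arr = values.to_numpy(dtype=float)
    groups = np.asarray(classes)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    n = arr.shape[0]
    a = len(uniq)
    d2 = squareform(bray_curtis(arr)) ** 2

    def pseudo_f(g: np.ndarray) -> float:
        sst, ssw = _permanova_ss(d2, g)
        ssa = sst - ssw
        if ssw <= 0:
            return np.inf if ssa > 0 else 0.0
        return (ssa / (a - 1)) / (ssw / (n - a))

    f_obs = pseudo_f(groups)
    sst, ssw = _permanova_ss(d2, groups)
    r2 = 0.0 if sst == 0 else max(0.0, min(1.0, (sst - ssw) / sst))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if pseudo_f(rng.permutation(groups)) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm)


def ora_enrich(query, library: PathwayLibrary, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of a metabolite set.

    For each pathway set S (intersected with the universe), the upper-tail
    probability P(X >= |query & S|) with population = |universe|, successes =
    |S|, draws = |query|; BH adjustment across the tested pathways.
    """
    universe = frozenset(universe)
    query = frozenset(query)
    if not query <= universe:
        raise ValueError("query metabolites must be a subset of the universe")
    big_n = len(universe)
    n_draw = len(query)
    rows = []
    for name, members in library.sets.items():
        members = members & universe
        if not members:
            warnings.warn(f"pathway {name!r} disjoint from universe; skipped",
                          stacklevel=2)
            continue
        k = len(members & query)
        p = float(sps.hypergeom.sf(k - 1, big_n, len(members), n_draw))
        rows.append({"pathway": name, "set_size": len(members),
                     "overlap": k, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["pathway", "set_size", "overlap", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out
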