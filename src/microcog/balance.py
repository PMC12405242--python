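"""Log-ratio balance indices over discriminant feature sets.

The core statistic: for a sample with abundances x, a numerator set N of
features enriched in the Lower (impaired) group at baseline and a
denominator set D enriched in the Higher group,

    index(x) = ln gm(x_N) - ln gm(x_D)

with gm the geometric mean. The statistic is invariant to per-sample
rescaling (so relative abundances and arbitrarily normalized intensities can
even be pooled in the combined index) and strictly monotone in each member
feature. Feature sets are frozen at baseline and applied unchanged at later
timepoints. Zeros are replaced by a pseudocount — half the smallest
non-zero value of the same table by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureTable
from .stats import exact_rank_sum


class UndefinedIndexError(ValueError):
    """Raised when an index cannot be built (an empty side)."""


@dataclass(frozen=True)
class IndexDefinition:
    """Frozen numerator/denominator feature sets of one balance index.

    ``kinds`` maps every member feature to the table kind it is read from
    (``taxon`` or ``metabolite``), which is what lets the combined index pull
    from both tables.
    """

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]
    kinds: dict[str, str] = field(default_factory=dict)
    pseudocount_policy: str = "half_min_nonzero"
    log_base: float = float(np.e)

    def __post_init__(self) -> None:
        if not self.numerator or not self.denominator:
            raise UndefinedIndexError(
                f"{self.name} index undefined: empty "
                f"{'numerator' if not self.numerator else 'denominator'}"
            )
        overlap = set(self.numerator) & set(self.denominator)
        if overlap:
            raise ValueError(
                f"{self.name} index: features in both numerator and "
                f"denominator: {sorted(overlap)}"
            )

    @property
    def features(self) -> tuple[str, ...]:
        return self.numerator + self.denominator

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "numerator": list(self.numerator),
            "denominator": list(self.denominator),
            "kinds": dict(self.kinds),
            "pseudocount_policy": self.pseudocount_policy,
            "log_base": self.log_base,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IndexDefinition":
        return cls(
            name=d["name"],
            numerator=tuple(d["numerator"]),
            denominator=tuple(d["denominator"]),
            kinds=dict(d.get("kinds", {})),
            pseudocount_policy=d.get("pseudocount_policy", "half_min_nonzero"),
            log_base=d.get("log_base", float(np.e)),
        )


def _pseudocount(values: np.ndarray, policy: str) -> float:
    if policy == "half_min_nonzero":
        nz = values[values > 0]
        if nz.size == 0:
            raise ValueError("table has no positive values")
        return float(nz.min() / 2.0)
    try:
        pc = float(policy)
    except (TypeError, ValueError):
        raise ValueError(f"unknown pseudocount policy {policy!r}") from None
    if pc <= 0:
        raise ValueError("numeric pseudocount must be positive")
    return pc


def _tables_by_kind(tables) -> dict[str, FeatureTable]:
    if isinstance(tables, FeatureTable):
        return {tables.kind: tables}
    if isinstance(tables, dict):
        return tables
    raise TypeError("tables must be a FeatureTable or a kind->FeatureTable dict")


def index_values(tables, definition: IndexDefinition) -> pd.Series:
    """Per-sample index values for one definition.

    ``tables`` is a single :class:`FeatureTable` or a mapping of kind to
    table (needed by the combined index). All tables must share sample ids.
    """
    by_kind = _tables_by_kind(tables)
    sample_ids = None
    for t in by_kind.values():
        if sample_ids is None:
            sample_ids = t.sample_ids
        elif t.sample_ids != sample_ids:
            raise ValueError("tables disagree on sample ids")
    pcs = {
        kind: _pseudocount(t.values.to_numpy(dtype=float),
                           definition.pseudocount_policy)
        for kind, t in by_kind.items()
    }
    logs: dict[str, np.ndarray] = {}
    for feat in definition.features:
        kind = definition.kinds.get(feat)
        if kind is None and len(by_kind) == 1:
            kind = next(iter(by_kind))
        if kind not in by_kind:
            raise KeyError(
                f"no table of kind {kind!r} supplied for feature {feat!r}"
            )
        table = by_kind[kind]
        if feat not in table.values.columns:
            raise KeyError(f"feature {feat!r} missing from the {kind} table")
        col = table.values[feat].to_numpy(dtype=float)
        logs[feat] = np.log(np.where(col > 0, col, pcs[kind]))
    num = np.mean([logs[f] for f in definition.numerator], axis=0)
    den = np.mean([logs[f] for f in definition.denominator], axis=0)
    out = (num - den) / np.log(definition.log_base)
    return pd.Series(out, index=sample_ids, name=definition.name)


def compute_index(sample_values, definition: IndexDefinition) -> float:
    """Index value for a single sample given as a feature->value mapping."""
    vals = pd.Series(sample_values, dtype=float)
    missing = [f for f in definition.features if f not in vals.index]
    if missing:
        raise KeyError(f"features missing from sample: {missing}")
    arr = vals.to_numpy(dtype=float)
    pc = _pseudocount(arr, definition.pseudocount_policy)
    logv = np.log(np.where(arr > 0, arr, pc))
    logv = pd.Series(logv, index=vals.index)
    num = float(np.mean([logv[f] for f in definition.numerator]))
    den = float(np.mean([logv[f] for f in definition.denominator]))
    return (num - den) / float(np.log(definition.log_base))


def build_microbial_index(species_bsl, classes, alpha: float = 0.05,
                          lower_label: str = "Lower",
                          name: str = "microbial") -> IndexDefinition:
    """Rank-sum-enriched species at baseline define the two sides.

    Numerator: species with exact two-sided rank-sum p < alpha and higher
    median abundance in the Lower group; denominator: the Higher-enriched
    analogues. An empty side makes the index undefined (error, never NaN).
    """
    frame = species_bsl.values if isinstance(species_bsl, FeatureTable) else species_bsl
    y = np.asarray(classes)
    mask_lower = y == lower_label
    if mask_lower.all() or not mask_lower.any():
        raise ValueError("need both groups present")
    arr = frame.to_numpy(dtype=float)
    num, den = [], []
    for j, feat in enumerate(frame.columns):
        col = arr[:, j]
        if np.all(col == col[0]):
            continue
        _, p = exact_rank_sum(col[mask_lower], col[~mask_lower])
        if p < alpha:
            if np.median(col[mask_lower]) > np.median(col[~mask_lower]):
                num.append(feat)
            else:
                den.append(feat)
    if not num or not den:
        raise UndefinedIndexError(
            f"microbial index undefined at alpha={alpha}: "
            f"{len(num)} Lower-enriched / {len(den)} Higher-enriched species"
        )
    kinds = {f: "taxon" for f in (*num, *den)}
    return IndexDefinition(name, tuple(num), tuple(den), kinds)


def build_metabolome_index(pc1_selection, name: str = "metabolome") -> IndexDefinition:
    """PC1-threshold metabolite sets define the two sides.

    The positive set (oriented toward Lower-group elevation) is the
    numerator, the negative set the denominator.
    """
    pos = list(getattr(pc1_selection, "positive_"))
    neg = list(getattr(pc1_selection, "negative_"))
    if not pos or not neg:
        raise UndefinedIndexError(
            f"metabolome index undefined: {len(pos)} positive / "
            f"{len(neg)} negative PC1 features"
        )
    kinds = {f: "metabolite" for f in (*pos, *neg)}
    return IndexDefinition(name, tuple(pos), tuple(neg), kinds)


def build_combined_index(microbial: IndexDefinition,
                         metabolome: IndexDefinition,
                         name: str = "combined") -> IndexDefinition:
    """Union of both numerators over the union of both denominators."""
    num = tuple(dict.fromkeys(microbial.numerator + metabolome.numerator))
    den = tuple(dict.fromkeys(microbial.denominator + metabolome.denominator))
    overlap = set(num) & set(den)
    if overlap:
        raise ValueError(
            f"combined index: conflicting membership for {sorted(overlap)}"
        )
    kinds = {**microbial.kinds, **metabolome.kinds}
    return IndexDefinition(name, num, den, kinds)


class BalanceIndex:
    """Estimator-style wrapper: learn a microbial index at baseline, apply anywhere.

    ``fit(X, y)`` builds the frozen definition from a baseline species table
    and group labels; ``transform(X)`` returns per-sample index values for
    any table holding the member features.
    """

    def __init__(self, alpha: float = 0.05, lower_label: str = "Lower"):
        self.alpha = alpha
        self.lower_label = lower_label

    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha, "lower_label": self.lower_label}

    def set_params(self, **params) -> "BalanceIndex":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "BalanceIndex":
        table = X if isinstance(X, FeatureTable) else FeatureTable(
            _coerce_frame(X), kind="taxon")
        self.definition_ = build_microbial_index(
            table, y, alpha=self.alpha, lower_label=self.lower_label
        )
        return self

    def transform(self, X) -> pd.Series:
        if not hasattr(self, "definition_"):
            raise ValueError("BalanceIndex is not fitted")
        table = X if isinstance(X, FeatureTable) else FeatureTable(
            _coerce_frame(X), kind="taxon")
        return index_values(table, self.definition_)

    def fit_transform(self, X, y) -> pd.Series:
        return self.fit(X, y).transform(X)


def _coerce_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"f{j}" for j in range(X.shape[1])])
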