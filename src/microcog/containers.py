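"""Core in-memory containers shared across the pipeline.

A :class:`FeatureTable` is a validated samples-by-features matrix (taxa,
pathways or metabolites); :class:`CohortMetadata` carries the per-sample
clinical annotation (participant, timepoint, NPZ-6 group, outcome scales);
:class:`PathwayLibrary` holds named metabolite sets for over-representation
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_KINDS = ("taxon", "pathway", "metabolite")

TIMEPOINTS = ("bsl", "post", "final")
GROUPS = ("Lower", "Higher")

#: the six standardized cognitive-domain measures averaged into NPZ-6
DOMAIN_COLS = (
    "z_attention_wm",
    "z_processing_speed",
    "z_memory_learning",
    "z_executive",
    "z_verbal_fluency",
    "z_motor",
)

#: functional outcome scales and the sign with which each loads on cognition
#: (quality of life and daily functioning improve with cognition; distress
#: scales worsen)
OUTCOME_SIGNS = {
    "qol": 1.0,
    "daily_functioning": 1.0,
    "depression_anxiety": -1.0,
    "stress": -1.0,
    "cns_symptoms": -1.0,
}
OUTCOME_COLS = tuple(OUTCOME_SIGNS)

NORMALIZED_TOL = 1e-6


@dataclass
class FeatureTable:
    """Samples x features non-negative matrix with a feature kind.

    Parameters
    ----------
    values:
        DataFrame with sample ids as the index and feature ids as columns.
    kind:
        One of ``taxon``, ``pathway`` or ``metabolite``.
    normalized:
        True when every row sums to 1 (relative abundances).
    """

    values: pd.DataFrame
    kind: str
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        v = self.values
        if v.index.duplicated().any():
            dups = v.index[v.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if v.columns.duplicated().any():
            dups = v.columns[v.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("non-finite values in feature table")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value at sample {v.index[i]!r}, feature {v.columns[j]!r}"
            )
        if self.normalized:
            sums = arr.sum(axis=1)
            bad = np.abs(sums - 1.0) > NORMALIZED_TOL
            if bad.any():
                raise ValueError(
                    f"table flagged normalized but row {v.index[int(np.argmax(bad))]!r} "
                    f"sums to {sums[int(np.argmax(bad))]:.6g}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.values.loc[list(sample_ids)], self.kind, self.normalized)

    def __eq__(self, other) -> bool:  # value equality, for round-trip checks
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.normalized == other.normalized
            and self.values.equals(other.values)
        )


@dataclass
class CohortMetadata:
    """Per-sample clinical annotation, one row per sample id."""

    frame: pd.DataFrame

    REQUIRED = ("participant", "timepoint", "npz6_group", "sex")

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        missing = [c for c in self.REQUIRED if c not in f.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        bad_tp = set(f["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoint labels: {sorted(bad_tp)}")
        bad_grp = set(f["npz6_group"]) - set(GROUPS)
        if bad_grp:
            raise ValueError(f"unknown NPZ-6 group labels: {sorted(bad_grp)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def samples_at(self, timepoint: str) -> pd.DataFrame:
        if timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {timepoint!r}")
        return self.frame[self.frame["timepoint"] == timepoint]

    def groups_for(self, sample_ids) -> pd.Series:
        return self.frame.loc[list(sample_ids), "npz6_group"]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CohortMetadata):
            return NotImplemented
        return self.frame.equals(other.frame)


@dataclass
class PathwayLibrary:
    """Named metabolite sets (GMT-style) plus descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"pathway set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def restricted_to(self, universe) -> "PathwayLibrary":
        """Intersect every set with *universe*, dropping sets that vanish."""
        universe = frozenset(universe)
        kept = {
            name: members & universe
            for name, members in self.sets.items()
            if members & universe
        }
        return PathwayLibrary(kept, {k: self.descriptions.get(k, "") for k in kept})
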