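"""Readers and writers for the pipeline's on-disk formats.

Feature tables live on disk features-as-rows (MetaPhlAn/HUMAnN orientation,
first header field ``feature_id``) and in memory samples-as-rows. Tables whose
per-sample totals are ~100 are treated as percentages and converted to
fractions. Pathway membership comes in as standard GMT.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import FeatureTable, CohortMetadata, PathwayLibrary

FEATURE_HEADER = "feature_id"
SAMPLE_HEADER = "sample_id"
PERCENT_TOL = 1e-3
FRACTION_TOL = 1e-6


def read_feature_table(path, kind: str, orientation: str = "auto") -> FeatureTable:
    """Read a TSV feature table and validate it.

    Orientation is auto-detected from the first header field (``feature_id``
    → features as rows, ``sample_id`` → samples as rows); pass
    ``orientation="features"``/``"samples"`` explicitly for headerless-token
    files. Taxon/pathway tables whose per-sample totals are ~100 are divided
    by 100 (percent convention); tables summing to ~1 are flagged normalized.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    token = str(frame.index.name or "").lstrip("#")
    if orientation == "auto":
        if token == FEATURE_HEADER:
            orientation = "features"
        elif token == SAMPLE_HEADER:
            orientation = "samples"
        else:
            raise ValueError(
                f"{path}: cannot auto-detect orientation from header token "
                f"{token!r}; pass orientation='features' or 'samples'"
            )
    if orientation == "features":
        frame = frame.T
    elif orientation != "samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    if frame.isna().any().any():
        raise ValueError(f"{path}: ragged or missing entries")

    normalized = False
    if kind in ("taxon", "pathway"):
        sums = frame.to_numpy(dtype=float).sum(axis=1)
        if np.all(np.abs(sums - 100.0) <= PERCENT_TOL * 100.0):
            frame = frame / 100.0
            normalized = True
        elif np.all(np.abs(sums - 1.0) <= FRACTION_TOL):
            normalized = True
    return FeatureTable(frame.astype(float), kind=kind, normalized=bool(normalized))


def write_feature_table(path, table: FeatureTable) -> None:
    """Write features-as-rows TSV at full double precision."""
    out = table.values.T
    out.index.name = FEATURE_HEADER
    out.to_csv(path, sep="\t", float_format="%.17g")


def metaphlan_species(table: FeatureTable) -> FeatureTable:
    """Extract the species level from a MetaPhlAn-style pipe-delimited table.

    Keeps clades whose last component is an ``s__`` entry (no strain level)
    and renames features to that component.
    """
    keep, names = [], []
    for fid in table.feature_ids:
        parts = fid.split("|")
        if parts[-1].startswith("s__"):
            keep.append(fid)
            names.append(parts[-1])
    sub = table.values[keep].copy()
    sub.columns = names
    return FeatureTable(sub, kind="taxon", normalized=False)


def read_metadata(path) -> CohortMetadata:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    return CohortMetadata(frame)


def write_metadata(path, metadata: CohortMetadata) -> None:
    out = metadata.frame.copy()
    out.index.name = SAMPLE_HEADER
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_gmt(path) -> PathwayLibrary:
    """Read a GMT pathway library (name, description, members...)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                warnings.warn(f"{path}:{lineno}: blank line skipped", stacklevel=2)
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT set {fields[0]!r} has no members"
                )
            name, desc, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            if not members:
                raise ValueError(
                    f"{path}:{lineno}: GMT set {name!r} has no members"
                )
            unique = frozenset(members)
            if len(unique) < len(members):
                warnings.warn(
                    f"{path}:{lineno}: duplicate members in set {name!r} collapsed",
                    stacklevel=2,
                )
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = unique
            descriptions[name] = desc
    return PathwayLibrary(sets, descriptions)


def write_gmt(path, library: PathwayLibrary) -> None:
    with open(path, "w") as fh:
        for name, members in library.sets.items():
            desc = library.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
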