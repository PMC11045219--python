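"""Readers and writers for the tabular formats the pipeline consumes.

Native dialect is TSV throughout: count matrices carry ``feature_id``,
``gene_id`` and ``length`` columns followed by one column per sample, with
a sidecar two-column TSV mapping sample names to condition labels.  Gene
sets use the GMT dialect; ranked lists use the two-column RNK dialect.
Missing values are encoded as ``NA`` and are only legal in derived result
columns, never in raw counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

_META_COLUMNS = ["feature_id", "gene_id", "length"]


@dataclass
class CountTable:
    """Feature-by-sample integer read counts with per-feature lengths.

    Parameters
    ----------
    features : pandas.DataFrame
        Indexed by ``feature_id``; columns ``gene_id`` (parent gene of the
        feature, equal to the feature id for gene-level tables) and
        ``length`` (feature length in nucleotides).
    counts : pandas.DataFrame
        Same index as ``features``; one integer column per sample.
    conditions : dict
        Maps each sample name to its condition label.
    """

    features: pd.DataFrame
    counts: pd.DataFrame
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.features.index.has_duplicates:
            dupes = self.features.index[self.features.index.duplicated()]
            raise FormatError(f"duplicate feature ids: {sorted(set(dupes))[:5]}")
        if not self.features.index.equals(self.counts.index):
            raise FormatError("features and counts indexes differ")
        if (self.features["length"] <= 0).any():
            raise FormatError("feature lengths must be positive")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                raise FormatError("counts must be integers (NA is not legal here)")
        if (arr < 0).any():
            raise FormatError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.conditions]
        if missing:
            raise FormatError(f"samples without condition label: {missing}")

    # -- convenience ------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def condition_names(self) -> list[str]:
        """Distinct condition labels in first-appearance sample order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.conditions[s], None)
        return list(seen)

    def condition_samples(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions[s] == condition]

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    # -- I/O --------------------------------------------------------------
    def write(self, path: str | Path, condition_map_path: str | Path) -> None:
        table = self.features.copy()
        table.insert(0, "feature_id", table.index)
        out = pd.concat([table.reset_index(drop=True),
                         self.counts.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False)
        cond = pd.DataFrame({"sample": self.samples,
                             "condition": [self.conditions[s] for s in self.samples]})
        cond.to_csv(condition_map_path, sep="\t", index=False)


def read_count_table(path: str | Path,
                     condition_map_path: str | Path) -> CountTable:
    """Read a TSV count matrix plus its sample-to-condition sidecar.

    Row order is preserved.  Duplicate feature ids, negative or
    non-integer counts, and samples missing from the condition map all
    raise :class:`~exonsi.errors.FormatError`.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"feature_id": str, "gene_id": str},
                      na_values=[], keep_default_na=False)
    for col in _META_COLUMNS:
        if col not in raw.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in raw.columns if c not in _META_COLUMNS]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns")
    try:
        counts = raw[sample_cols].apply(pd.to_numeric).astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric count field ({exc})") from exc
    if not (raw[sample_cols].apply(pd.to_numeric) == counts).all().all():
        raise FormatError(f"{path}: counts must be integers")
    features = raw[_META_COLUMNS].set_index("feature_id")
    features["length"] = pd.to_numeric(features["length"])
    counts.index = features.index

    cond = pd.read_csv(condition_map_path, sep="\t")
    if not {"sample", "condition"} <= set(cond.columns):
        raise FormatError(f"{condition_map_path}: need 'sample' and 'condition' columns")
    conditions = dict(zip(cond["sample"].astype(str), cond["condition"].astype(str)))
    return CountTable(features=features, counts=counts, conditions=conditions)


@dataclass
class GeneSetCollection:
    """Named gene sets; member order is preserved, members are unique."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {name!r} has duplicate members")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (set name, description, members; tab-separated).

    The description field is ignored.  Duplicate members within a set are
    stored once with a logged warning; a line with fewer than three fields
    or an empty member list is a format error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields")
            name = fields[0]
            members: list[str] = []
            seen: set[str] = set()
            n_dupes = 0
            for m in fields[2:]:
                if not m:
                    continue
                if m in seen:
                    n_dupes += 1
                    continue
                seen.add(m)
                members.append(m)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
            if n_dupes:
                logger.warning("%s:%d: %d duplicate members in set %r dropped",
                               path, lineno, n_dupes, name)
            sets[name] = members
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, members in collection.items():
            handle.write("\t".join([name, "na", *members]) + "\n")


def write_rnk(ranked, path: str | Path) -> None:
    """Write a two-column RNK file sorted by score descending, stable ties.

    ``ranked`` may be a :class:`~exonsi.enrichment.RankedList` (or anything
    with ``ids``/``scores`` attributes) or an iterable of ``(id, score)``.
    """
    if hasattr(ranked, "ids") and hasattr(ranked, "scores"):
        pairs = list(zip(ranked.ids, ranked.scores))
    else:
        pairs = list(ranked)
    order = np.argsort([-float(s) for _, s in pairs], kind="stable")
    with open(path, "w") as handle:
        for i in order:
            ident, score = pairs[i]
            handle.write(f"{ident}\t{score:.10g}\n")


def read_rnk(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "score"],
                     dtype={"id": str})
    df["score"] = pd.to_numeric(df["score"])
    return df


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with a stable column order and NA for missing."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
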