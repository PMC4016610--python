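"""SCOP-style hierarchical classifications as gold-standard annotations.

A classification assigns each entity a dotted sccs code such as ``a.1.1.2``
(class.fold.superfamily.family).  Truncating the code at a depth yields the
clade partition at that level; two entities sharing the truncated code are
"related" at that level, which defines the binary adjacency used as the
gold standard for ROC analysis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LEVELS",
    "ClassificationTable",
    "Partition",
    "PairAdjacency",
    "parse_classification",
    "clade_partition",
    "shared_annotation_adjacency",
]

LEVELS: dict[str, int] = {"class": 1, "fold": 2, "superfamily": 3, "family": 4}

_SCCS_RE = re.compile(r"^[A-Za-z0-9]+(\.[A-Za-z0-9]+){0,3}$")


@dataclass
class ClassificationTable:
    """Mapping from entity id to sccs code."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        for entity, code in self.entries.items():
            if not _SCCS_RE.match(code):
                raise ValueError(f"malformed sccs code {code!r} for {entity!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return sorted(self.entries)

    def code_at_level(self, entity: str, level: str) -> str:
        depth = LEVELS[level]
        return ".".join(self.entries[entity].split(".")[:depth])


@dataclass
class Partition:
    """Mutually exclusive clusters: label -> member id set."""

    clusters: dict[str, set[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, members in self.clusters.items():
            dup = seen & members
            if dup:
                raise ValueError(f"entities in multiple clusters: {sorted(dup)[:5]}")
            seen |= members
        self._universe = seen

    @property
    def assignment(self) -> dict[str, str]:
        return {e: label for label, members in self.clusters.items() for e in members}

    @property
    def universe(self) -> set[str]:
        return set(self._universe)

    def __len__(self) -> int:
        return len(self.clusters)


@dataclass
class PairAdjacency:
    """Binary shared-clade indicator over annotated entities (unordered pairs)."""

    ids: list[str]
    values: np.ndarray
    level: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("adjacency shape does not match ids")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("adjacency must be symmetric")


def parse_classification(
    source: str | Path,
    dialect: Literal["dir_cla", "two_column"] = "two_column",
) -> ClassificationTable:
    """Parse a classification file.

    ``dir_cla`` takes whitespace-separated records with the domain id in
    field 1 and the sccs code in field 4, skipping ``#`` comments; entities
    occurring on more than one line are multi-domain chains and are dropped
    (count logged).  ``two_column`` takes ``id<TAB>code`` lines; conflicting
    duplicates are an error.
    """
    path = Path(source)
    entries: dict[str, str] = {}
    multi: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if dialect == "dir_cla":
                fields = line.split()
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: expected >= 4 fields")
                entity, code = fields[0], fields[3]
            else:
                fields = line.split("\t")
                if len(fields) != 2:
                    raise ValueError(f"{path}:{lineno}: expected 'id<TAB>code'")
                entity, code = fields
            if not _SCCS_RE.match(code):
                raise ValueError(f"{path}:{lineno}: malformed sccs code {code!r}")
            if entity in entries or entity in multi:
                if dialect == "two_column":
                    if entries.get(entity) == code:
                        continue
                    raise ValueError(f"{path}:{lineno}: conflicting codes for {entity!r}")
                multi.add(entity)
                entries.pop(entity, None)
                continue
            entries[entity] = code
    if multi:
        logger.info("dropped %d multi-domain entities", len(multi))
    return ClassificationTable(entries=entries)


def clade_partition(table: ClassificationTable, level: str) -> Partition:
    """Group entities by their code prefix at the requested level."""
    if not table.entries:
        raise ValueError("empty classification table")
    clusters: dict[str, set[str]] = {}
    for entity in table.entries:
        clusters.setdefault(table.code_at_level(entity, level), set()).add(entity)
    return Partition(clusters=clusters)


def shared_annotation_adjacency(table: ClassificationTable, level: str) -> PairAdjacency:
    """Binary matrix: 1 iff two annotated entities share the clade at ``level``."""
    ids = table.ids()
    if len(ids) < 2:
        raise ValueError("need at least two annotated entities")
    codes = np.array([table.code_at_level(e, level) for e in ids])
    values = codes[:, None] == codes[None, :]
    return PairAdjacency(ids=ids, values=values, level=level)
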