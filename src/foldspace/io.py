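"""Readers and writers for the pipeline's file formats.

Distance matrices travel as dense TSV (header row of ids), PHYLIP square
matrices, or sparse triplet TSV (``id1<TAB>id2<TAB>value``; unlisted pairs
are unobserved).  Coordinates are TSV with an ``id dim1 ... dimR`` header
plus a JSON metadata sidecar; dendrograms are Newick; partitions and
classifications are two-column TSV.  Values are serialized with 12
significant digits so write/read round-trips are exact at that precision.

The module also parses the compact representation-naming code used to label
a structure-space representation, e.g. ``Dali(S12)`` = raw Dali scores
embedded by SMACOF in 12 dimensions, ``MATT(ZC24)`` = MATT probability
scores by classical scaling in 24 dimensions, ``CE(Z)`` = pairwise CE
probability scores with no projection.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .annotate import Partition
from .embed import Configuration
from .scores import DistanceMatrix, SimilarityMatrix
from .treecluster import Dendrogram, TreeNode

__all__ = [
    "RepresentationCode",
    "parse_representation_code",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_similarity_matrix",
    "read_coordinates",
    "write_coordinates",
    "read_partition",
    "write_partition",
    "to_newick",
    "write_newick",
]

_FMT = "%.12g"


@dataclass(frozen=True)
class RepresentationCode:
    aligner: str
    score_type: Literal["raw", "probability"]
    projection: Literal["pairwise", "cmds", "smacof"]
    dim: int | None = None

    def render(self) -> str:
        flags = "Z" if self.score_type == "probability" else ""
        if self.projection != "pairwise":
            flags += "C" if self.projection == "cmds" else "S"
            if self.dim is not None:
                flags += str(self.dim)
        return f"{self.aligner}({flags})" if flags else self.aligner


_CODE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_-]*)(?:\((.*)\))?$")
_FLAGS_RE = re.compile(r"^(Z)?([CS])?(\d+)?$")


def parse_representation_code(code: str) -> RepresentationCode:
    """Parse ``ALIGNER``, ``ALIGNER(Z)`` or ``ALIGNER([Z][C|S][dim])``."""
    if not code:
        raise ValueError("empty representation code")
    m = _CODE_RE.match(code)
    if not m:
        raise ValueError(f"unparsable representation code {code!r}")
    aligner, flags = m.group(1), m.group(2)
    if flags is None or flags == "":
        if flags == "":
            raise ValueError(f"{code!r}: empty parentheses")
        return RepresentationCode(aligner, "raw", "pairwise")
    fm = _FLAGS_RE.match(flags)
    if not fm:
        bad = next((k for k, ch in enumerate(flags) if ch not in "ZCS0123456789"), len(flags) - 1)
        raise ValueError(f"{code!r}: bad flag at position {len(aligner) + 1 + bad}")
    z, proj, dim = fm.groups()
    if dim is not None and proj is None:
        raise ValueError(f"{code!r}: dimensionality requires a projection flag C or S")
    if z is None and proj is None:
        raise ValueError(f"{code!r}: empty or misordered flags")
    return RepresentationCode(
        aligner=aligner,
        score_type="probability" if z else "raw",
        projection={"C": "cmds", "S": "smacof", None: "pairwise"}[proj],
        dim=int(dim) if dim is not None else None,
    )


# ---------------------------------------------------------------- distances


def _validate_dense(ids: list[str], values: np.ndarray, where: str) -> None:
    n = len(ids)
    if values.shape != (n, n):
        raise ValueError(f"{where}: matrix is not {n}x{n}")
    if not np.allclose(values, values.T, rtol=1e-9, atol=0.0):
        raise ValueError(f"{where}: matrix is asymmetric beyond tolerance")
    if (values < 0).any():
        raise ValueError(f"{where}: negative distance")


def read_distance_matrix(
    path: str | Path,
    format: Literal["tsv_dense", "phylip_square", "tsv_triplet"] = "tsv_dense",
) -> DistanceMatrix:
    path = Path(path)
    if format == "tsv_dense":
        with path.open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            ids = header[1:]
            rows, row_ids = [], []
            for lineno, line in enumerate(fh, start=2):
                fields = line.rstrip("\n").split("\t")
                if len(fields) != len(ids) + 1:
                    raise ValueError(f"{path}:{lineno}: ragged row")
                row_ids.append(fields[0])
                rows.append([float(v) for v in fields[1:]])
        if row_ids != ids:
            raise ValueError(f"{path}: row ids do not match header ids")
        values = np.array(rows, dtype=float)
        _validate_dense(ids, values, str(path))
        return DistanceMatrix(ids=ids, values=values)
    if format == "phylip_square":
        with path.open() as fh:
            n = int(fh.readline().split()[0])
            ids, rows = [], []
            for lineno, line in enumerate(fh, start=2):
                fields = line.split()
                if not fields:
                    continue
                if len(fields) != n + 1:
                    raise ValueError(f"{path}:{lineno}: ragged row")
                ids.append(fields[0])
                rows.append([float(v) for v in fields[1:]])
        if len(ids) != n:
            raise ValueError(f"{path}: expected {n} rows, got {len(ids)}")
        values = np.array(rows, dtype=float)
        _validate_dense(ids, values, str(path))
        return DistanceMatrix(ids=ids, values=values)
    if format == "tsv_triplet":
        ids: list[str] = []
        index: dict[str, int] = {}
        entries: dict[tuple[int, int], float] = {}
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 'id1<TAB>id2<TAB>value'")
                a, b, sval = fields
                v = float(sval)
                if v < 0:
                    raise ValueError(f"{path}:{lineno}: negative distance")
                for e in (a, b):
                    if e not in index:
                        index[e] = len(ids)
                        ids.append(e)
                key = (min(index[a], index[b]), max(index[a], index[b]))
                if key in entries and entries[key] != v:
                    raise ValueError(f"{path}:{lineno}: conflicting duplicate for pair {a!r},{b!r}")
                entries[key] = v
        n = len(ids)
        values = np.zeros((n, n))
        observed = np.eye(n, dtype=bool)
        for (i, j), v in entries.items():
            if i == j:
                continue
            values[i, j] = values[j, i] = v
            observed[i, j] = observed[j, i] = True
        return DistanceMatrix(ids=ids, values=values, observed=observed)
    raise ValueError(f"unknown format {format!r}")


def write_distance_matrix(
    dist: DistanceMatrix,
    path: str | Path,
    format: Literal["tsv_dense", "phylip_square", "tsv_triplet"] = "tsv_dense",
) -> None:
    path = Path(path)
    if format == "tsv_dense":
        with path.open("w") as fh:
            fh.write("id\t" + "\t".join(dist.ids) + "\n")
            for i, e in enumerate(dist.ids):
                fh.write(e + "\t" + "\t".join(_FMT % v for v in dist.values[i]) + "\n")
        return
    if format == "phylip_square":
        with path.open("w") as fh:
            fh.write(f"{dist.n}\n")
            for i, e in enumerate(dist.ids):
                fh.write(e + "  " + "  ".join(_FMT % v for v in dist.values[i]) + "\n")
        return
    if format == "tsv_triplet":
        iu, ju = dist.observed_pairs()
        with path.open("w") as fh:
            for i, j in zip(iu, ju):
                fh.write(f"{dist.ids[i]}\t{dist.ids[j]}\t{_FMT % dist.values[i, j]}\n")
        return
    raise ValueError(f"unknown format {format!r}")


def read_similarity_matrix(
    path: str | Path,
    format: Literal["tsv_dense", "phylip_square", "tsv_triplet"] = "tsv_dense",
    polarity: Literal["similarity", "dissimilarity"] = "similarity",
    aligner: str = "",
    score_type: Literal["raw", "probability"] = "raw",
) -> SimilarityMatrix:
    """Read raw alignment scores; no symmetry or sign validation is applied.

    Aligners may emit asymmetric and negative scores, so unlike
    :func:`read_distance_matrix` this reader only checks shape.  Triplet
    entries are mirrored; dense/PHYLIP layouts follow the distance formats.
    """
    path = Path(path)
    if format == "tsv_triplet":
        ids: list[str] = []
        index: dict[str, int] = {}
        entries: dict[tuple[int, int], float] = {}
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 'id1<TAB>id2<TAB>score'")
                a, b, sval = fields
                for e in (a, b):
                    if e not in index:
                        index[e] = len(ids)
                        ids.append(e)
                key = (min(index[a], index[b]), max(index[a], index[b]))
                v = float(sval)
                if key in entries and entries[key] != v:
                    raise ValueError(f"{path}:{lineno}: conflicting duplicate for pair {a!r},{b!r}")
                entries[key] = v
        n = len(ids)
        values = np.zeros((n, n))
        observed = np.eye(n, dtype=bool)
        for (i, j), v in entries.items():
            if i == j:
                continue
            values[i, j] = values[j, i] = v
            observed[i, j] = observed[j, i] = True
        return SimilarityMatrix(
            ids=ids, values=values, observed=observed,
            polarity=polarity, aligner=aligner, score_type=score_type,
        )
    with path.open() as fh:
        if format == "phylip_square":
            n = int(fh.readline().split()[0])
            ids, rows = [], []
            for lineno, line in enumerate(fh, start=2):
                fields = line.split()
                if not fields:
                    continue
                if len(fields) != n + 1:
                    raise ValueError(f"{path}:{lineno}: ragged row")
                ids.append(fields[0])
                rows.append([float(v) for v in fields[1:]])
        else:
            header = fh.readline().rstrip("\n").split("\t")
            ids = header[1:]
            rows = []
            for lineno, line in enumerate(fh, start=2):
                fields = line.rstrip("\n").split("\t")
                if len(fields) != len(ids) + 1:
                    raise ValueError(f"{path}:{lineno}: ragged row")
                rows.append([float(v) for v in fields[1:]])
    return SimilarityMatrix(
        ids=ids, values=np.array(rows, dtype=float),
        polarity=polarity, aligner=aligner, score_type=score_type,
    )


# -------------------------------------------------------------- coordinates


def write_coordinates(config: Configuration, path: str | Path) -> None:
    """Coordinate TSV plus a ``<path>.meta.json`` provenance sidecar."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\t" + "\t".join(f"dim{k + 1}" for k in range(config.dim)) + "\n")
        for e, row in zip(config.ids, config.coords):
            fh.write(e + "\t" + "\t".join(_FMT % v for v in row) + "\n")
    meta = {
        "method": config.method,
        "dim": config.dim,
        "stress": config.stress,
        "iterations": config.iterations,
        "seed": config.seed,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1) + "\n")


def read_coordinates(path: str | Path) -> Configuration:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        dim = len(header) - 1
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != dim + 1:
                raise ValueError(f"{path}:{lineno}: ragged row")
            ids.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Configuration(
        ids=ids,
        coords=np.array(rows, dtype=float),
        method=meta.get("method", "given"),
        stress=meta.get("stress"),
        iterations=meta.get("iterations", 0),
        seed=meta.get("seed"),
    )


# --------------------------------------------------------------- partitions


def write_partition(partition: Partition, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for label in sorted(partition.clusters):
            for e in sorted(partition.clusters[label]):
                fh.write(f"{e}\t{label}\n")


def read_partition(path: str | Path) -> Partition:
    clusters: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>cluster'")
            clusters.setdefault(fields[1], set()).add(fields[0])
    return Partition(clusters=clusters)


# ------------------------------------------------------------------- newick

_PLAIN_LABEL_RE = re.compile(r"^[A-Za-z0-9_.|+-]+$")


def _newick_label(name: str) -> str:
    if _PLAIN_LABEL_RE.match(name):
        return name
    return "'" + name.replace("'", "''") + "'"


def to_newick(tree: Dendrogram) -> str:
    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _newick_label(node.name)
        inner = ",".join(f"{render(c)}:{_FMT % length}" for c, length in node.children)
        return f"({inner})"

    return render(tree.root) + ";"


def write_newick(tree: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")
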