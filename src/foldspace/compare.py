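"""Agreement between an automatic tessellation and a clade system.

Each group in the source partition is mapped to the target group with the
highest Jaccard coefficient J = |A n B| / |A u B|.  Summary statistics of
the mapping — how many distinct targets are used, the degree to which one
target absorbs several sources, and the distribution of best-match J —
quantify how closely the two tessellations correspond.  The analysis is
directional; both directions are normally reported.  A power-law fit to the
per-entity alignment-count histogram diagnoses scale-free sparsity of
incomplete alignment sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

import numpy as np

from .annotate import Partition

__all__ = [
    "MappingStats",
    "PowerLawFit",
    "jaccard",
    "best_match_mapping",
    "mapping_stats",
    "degree_powerlaw_fit",
]


@dataclass
class MappingStats:
    """Directional best-match summary (the Ratio-1 table row).

    ``mean_degree * n_unique_targets == n_matched`` by construction;
    ``ratio_minus_1 = n_source / n_unique_targets - 1`` is 0 for a perfect
    one-to-one correspondence.
    """

    direction: tuple[str, str]
    n_source: int
    n_unique_targets: int
    max_degree: int
    mean_degree: float
    std_degree: float
    mean_sim: float
    std_sim: float
    ratio_minus_1: float


@dataclass
class PowerLawFit:
    """Least-squares line on log10(frequency) vs log10(bin center)."""

    exponent: float
    intercept: float
    r_squared: float
    bins: int


def jaccard(a: set[str], b: set[str]) -> float:
    """|A n B| / |A u B|; undefined (error) when both sets are empty."""
    if not a and not b:
        raise ValueError("Jaccard coefficient undefined for two empty sets")
    return len(a & b) / len(a | b)


def best_match_mapping(
    source: Partition, target: Partition
) -> dict[str, tuple[str | None, float]]:
    """Map every source group to its most similar target group by Jaccard.

    Ties are broken toward the lexicographically smallest target label.  A
    source group overlapping no target group maps to ``(None, 0.0)``.
    """
    entity_to_targets: dict[str, list[str]] = {}
    for label, members in target.clusters.items():
        for e in members:
            entity_to_targets.setdefault(e, []).append(label)
    mapping: dict[str, tuple[str | None, float]] = {}
    for s_label, s_members in source.clusters.items():
        candidates = sorted({t for e in s_members for t in entity_to_targets.get(e, [])})
        best: tuple[str | None, float] = (None, 0.0)
        for t_label in candidates:
            j = jaccard(s_members, target.clusters[t_label])
            if j > best[1]:
                best = (t_label, j)
        mapping[s_label] = best
    return mapping


def mapping_stats(
    source: Partition,
    target: Partition,
    names: tuple[str, str] = ("source", "target"),
) -> MappingStats:
    """Degree and similarity statistics of the best-match mapping.

    The degree of a used target is the number of source groups best-matched
    to it.  Standard deviations are population (divide by n).  Note the
    statistics are NOT symmetric in the two partitions.
    """
    mapping = best_match_mapping(source, target)
    sims = np.array([j for _, j in mapping.values()])
    matched = [t for t, _ in mapping.values() if t is not None]
    if not matched:
        raise ValueError("no source group overlaps any target group")
    degrees = np.array(list(Counter(matched).values()))
    n_unique = degrees.size
    return MappingStats(
        direction=names,
        n_source=len(source.clusters),
        n_unique_targets=n_unique,
        max_degree=int(degrees.max()),
        mean_degree=float(len(matched) / n_unique),
        std_degree=float(degrees.std()),
        mean_sim=float(sims.mean()),
        std_sim=float(sims.std()),
        ratio_minus_1=float(len(source.clusters) / n_unique - 1.0),
    )


def degree_powerlaw_fit(counts, n_bins: int = 20, spacing: str = "log") -> PowerLawFit:
    """Fit a power law to the histogram of per-entity alignment counts.

    The counts are binned into ``n_bins`` bins — logarithmically spaced with
    geometric bin centers by default, the standard treatment for scale-free
    degree data, since equal-width bins leave the tail Poisson-dominated at
    moderate sample sizes (``spacing='linear'`` gives equal-width bins with
    arithmetic centers).  Zero-frequency bins are dropped (their log is
    undefined) and a straight line is fitted to log10(frequency) against
    log10(bin center).  The slope is the power-law exponent of the bin
    counts (negative for a decaying law).
    """
    counts = np.asarray(counts, dtype=float)
    if spacing == "log":
        positive = counts[counts > 0]
        if positive.size == 0:
            raise ValueError("log-spaced binning needs positive counts")
        edges = np.logspace(
            np.log10(positive.min()), np.log10(positive.max() + 1.0), n_bins + 1
        )
        freq, edges = np.histogram(counts, bins=edges)
        centers = np.sqrt(edges[:-1] * edges[1:])
    elif spacing == "linear":
        freq, edges = np.histogram(counts, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    keep = (freq > 0) & (centers > 0)
    if int(keep.sum()) < 3:
        raise ValueError("need at least three non-empty histogram bins")
    x = np.log10(centers[keep])
    y = np.log10(freq[keep])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return PowerLawFit(exponent=float(slope), intercept=float(intercept), r_squared=r2, bins=n_bins)
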