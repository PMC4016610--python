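"""Transform pairwise structure-alignment scores into distance matrices.

Structure aligners report similarity scores (higher = more alike).  To treat
them as dissimilarities they are subtracted from a cap ``s_n`` chosen as a
high percentile (default 99.95%) of the observed score distribution, so that
a handful of outlier scores cannot dominate the geometry of the resulting
map.  Scores at or above the cap map to distance zero by default ("clamp"),
i.e. the most similar pairs coincide; a "literal" mode assigning the cap
distance instead is retained for comparison experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "SimilarityMatrix",
    "DistanceMatrix",
    "percentile_index",
    "pair_rank",
    "select_max_score",
    "similarity_to_distance",
    "passthrough_dissimilarity",
    "symmetrize",
    "DEFAULT_PERCENTILE",
]

DEFAULT_PERCENTILE = 99.95

Polarity = Literal["similarity", "dissimilarity"]


def _full_mask(n: int) -> np.ndarray:
    return np.ones((n, n), dtype=bool)


@dataclass
class SimilarityMatrix:
    """Square matrix of pairwise alignment scores with an observation mask.

    ``observed[i, j]`` is False for pairs the aligner never scored (sparse
    aligners such as Dali skip most pairs).  The diagonal is ignored by all
    downstream operations.
    """

    ids: list[str]
    values: np.ndarray
    observed: np.ndarray | None = None
    polarity: Polarity = "similarity"
    aligner: str = ""
    score_type: Literal["raw", "probability"] = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} does not match {n} ids")
        if self.observed is None:
            self.observed = _full_mask(n)
        else:
            self.observed = np.asarray(self.observed, dtype=bool)
            if not np.array_equal(self.observed, self.observed.T):
                raise ValueError("observation mask must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_symmetric(self, rtol: float = 1e-9) -> bool:
        both = self.observed & self.observed.T
        a, b = self.values[both], self.values.T[both]
        return bool(np.allclose(a, b, rtol=rtol, atol=0.0))


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarities with zero diagonal.

    ``cap`` records the maximum score used by :func:`similarity_to_distance`
    (and hence the largest possible distance); it is absent for matrices that
    did not come from the score transform.
    """

    ids: list[str]
    values: np.ndarray
    observed: np.ndarray | None = None
    cap: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} does not match {n} ids")
        if self.observed is None:
            self.observed = _full_mask(n)
        else:
            self.observed = np.asarray(self.observed, dtype=bool)
            np.fill_diagonal(self.observed, True)
            if not np.array_equal(self.observed, self.observed.T):
                raise ValueError("observation mask must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def complete(self) -> bool:
        return bool(self.observed.all())

    def observed_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Index arrays (i, j) with i < j of observed off-diagonal pairs."""
        iu, ju = np.triu_indices(self.n, k=1)
        keep = self.observed[iu, ju]
        return iu[keep], ju[keep]

    def copy(self) -> "DistanceMatrix":
        return DistanceMatrix(
            ids=list(self.ids),
            values=self.values.copy(),
            observed=self.observed.copy(),
            cap=self.cap,
        )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def pair_rank(p: float, n_pairs: int) -> int:
    """Nearest-rank index of the p-th percentile in a sorted list of scores.

    ``n = round(p/100 * (M + 1))`` with round-half-up, clamped to
    ``[1, M]`` where ``M`` is the number of scored pairs.
    """
    if n_pairs < 1:
        raise ValueError("need at least one scored pair")
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"percentile must lie in [0, 100], got {p}")
    n = _round_half_up(p / 100.0 * (n_pairs + 1))
    return min(max(n, 1), n_pairs)


def percentile_index(p: float, n_entities: int) -> int:
    """Rank of the p-th percentile among all N(N-1)/2 pairwise scores."""
    if n_entities < 2:
        raise ValueError("need at least two entities")
    return pair_rank(p, n_entities * (n_entities - 1) // 2)


def _observed_upper_scores(sim: SimilarityMatrix) -> np.ndarray:
    iu, ju = np.triu_indices(sim.n, k=1)
    keep = sim.observed[iu, ju]
    return sim.values[iu[keep], ju[keep]]


def select_max_score(sim: SimilarityMatrix, p: float = DEFAULT_PERCENTILE) -> float:
    """Cap score s_n: the score at the p-th percentile rank of observed pairs.

    Each unordered pair counts once; the percentile is taken over observed
    pairs only, so sparse inputs are handled consistently.
    """
    scores = _observed_upper_scores(sim)
    if scores.size == 0:
        raise ValueError("no observed off-diagonal scores")
    n = pair_rank(p, scores.size)
    return float(np.sort(scores, kind="stable")[n - 1])


def symmetrize(sim: SimilarityMatrix, rule: Literal["mean", "min", "max"] = "mean") -> SimilarityMatrix:
    """Combine s_ij and s_ji into a symmetric score matrix.

    Pairs observed in both directions are combined by ``rule``; pairs
    observed in one direction only are copied across.
    """
    combine = {"mean": lambda a, b: 0.5 * (a + b), "min": np.minimum, "max": np.maximum}[rule]
    v, vt = sim.values, sim.values.T
    obs, obst = sim.observed, sim.observed.T
    out = np.zeros_like(v)
    both = obs & obst
    out[both] = combine(v[both], vt[both])
    only_fwd = obs & ~obst
    out[only_fwd] = v[only_fwd]
    out[only_fwd.T] = v.T[only_fwd.T]
    return replace(sim, values=out, observed=obs | obst)


def similarity_to_distance(
    sim: SimilarityMatrix,
    p: float = DEFAULT_PERCENTILE,
    overflow_mode: Literal["clamp", "literal"] = "clamp",
) -> DistanceMatrix:
    """Distances by subtracting similarity scores from the cap s_n.

    ``delta_ij = s_n - s_ij`` for scores below the cap and 0 on the diagonal.
    Scores at or above the cap become 0 ("clamp", default: most-similar pairs
    get zero distance) or ``s_n`` ("literal").  Unobserved pairs stay
    unobserved; ``cap`` records s_n.
    """
    if sim.polarity != "similarity":
        raise ValueError(
            "input carries dissimilarities; use passthrough_dissimilarity instead"
        )
    if not sim.is_symmetric():
        raise ValueError("scores are asymmetric; apply symmetrize() first")
    s_n = select_max_score(sim, p)
    delta = s_n - sim.values
    over = sim.values >= s_n
    delta[over] = 0.0 if overflow_mode == "clamp" else s_n
    delta[~sim.observed] = 0.0
    np.fill_diagonal(delta, 0.0)
    # mirror to remove floating asymmetry from one-directional copies
    delta = 0.5 * (delta + delta.T)
    return DistanceMatrix(ids=list(sim.ids), values=delta, observed=sim.observed.copy(), cap=s_n)


def passthrough_dissimilarity(sim: SimilarityMatrix) -> DistanceMatrix:
    """Adopt an already-dissimilar score matrix as distances.

    MATT probability scores, for instance, are distances already.  The
    diagonal is forced to zero; negative off-diagonal values are rejected.
    """
    if sim.polarity != "dissimilarity":
        raise ValueError("input carries similarities; use similarity_to_distance")
    if not sim.is_symmetric():
        raise ValueError("scores are asymmetric; apply symmetrize() first")
    values = sim.values.copy()
    off = ~np.eye(sim.n, dtype=bool)
    if np.any((values < 0) & off & sim.observed):
        raise ValueError("negative off-diagonal dissimilarity")
    np.fill_diagonal(values, 0.0)
    values[~sim.observed] = 0.0
    return DistanceMatrix(ids=list(sim.ids), values=values, observed=sim.observed.copy())
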