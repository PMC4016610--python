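"""Synthetic structure-space fixtures with known ground truth.

Real fold space, as catalogued by SCOP, is hierarchical (folds contain
superfamilies contain members), extremely size-skewed (many singleton
clades), noisy (alignment scores are not exact metric distances and may
violate the triangle inequality), and — for some aligners — observed only on
a small, scale-free subset of pairs.  The generator emulates those four
statistical features with nested isotropic Gaussian clusters in ``r_true``
dimensions, Zipf-distributed clade sizes, additive distance noise with
optional multiplicative triangle-breaking inflation, and a hub-weighted
sparsity mask.  Every stage of the pipeline can therefore be tested against
a known answer.  All randomness flows from one seed through named
substreams (hierarchy / noise / mask), so the stages can be varied
independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .annotate import ClassificationTable
from .scores import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SizeSpec",
    "SynthParams",
    "SyntheticSpace",
    "generate_space",
    "perturb_distances",
    "sparsify",
    "observed_graph_connected",
]

# multiplicative inflation applied to violation pairs; large enough that an
# inflated edge typically breaks triangles through nearby points
VIOLATION_FACTOR = 2.5


@dataclass(frozen=True)
class SizeSpec:
    """Clade-size distribution: fixed count or truncated Zipf.

    ``zipf(a, max)`` draws sizes k in [1, max] with probability
    proportional to k**(-a); exponent 1.5 reproduces the singleton-heavy
    skew of SCOP clade sizes.
    """

    kind: str = "zipf"  # "fixed" | "zipf"
    value: int = 1
    exponent: float = 1.5
    maximum: int = 100

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(n, self.value, dtype=int)
        k = np.arange(1, self.maximum + 1)
        p = k ** (-self.exponent)
        return rng.choice(k, size=n, p=p / p.sum())


SizeLike = Union[int, SizeSpec]


def _as_spec(s: SizeLike) -> SizeSpec:
    return SizeSpec(kind="fixed", value=s) if isinstance(s, int) else s


@dataclass
class SynthParams:
    """Study conditions for a synthetic space.

    Defaults give ~15 folds, ~35 superfamilies, ~300 members in 12
    dimensions with nested spreads 10 : 3 : 1 and additive distance noise of
    0.5 — well separated at the superfamily level but not trivially so.
    """

    r_true: int = 12
    n_folds: int = 15
    superfamilies_per_fold: SizeLike = field(default_factory=lambda: SizeSpec("zipf", exponent=1.5, maximum=8))
    members_per_superfamily: SizeLike = field(default_factory=lambda: SizeSpec("zipf", exponent=1.5, maximum=120))
    fold_scale: float = 10.0
    superfamily_scale: float = 3.0
    member_scale: float = 1.0
    noise_sd: float = 0.5
    violation_rate: float = 0.0
    sparsity_fraction: float = 1.0
    hub_exponent: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.fold_scale, self.superfamily_scale, self.member_scale) <= 0:
            raise ValueError("scales must be positive")
        if not 0.0 < self.sparsity_fraction <= 1.0:
            raise ValueError("sparsity_fraction must lie in (0, 1]")
        if self.n_folds < 1 or self.r_true < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class SyntheticSpace:
    ids: list[str]
    coords_true: np.ndarray
    classification: ClassificationTable
    distances: DistanceMatrix
    params: SynthParams

    @property
    def n(self) -> int:
        return len(self.ids)

    def true_distances(self) -> DistanceMatrix:
        """Exact Euclidean distances of the ground-truth coordinates."""
        return DistanceMatrix(ids=list(self.ids), values=squareform(pdist(self.coords_true)))


def generate_space(params: SynthParams) -> SyntheticSpace:
    """Draw a clade-structured point cloud and its (optionally degraded) distances.

    Fold centers ~ N(0, fold_scale^2 I); superfamily centers ~ N(fold,
    superfamily_scale^2 I); members ~ N(superfamily, member_scale^2 I).
    Synthetic sccs codes are ``c1.f<i>.s<j>.m<k>``.  Distance noise,
    triangle violations and the sparsity mask are applied afterwards from
    independent substreams when the corresponding parameters request them.
    """
    ss_hier, ss_noise, ss_mask = np.random.SeedSequence(params.seed).spawn(3)
    rng = np.random.default_rng(ss_hier)
    sf_spec = _as_spec(params.superfamilies_per_fold)
    mem_spec = _as_spec(params.members_per_superfamily)

    ids: list[str] = []
    codes: dict[str, str] = {}
    coords: list[np.ndarray] = []
    sf_counts = sf_spec.sample(rng, params.n_folds)
    sf_global = 0
    for f in range(params.n_folds):
        fold_center = rng.normal(0.0, params.fold_scale, size=params.r_true)
        mem_counts = mem_spec.sample(rng, int(sf_counts[f]))
        for s in range(int(sf_counts[f])):
            sf_global += 1
            sf_center = fold_center + rng.normal(0.0, params.superfamily_scale, size=params.r_true)
            for k in range(int(mem_counts[s])):
                entity = f"p{len(ids):05d}"
                ids.append(entity)
                codes[entity] = f"c1.f{f + 1}.s{sf_global}.m{k + 1}"
                coords.append(sf_center + rng.normal(0.0, params.member_scale, size=params.r_true))

    x = np.vstack(coords)
    dist = DistanceMatrix(ids=ids, values=squareform(pdist(x)))
    if params.noise_sd > 0 or params.violation_rate > 0:
        dist = perturb_distances(
            dist, params.noise_sd, params.violation_rate, np.random.default_rng(ss_noise)
        )
    if params.sparsity_fraction < 1.0:
        dist = sparsify(
            dist, params.sparsity_fraction, params.hub_exponent, np.random.default_rng(ss_mask)
        )
    return SyntheticSpace(
        ids=ids,
        coords_true=x,
        classification=ClassificationTable(entries=codes),
        distances=dist,
        params=params,
    )


def _rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def perturb_distances(
    dist: DistanceMatrix,
    noise_sd: float,
    violation_rate: float = 0.0,
    seed: Union[int, np.random.Generator, None] = None,
) -> DistanceMatrix:
    """Add Gaussian noise per unordered pair and inflate a fraction of pairs.

    Noise is clamped at zero.  Inflated pairs (factor 2.5) break the triangle
    inequality through nearby third points, which shows up downstream as
    negative eigenvalues of the double-centered matrix.
    """
    if noise_sd < 0 or not 0.0 <= violation_rate <= 1.0:
        raise ValueError("noise_sd must be >= 0 and violation_rate in [0, 1]")
    rng = _rng(seed)
    n = dist.n
    values = dist.values.copy()
    iu, ju = np.triu_indices(n, k=1)
    upper = values[iu, ju]
    if noise_sd > 0:
        upper = np.maximum(upper + rng.normal(0.0, noise_sd, size=upper.size), 0.0)
    if violation_rate > 0:
        k = int(round(violation_rate * upper.size))
        if k > 0:
            chosen = rng.choice(upper.size, size=k, replace=False)
            upper[chosen] *= VIOLATION_FACTOR
    values[iu, ju] = upper
    values[ju, iu] = upper
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(ids=list(dist.ids), values=values, observed=dist.observed.copy(), cap=dist.cap)


def sparsify(
    dist: DistanceMatrix,
    fraction: float,
    hub_exponent: float = 1.2,
    seed: Union[int, np.random.Generator, None] = None,
) -> DistanceMatrix:
    """Retain a hub-weighted random subset of pairs.

    Entities get rank-based power-law weights w_(rank) = rank**(-hub_exponent)
    (ranks shuffled); pair (i, j) is kept with probability min(1, c w_i w_j),
    with c calibrated by bisection so the expected observed fraction equals
    ``fraction``.  High-weight hubs are observed against most partners, as
    seen for aligners that skip unpromising pairs, and the per-entity degree
    histogram follows a power law.  A disconnected observed graph is logged
    as a warning (SMACOF cannot place isolated components relative to each
    other).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return dist.copy()
    rng = _rng(seed)
    n = dist.n
    ranks = rng.permutation(n) + 1
    w = ranks.astype(float) ** (-hub_exponent)
    iu, ju = np.triu_indices(n, k=1)
    prod = w[iu] * w[ju]

    def expected(c: float) -> float:
        return float(np.minimum(1.0, c * prod).mean())

    lo, hi = 0.0, 1.0 / prod.min()  # at hi every pair probability is capped at 1
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected(mid) < fraction:
            lo = mid
        else:
            hi = mid
    p = np.minimum(1.0, hi * prod)
    keep = rng.random(p.size) < p

    observed = np.zeros((n, n), dtype=bool)
    observed[iu[keep], ju[keep]] = True
    observed |= observed.T
    np.fill_diagonal(observed, True)
    values = np.where(observed, dist.values, 0.0)
    out = DistanceMatrix(ids=list(dist.ids), values=values, observed=observed, cap=dist.cap)
    if not observed_graph_connected(out):
        logger.warning("observed pair graph is disconnected at fraction %.4f", fraction)
    return out


def observed_graph_connected(dist: DistanceMatrix) -> bool:
    """True when the graph of observed off-diagonal pairs is connected."""
    adj = dist.observed.copy()
    np.fill_diagonal(adj, False)
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    return bool(n_comp == 1)
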