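"""Low-dimensional coordinate maps from distance matrices.

Two multidimensional-scaling routes are provided.  Classical MDS double
centers the squared distances into an inner-product (Gram) matrix and reads
coordinates off its eigendecomposition; it is the linear least-squares
optimum but does not minimise stress.  SMACOF minimises raw stress

    sigma(X) = sum_{i<j} w_ij (d_ij(X) - delta_ij)^2

by iterative majorization (the Guttman transform), which decreases stress
monotonically at every step.  Sparse inputs are handled either by weighting
unobserved pairs out of the stress (the default, which lets SMACOF infer
unaligned pairs transitively) or by imputing them first for classical MDS.

A Procrustes statistic (normalized residual after optimal translation,
rotation/reflection and scaling) quantifies agreement between two maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform

from .scores import DistanceMatrix

__all__ = [
    "InnerProductMatrix",
    "Configuration",
    "double_center",
    "classical_mds",
    "stress",
    "smacof_update",
    "smacof",
    "impute_missing",
    "config_distances",
    "procrustes_statistic",
    "DEFAULT_TOL",
    "DEFAULT_MAX_ITER",
    "DEFAULT_DIM_SWEEP",
]

DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = 10_000
# dimensionalities used when sweeping map size in experiments
DEFAULT_DIM_SWEEP = (3, 6, 12, 24, 30, 60, 90, 120)


@dataclass
class InnerProductMatrix:
    """Double-centered Gram matrix A with its source entity ids."""

    values: np.ndarray
    source_ids: list[str]


@dataclass
class Configuration:
    """An N x r coordinate map with provenance.

    ``stress`` is the raw stress of ``coords`` against the distances the
    configuration was fitted to; ``eigenvalues`` is recorded for classical
    MDS only (non-increasing; non-positive eigenvalues yield zero columns).
    """

    ids: list[str]
    coords: np.ndarray
    method: Literal["cmds", "smacof", "random", "given"] = "given"
    stress: float | None = None
    iterations: int = 0
    eigenvalues: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be a 2-D array")
        if self.coords.shape[0] != len(self.ids):
            raise ValueError("coords row count does not match ids")
        if not np.isfinite(self.coords).all():
            raise ValueError("coords must be finite")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def dim(self) -> int:
        return self.coords.shape[1]


def double_center(dist: DistanceMatrix) -> InnerProductMatrix:
    """Inner-product matrix A_ij = -1/2 (d2_ij - row_i - col_j + grand).

    The row, column and grand means are taken over the squared distances;
    rows of A sum to zero.  Requires a complete matrix (impute first when
    sparse).
    """
    if not dist.complete:
        raise ValueError("distance matrix has unobserved pairs; impute_missing first")
    d2 = dist.values**2
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    grand = d2.mean()
    a = -0.5 * (d2 - row - col + grand)
    a = 0.5 * (a + a.T)  # enforce exact symmetry against rounding
    return InnerProductMatrix(values=a, source_ids=list(dist.ids))


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector orientation: largest-|.| component positive."""
    out = vecs.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            out[:, k] = -col
    return out


def classical_mds(dist: DistanceMatrix, r: int) -> Configuration:
    """Classical (Torgerson) MDS: X_ik = sqrt(lambda_k) v_ik.

    Eigenpairs of the double-centered matrix are sorted by descending
    eigenvalue (ties broken by original index); columns belonging to
    non-positive eigenvalues among the top ``r`` are zero.  Negative
    eigenvalues indicate triangle-inequality violations in the input.
    """
    n = dist.n
    if not 1 <= r <= n - 1:
        raise ValueError(f"dimension r={r} must satisfy 1 <= r <= N-1 = {n - 1}")
    a = double_center(dist)
    w, v = np.linalg.eigh(a.values)
    order = np.argsort(-w, kind="stable")
    w, v = w[order], _fix_signs(v[:, order])
    x = np.zeros((n, r))
    for k in range(r):
        if w[k] > 0:
            x[:, k] = math.sqrt(w[k]) * v[:, k]
    cfg = Configuration(ids=list(dist.ids), coords=x, method="cmds", eigenvalues=w)
    cfg.stress = stress(cfg, dist)
    return cfg


def _check_ids(config: Configuration, dist: DistanceMatrix) -> None:
    if list(config.ids) != list(dist.ids):
        raise ValueError("configuration and distance matrix ids do not match")


def _weight_matrix(dist: DistanceMatrix, weights: np.ndarray | None) -> np.ndarray:
    if weights is None:
        w = dist.observed.astype(float)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != dist.values.shape:
            raise ValueError("weight matrix shape mismatch")
    w = w.copy()
    np.fill_diagonal(w, 0.0)
    return w


def stress(config: Configuration, dist: DistanceMatrix, weights: np.ndarray | None = None) -> float:
    """Raw stress: weighted sum of squared residuals over unordered pairs.

    Weights default to the observation mask, so unobserved pairs contribute
    nothing.  Invariant under rotation and translation of the coordinates.
    """
    _check_ids(config, dist)
    w = _weight_matrix(dist, weights)
    d = squareform(pdist(config.coords))
    iu, ju = np.triu_indices(config.n, k=1)
    res = (d[iu, ju] - dist.values[iu, ju]) ** 2
    return float(np.sum(w[iu, ju] * res))


def _guttman_unweighted(x: np.ndarray, delta: np.ndarray) -> np.ndarray:
    # x_i' = (1/N) sum_j [x_j + delta_ij (x_i - x_j) / ||x_i - x_j||]
    n = x.shape[0]
    d = squareform(pdist(x))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, delta / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(ratio, 0.0)
    return x.mean(axis=0) + (ratio.sum(axis=1)[:, None] * x - ratio @ x) / n


def _guttman_weighted(
    x: np.ndarray, delta: np.ndarray, w: np.ndarray, v_pinv: np.ndarray | None = None
) -> np.ndarray:
    # X' = V^+ B(X) X with V = diag(W 1) - W; guarantees non-increasing stress
    d = squareform(pdist(x))
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(d > 0, -w * delta / np.where(d > 0, d, 1.0), 0.0)
    np.fill_diagonal(b, 0.0)
    np.fill_diagonal(b, -b.sum(axis=1))
    if v_pinv is None:
        v = np.diag(w.sum(axis=1)) - w
        v_pinv = np.linalg.pinv(v)
    return v_pinv @ (b @ x)


def smacof_update(
    config: Configuration, dist: DistanceMatrix, weights: np.ndarray | None = None
) -> Configuration:
    """One Guttman-transform step; stress never increases.

    With no weights and a complete matrix this is the plain update
    x_i' = (1/N) sum_j [x_j + delta_ij (x_i - x_j)/||x_i - x_j||], with the
    convention that the direction term vanishes for coincident points.  With
    weights (or a sparse mask) the weighted Guttman transform V^+ B(X) X is
    used, restricted to observed pairs.
    """
    _check_ids(config, dist)
    unweighted = weights is None and dist.complete
    if unweighted:
        x_new = _guttman_unweighted(config.coords, dist.values)
    else:
        w = _weight_matrix(dist, weights)
        x_new = _guttman_weighted(config.coords, dist.values, w)
    cfg = Configuration(
        ids=list(config.ids),
        coords=x_new,
        method="smacof",
        iterations=config.iterations + 1,
        seed=config.seed,
    )
    cfg.stress = stress(cfg, dist, weights)
    return cfg


def _random_init(dist: DistanceMatrix, r: int, seed: int | None) -> np.ndarray:
    rng = np.random.default_rng(seed)
    scale = float(dist.values[dist.observed].max()) or 1.0
    return rng.uniform(0.0, scale, size=(dist.n, r))


def smacof(
    dist: DistanceMatrix,
    r: int,
    init: Literal["cmds", "random", "given"] = "cmds",
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int | None = None,
    given: Configuration | None = None,
    weights: np.ndarray | None = None,
    missing: Literal["weights", "impute-cap", "impute-mean"] = "weights",
) -> Configuration:
    """Stress majorization until the relative stress drop falls below ``tol``.

    Iterates the Guttman transform from a classical-MDS (default), random, or
    caller-supplied start until (sigma_prev - sigma_new)/sigma_prev < tol
    (default 1e-5) or ``max_iter`` steps.  Sparse matrices are fitted with
    zero weight on unobserved pairs by default; ``missing='impute-cap'`` or
    ``'impute-mean'`` fills them instead and runs the unweighted update.
    """
    n = dist.n
    if not 1 <= r <= n - 1:
        raise ValueError(f"dimension r={r} must satisfy 1 <= r <= N-1 = {n - 1}")
    work = dist
    if not dist.complete and missing != "weights":
        work = impute_missing(dist, mode="cap" if missing == "impute-cap" else "mean")
    use_weights = weights is not None or not work.complete
    w = _weight_matrix(work, weights) if use_weights else None

    if init == "cmds":
        base = work if work.complete else impute_missing(work, "cap" if work.cap is not None else "mean")
        x = classical_mds(base, r).coords
    elif init == "random":
        x = _random_init(work, r, seed)
    elif init == "given":
        if given is None:
            raise ValueError("init='given' requires a starting configuration")
        if list(given.ids) != list(work.ids) or given.dim != r:
            raise ValueError("given configuration does not match ids/dimension")
        x = given.coords.copy()
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown init {init!r}")

    def _stress_of(coords: np.ndarray) -> float:
        d = squareform(pdist(coords))
        iu, ju = np.triu_indices(n, k=1)
        res = (d[iu, ju] - work.values[iu, ju]) ** 2
        ww = w[iu, ju] if w is not None else 1.0
        return float(np.sum(ww * res))

    v_pinv = None
    if use_weights:
        v = np.diag(w.sum(axis=1)) - w
        v_pinv = np.linalg.pinv(v)

    sigma = _stress_of(x)
    iterations = 0
    if sigma > 0:
        while iterations < max_iter:
            if use_weights:
                x_new = _guttman_weighted(x, work.values, w, v_pinv)
            else:
                x_new = _guttman_unweighted(x, work.values)
            sigma_new = _stress_of(x_new)
            if sigma_new == 0.0:
                x, sigma = x_new, sigma_new
                iterations += 1
                break
            if (sigma - sigma_new) / sigma < tol:
                break
            x, sigma = x_new, sigma_new
            iterations += 1

    return Configuration(
        ids=list(work.ids),
        coords=x,
        method="smacof",
        stress=sigma,
        iterations=iterations,
        seed=seed if init == "random" else None,
    )


def impute_missing(dist: DistanceMatrix, mode: Literal["cap", "mean"] = "cap") -> DistanceMatrix:
    """Fill unobserved off-diagonal entries with the cap or the observed mean."""
    if dist.complete:
        return dist.copy()
    if mode == "cap":
        if dist.cap is None:
            raise ValueError("mode='cap' requires a recorded cap")
        fill = float(dist.cap)
    elif mode == "mean":
        iu, ju = dist.observed_pairs()
        if iu.size == 0:
            raise ValueError("no observed off-diagonal distances to average")
        fill = float(dist.values[iu, ju].mean())
    else:  # pragma: no cover
        raise ValueError(f"unknown mode {mode!r}")
    values = dist.values.copy()
    values[~dist.observed] = fill
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(ids=list(dist.ids), values=values, cap=dist.cap)


def config_distances(config: Configuration) -> DistanceMatrix:
    """Full Euclidean distance matrix of a coordinate map."""
    values = squareform(pdist(config.coords)) if config.n > 1 else np.zeros((config.n, config.n))
    return DistanceMatrix(ids=list(config.ids), values=values)


def procrustes_statistic(a: Configuration, b: Configuration) -> float:
    """Normalized residual after optimally superimposing b onto a.

    Optimal translation, rotation (reflection allowed) and scaling are
    applied; the residual sum of squares is normalized by the centered sum
    of squares of ``a``.  0 means a perfect fit; 1 is attained by an
    uncorrelated configuration.
    """
    if list(a.ids) != list(b.ids):
        raise ValueError("configurations carry different ids")
    if a.dim != b.dim:
        raise ValueError("configurations have different dimensionality")
    _, _, disparity = _scipy_procrustes(a.coords, b.coords)
    return float(disparity)
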