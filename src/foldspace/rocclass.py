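"""ROC evaluation of a structure-space representation as a pair classifier.

A distance threshold t declares a pair of structures "related" when their
distance is at most t.  Sweeping t over every observed distance gives the
exhaustive ROC curve against the shared-annotation gold standard; the area
under the curve (trapezoidal rule) summarises overall accuracy, and the best
single threshold maximises the total true classification rate TCR = TPR + TNR.
Per-clade precision/recall/F1 summarise how well one clade is captured at a
fixed threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import PairAdjacency, Partition
from .scores import DistanceMatrix

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "confusion_at_threshold",
    "roc_curve",
    "clade_prf",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class RocCurve:
    """Threshold sweep with rates, trapezoidal AUC and the TCR-optimal point."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    tnr: np.ndarray
    tcr: np.ndarray
    auc: float
    best_threshold: float
    best_tcr: float


def _pair_distances(dist: DistanceMatrix, adj: PairAdjacency) -> tuple[np.ndarray, np.ndarray]:
    """Observed distances split into positive (same-clade) and negative pairs."""
    common = [e for e in dist.ids if e in set(adj.ids)]
    if not common:
        raise ValueError("no shared entities between distances and annotation")
    di = {e: k for k, e in enumerate(dist.ids)}
    ai = {e: k for k, e in enumerate(adj.ids)}
    rows_d = np.array([di[e] for e in common])
    rows_a = np.array([ai[e] for e in common])
    sub_d = dist.values[np.ix_(rows_d, rows_d)]
    sub_o = dist.observed[np.ix_(rows_d, rows_d)]
    sub_a = adj.values[np.ix_(rows_a, rows_a)]
    iu, ju = np.triu_indices(len(common), k=1)
    keep = sub_o[iu, ju]
    d = sub_d[iu, ju][keep]
    pos = sub_a[iu, ju][keep]
    return d[pos], d[~pos]


def confusion_at_threshold(dist: DistanceMatrix, adj: PairAdjacency, t: float) -> ConfusionCounts:
    """Counts over unordered annotated pairs; predicted positive iff d <= t."""
    pos_d, neg_d = _pair_distances(dist, adj)
    tp = int(np.count_nonzero(pos_d <= t))
    fp = int(np.count_nonzero(neg_d <= t))
    return ConfusionCounts(tp=tp, fp=fp, tn=neg_d.size - fp, fn=pos_d.size - tp)


def roc_curve(dist: DistanceMatrix, adj: PairAdjacency) -> RocCurve:
    """Exhaustive ROC: one threshold per unique observed distance.

    A sentinel below the minimum distance anchors the curve at (0, 0); the
    maximum distance predicts every pair positive, anchoring (1, 1).  AUC is
    the trapezoidal integral of TPR over FPR; ``best_threshold`` is the
    smallest threshold attaining the maximal TCR.
    """
    pos_d, neg_d = _pair_distances(dist, adj)
    if pos_d.size == 0 or neg_d.size == 0:
        raise ValueError("need at least one positive and one negative pair")
    uniq = np.unique(np.concatenate([pos_d, neg_d]))
    thresholds = np.concatenate([[uniq[0] - 1.0], uniq])
    pos_sorted = np.sort(pos_d)
    neg_sorted = np.sort(neg_d)
    tp = np.searchsorted(pos_sorted, thresholds, side="right")
    fp = np.searchsorted(neg_sorted, thresholds, side="right")
    tpr = tp / pos_d.size
    fpr = fp / neg_d.size
    tnr = 1.0 - fpr
    tcr = tpr + tnr
    auc = float(np.trapezoid(tpr, fpr))
    # smallest OBSERVED distance achieving the maximal TCR; the sub-minimum
    # sentinel (TCR = 1 by construction) is never selected as a threshold.
    # Ties are exact in integer arithmetic: TCR ∝ tp*|neg| + tn*|pos|.
    tcr_exact = tp * neg_d.size + (neg_d.size - fp) * pos_d.size
    best = 1 + int(np.argmax(tcr_exact[1:]))
    return RocCurve(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        tnr=tnr,
        tcr=tcr,
        auc=auc,
        best_threshold=float(thresholds[best]),
        best_tcr=float(tcr[best]),
    )


def clade_prf(
    dist: DistanceMatrix, partition: Partition, clade: str, t: float
) -> tuple[float, float, float]:
    """Precision, recall and F1 for one clade at threshold t.

    The pair universe is every observed pair with at least one member in the
    clade.  Within-clade pairs at distance <= t are true positives, those
    beyond t false negatives; mixed pairs (exactly one endpoint in the
    clade) at distance <= t are false positives.  Precision defaults to 1
    when nothing is predicted; F1 is 0 when precision + recall is 0.
    """
    members = partition.clusters.get(clade)
    if members is None:
        raise KeyError(f"unknown clade {clade!r}")
    di = {e: k for k, e in enumerate(dist.ids)}
    inside = sorted(members & di.keys())
    if len(inside) < 2:
        raise ValueError(f"clade {clade!r} has fewer than two members with distances")
    outside = sorted((partition.universe & di.keys()) - members)
    in_idx = np.array([di[e] for e in inside])
    out_idx = np.array([di[e] for e in outside], dtype=int)

    iu, ju = np.triu_indices(len(inside), k=1)
    w_obs = dist.observed[in_idx[iu], in_idx[ju]]
    w_d = dist.values[in_idx[iu], in_idx[ju]][w_obs]
    tp = int(np.count_nonzero(w_d <= t))
    fn = w_d.size - tp

    fp = 0
    if out_idx.size:
        m_obs = dist.observed[np.ix_(in_idx, out_idx)]
        m_d = dist.values[np.ix_(in_idx, out_idx)][m_obs]
        fp = int(np.count_nonzero(m_d <= t))

    precision = tp / (tp + fp) if tp + fp > 0 else 1.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1
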