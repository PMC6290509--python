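"""Evaluation metrics for imbalanced binary probability predictions.

Average Precision (AP) is the mean, over positives in descending-score
order, of the precision at each positive's rank.  Tied scores are treated
as an exchangeable block: the reported AP is the expectation over uniformly
random orderings of each block, computed in closed form (for a block of
``m`` items with ``k`` positives preceded by ``A`` items of which ``P``
positive, the positive occupying in-block rank ``i`` contributes
``(k/m) * (P + 1 + (i-1)(k-1)/(m-1)) / (A + i)``).

AUROC is the Mann-Whitney probability that a random positive outscores a
random negative, ties counted half, computed from average ranks.

The interpolated precision-recall curve follows the information-retrieval
convention: ``p_interp(r) = max over points with recall >= r of precision``,
which is non-increasing in recall by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError(f"scores and labels must be equal-length 1-d arrays "
                         f"({s.shape} vs {y.shape})")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return s, y.astype(int)


def average_precision(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AP with exchangeable-block tie handling (see module docstring)."""
    s, y = _check(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("average precision is undefined without positives")
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    total = 0.0
    a = 0        # items before current block
    p_prev = 0   # positives before current block
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j < n and s[j] == s[i]:
            j += 1
        m = j - i
        k = int(y[i:j].sum())
        if k:
            slope = (k - 1) / (m - 1) if m > 1 else 0.0
            for t in range(1, m + 1):
                total += (k / m) * (p_prev + 1 + (t - 1) * slope) / (a + t)
        a += m
        p_prev += k
        i = j
    return total / n_pos


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUROC with half-credit for ties."""
    s, y = _check(scores, labels)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(s, method="average")
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def brier(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mean squared difference between predicted probability and outcome."""
    s, y = _check(scores, labels)
    if ((s < 0) | (s > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    return float(np.mean((s - y) ** 2))


@dataclass
class PRCurve:
    """Raw PR points (ascending recall) and their IR-style interpolation."""

    points: list  # (recall, precision, threshold)

    def interpolated_precision(self, recall: float) -> float:
        vals = [p for r, p, _ in self.points if r >= recall - 1e-12]
        return max(vals) if vals else 0.0


def interpolated_pr(scores: Sequence[float], labels: Sequence[int]) -> PRCurve:
    """PR points at every distinct threshold, plus max-over-higher-recall
    interpolation."""
    s, y = _check(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("PR curve is undefined without positives")
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    tp = np.cumsum(y)
    n = len(s)
    # block ends = last index of each distinct score
    ends = np.flatnonzero(np.diff(s) != 0)
    ends = np.append(ends, n - 1)
    points = []
    for e in ends:
        k = e + 1
        points.append((float(tp[e] / n_pos), float(tp[e] / k), float(s[e])))
    points.sort(key=lambda p: (p[0], -p[1]))
    return PRCurve(points)


def recall_at_precision(pr: PRCurve, target: float = 0.9) -> float:
    """Largest recall whose interpolated precision meets ``target``; 0 if none."""
    if not 0.0 < target <= 1.0:
        raise ValueError("target precision must be in (0, 1]")
    feasible = [r for r, _, _ in pr.points if pr.interpolated_precision(r) >= target]
    return max(feasible) if feasible else 0.0


@dataclass
class ReliabilityBins:
    """Equal-width right-closed calibration bins on [0, 1].

    Empty bins are kept (count 0, NaN summaries) so they are flagged rather
    than silently dropped.
    """

    edges: np.ndarray
    mean_predicted: np.ndarray
    observed_fraction: np.ndarray
    counts: np.ndarray

    def max_discrepancy(self) -> float:
        occ = self.counts > 0
        if not occ.any():
            return float("nan")
        return float(np.max(np.abs(self.mean_predicted[occ]
                                   - self.observed_fraction[occ])))


def reliability_curve(scores: Sequence[float], labels: Sequence[int],
                      n_bins: int = 10) -> ReliabilityBins:
    s, y = _check(scores, labels)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(s) and ((s < 0) | (s > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-closed bins (lo, hi]; scores of exactly 0 go to the first bin
    ix = np.ceil(s * n_bins).astype(int) - 1
    ix = np.clip(ix, 0, n_bins - 1)
    counts = np.bincount(ix, minlength=n_bins)
    sums = np.bincount(ix, weights=s, minlength=n_bins)
    pos = np.bincount(ix, weights=y, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_pred = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        frac = np.where(counts > 0, pos / np.maximum(counts, 1), np.nan)
    return ReliabilityBins(edges, mean_pred, frac, counts)


@dataclass
class EvaluationReport:
    """All scalar metrics plus the PR curve and reliability bins."""

    ap: float
    auroc: float
    brier: float
    recall_at_precision: Mapping[float, float]
    pr: PRCurve
    reliability: ReliabilityBins
    n: int = 0
    prevalence: float = float("nan")

    def to_dict(self) -> dict:
        rel = self.reliability
        return {
            "n": self.n,
            "prevalence": self.prevalence,
            "ap": self.ap,
            "auroc": self.auroc,
            "brier": self.brier,
            "recall_at_precision": {str(k): v
                                    for k, v in self.recall_at_precision.items()},
            "pr_points": [list(p) for p in self.pr.points],
            "reliability": {
                "edges": rel.edges.tolist(),
                "mean_predicted": [None if math.isnan(v) else v
                                   for v in rel.mean_predicted],
                "observed_fraction": [None if math.isnan(v) else v
                                      for v in rel.observed_fraction],
                "counts": rel.counts.tolist(),
            },
        }


def evaluate(scores: Sequence[float], labels: Sequence[int],
             precision_targets: Sequence[float] = (0.9,),
             n_bins: int = 10) -> EvaluationReport:
    """Compute the full evaluation report on one score/label set."""
    s, y = _check(scores, labels)
    pr = interpolated_pr(s, y)
    return EvaluationReport(
        ap=average_precision(s, y),
        auroc=auroc(s, y),
        brier=brier(s, y),
        recall_at_precision={t: recall_at_precision(pr, t) for t in precision_targets},
        pr=pr,
        reliability=reliability_curve(s, y, n_bins),
        n=len(s),
        prevalence=float(y.mean()),
    )
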