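"""Nucleus-based detection scoring.

A detected cell counts as correct when its centroid can be paired one-to-one
with a ground-truth centroid at Euclidean distance below the cell radius R.
With N_g truth cells, N_d detections and N_m matched pairs:

    recall = N_m / N_g        precision = N_m / N_d
    F = 2 * P * R / (P + R)   (harmonic mean)

Pairing uses minimum-cost maximum-cardinality assignment with the distance
cutoff, so the matching is deterministic and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist


@dataclass
class EvalScores:
    """Per-image counts and rates (fractions in [0, 1])."""

    n_truth: int
    n_detected: int
    n_matched: int
    recall: float
    precision: float
    f_score: float

    def as_percent(self) -> dict[str, float]:
        return {
            "recall": 100 * self.recall,
            "precision": 100 * self.precision,
            "f_score": 100 * self.f_score,
        }


def match_centroids(
    pred: np.ndarray, truth: np.ndarray, radius: float
) -> list[tuple[int, int]]:
    """Maximum one-to-one matching of pred to truth within ``radius``.

    Among maximum-cardinality matchings the one of minimum total distance is
    returned, as (pred_index, truth_index) pairs.  Pairs at distance >=
    ``radius`` are never matched.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pred = np.asarray(pred, dtype=np.float64).reshape(-1, 2)
    truth = np.asarray(truth, dtype=np.float64).reshape(-1, 2)
    if len(pred) == 0 or len(truth) == 0:
        return []
    dist = cdist(pred, truth)
    # a forbidden pair costs more than every admissible matching combined,
    # so minimizing total cost maximizes the number of admissible pairs
    big = radius * (len(pred) + len(truth) + 1)
    cost = np.where(dist < radius, dist, big)
    ri, ci = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(ri, ci) if dist[i, j] < radius]


def score(n_matched: int, n_truth: int, n_detected: int) -> EvalScores:
    """Recall/precision/F from match counts; requires ground truth."""
    if n_truth <= 0:
        raise ValueError("no ground-truth cells (N_g = 0)")
    if not n_matched <= min(n_truth, max(n_detected, 0)):
        raise ValueError("matched count exceeds side cardinality")
    recall = n_matched / n_truth
    precision = n_matched / n_detected if n_detected > 0 else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return EvalScores(
        n_truth=n_truth,
        n_detected=n_detected,
        n_matched=n_matched,
        recall=recall,
        precision=precision,
        f_score=f,
    )


def evaluate_detection(
    pred: np.ndarray, truth: np.ndarray, radius: float
) -> EvalScores:
    """Match and score one image in a single call."""
    matches = match_centroids(pred, truth, radius)
    return score(len(matches), len(np.atleast_2d(truth)), len(np.atleast_2d(pred)))


def aggregate(per_image: list[EvalScores]) -> pd.DataFrame:
    """Unweighted mean and sample (n-1) standard deviation per metric.

    Returns a frame indexed by metric with columns ``mean`` and ``sd``
    (fractions); a single image has sd 0.
    """
    if not per_image:
        raise ValueError("no scores to aggregate")
    data = {
        "recall": [s.recall for s in per_image],
        "precision": [s.precision for s in per_image],
        "f_score": [s.f_score for s in per_image],
    }
    rows = {}
    for metric, vals in data.items():
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        rows[metric] = {"mean": float(arr.mean()), "sd": sd}
    return pd.DataFrame(rows).T[["mean", "sd"]]


def radius_in_pixels(
    radius_um: float, pixel_size_um: tuple[float, float] | None
) -> float:
    """Convert a matching radius in micrometers to pixels.

    Uses the geometric mean of the (possibly anisotropic) pixel pitch; when
    no pixel size is known the caller must supply a pixel radius directly.
    """
    if pixel_size_um is None:
        raise ValueError("image has no pixel size; pass a pixel radius instead")
    return radius_um / float(np.sqrt(pixel_size_um[0] * pixel_size_um[1]))


def scores_table(per_image: list[EvalScores]) -> str:
    """Pretty text table: one row per image plus the mean +/- sd row."""
    lines = [f"{'image':>6} {'recall':>8} {'precision':>10} {'F-score':>8}"]
    for i, s in enumerate(per_image, start=1):
        p = s.as_percent()
        lines.append(
            f"{i:>6} {p['recall']:>8.1f} {p['precision']:>10.1f} {p['f_score']:>8.1f}"
        )
    agg = aggregate(per_image)
    lines.append(
        f"{'mu+/-sd':>6} "
        f"{100 * agg.loc['recall', 'mean']:.1f}+/-{100 * agg.loc['recall', 'sd']:.1f} "
        f"{100 * agg.loc['precision', 'mean']:.1f}+/-{100 * agg.loc['precision', 'sd']:.1f} "
        f"{100 * agg.loc['f_score', 'mean']:.1f}+/-{100 * agg.loc['f_score', 'sd']:.1f}"
    )
    return "\n".join(lines)
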