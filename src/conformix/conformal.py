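"""Split conformal calibration of quantile-regression intervals.

The raw network intervals [q_lo(x), q_hi(x)] carry no finite-sample
guarantee. Split conformal prediction restores one: hold out a calibration
set, score each calibration point by how far it falls outside (or inside)
its interval,

    E_i = max(q_lo(X_i) - y_i,  y_i - q_hi(X_i)),

take Q = the ceil((1 - alpha/2) * (n + 1))-th smallest score (capped at the
maximum when that rank exceeds n), and widen every interval by Q on both
sides. Under exchangeability of calibration and test samples the resulting
interval contains the true value with probability at least 1 - alpha,
distribution-free. The quantile level uses alpha/2 because the target is one
coordinate of a two-class composition (malignant vs normal), following the
multivariate quantile-regression convention.

Intervals are clipped to [0, 1] by default -- fractions are proportions --
which never reduces coverage of a value in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bulk import BulkDataset


@dataclass
class ConformalCalibration:
    """Conformity scores on the calibration split and their adjusted quantile."""

    scores: np.ndarray
    adjustment: float
    alpha: float

    @property
    def n_calib(self) -> int:
        return len(self.scores)


def split_train_calib(data: BulkDataset, train_frac: float = 0.7,
                      seed: int | None = None) -> tuple[BulkDataset, BulkDataset]:
    """Randomly partition samples into training and calibration subsets
    (round(n * train_frac) rows in the training part)."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    n = data.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(round(n * train_frac))
    if n_train == 0 or n_train == n:
        raise ValueError("split would leave one part empty")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tr, ca = perm[:n_train], perm[n_train:]

    def take(rows):
        return BulkDataset(
            expression=data.expression[rows],
            fractions=None if data.fractions is None else data.fractions[rows],
            subject_id=data.subject_id,
            gene_ids=data.gene_ids.copy(),
            cells_per_sample=data.cells_per_sample,
        )

    return take(tr), take(ca)


def conformity_scores(q_lo, q_hi, y) -> np.ndarray:
    """E_i = max(q_lo_i - y_i, y_i - q_hi_i): negative strictly inside the
    interval, positive outside."""
    q_lo = np.asarray(q_lo, dtype=float)
    q_hi = np.asarray(q_hi, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (q_lo.shape == q_hi.shape == y.shape):
        raise ValueError("q_lo, q_hi and y must have equal lengths")
    return np.maximum(q_lo - y, y - q_hi)


def conformal_quantile(scores, alpha: float) -> float:
    """The finite-sample-corrected (1 - alpha/2)(1 + 1/n)-th empirical
    quantile of the scores: the k-th smallest with
    k = ceil((1 - alpha/2) * (n + 1)), capped at the maximum."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("scores must be nonempty")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    n = scores.size
    k = math.ceil((1.0 - alpha / 2.0) * (n + 1))
    srt = np.sort(scores)
    if k > n:
        return float(srt[-1])
    return float(srt[k - 1])


def calibrate(q_lo, q_hi, y, alpha: float) -> ConformalCalibration:
    """Score a calibration set and compute its conformal adjustment."""
    scores = conformity_scores(q_lo, q_hi, y)
    return ConformalCalibration(scores=scores,
                                adjustment=conformal_quantile(scores, alpha),
                                alpha=alpha)


def conformalize(q_lo, q_hi, Q: float, clip: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Widen intervals by Q on both sides; clip to [0, 1] by default."""
    q_lo = np.asarray(q_lo, dtype=float)
    q_hi = np.asarray(q_hi, dtype=float)
    if (q_lo > q_hi).any():
        raise ValueError("q_lo must be <= q_hi elementwise")
    lower = q_lo - Q
    upper = q_hi + Q
    if clip:
        lower = np.clip(lower, 0.0, 1.0)
        upper = np.clip(upper, 0.0, 1.0)
    return lower, upper
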