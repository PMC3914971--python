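"""Cosine-nearness nearest-neighbor classification, jackknife CV, and metrics.

The classifier assigns a query the label of the training sample with minimal
*nearness*, defined as one minus the cosine of the angle between the two
copy-number vectors (so nearness 0 means parallel, 1 orthogonal, 2
anti-parallel).  Performance is evaluated by jackknife (leave-one-out)
cross-validation: each sample is predicted by the classifier trained on all
the other samples, and the resulting confusion counts yield sensitivity,
specificity, accuracy and the Matthews correlation coefficient.

Conventions: ACA is the positive class (sensitivity = ACA recall), ties in
nearness are broken by training-sample order, and MCC is defined as 0 when
any factor of its denominator is 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import CNAMatrix


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies from one jackknife pass (positive class = ACA)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PerformanceMetrics:
    """Sensitivity, specificity, accuracy and MCC of a binary classifier."""

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float

    def rounded(self, ndigits: int = 4) -> "PerformanceMetrics":
        """Display rounding (the conventional 4-decimal reporting format)."""
        return PerformanceMetrics(
            *(round(v, ndigits) for v in
              (self.sensitivity, self.specificity, self.accuracy, self.mcc))
        )


# ---------------------------------------------------------------------------
# Nearness and prediction
# ---------------------------------------------------------------------------

def nearness(x: Sequence[float], y: Sequence[float]) -> float:
    """1 - cos(x, y): 0 for parallel vectors, up to 2 for anti-parallel.

    Undefined (raises) for a zero-modulus vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must have equal length, got {x.shape} vs {y.shape}")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("nearness is undefined for a zero-modulus vector")
    # clamp float round-off to the mathematical range of 1 - cos
    return float(min(max(1.0 - np.dot(x, y) / (nx * ny), 0.0), 2.0))


def predict(
    train: CNAMatrix,
    query: Sequence[float],
    probe_subset: Sequence[str] | None = None,
) -> str:
    """Label of the training sample nearest to *query* (first minimum wins)."""
    X = train.subset(probe_subset) if probe_subset is not None else train.values
    q = np.asarray(query, dtype=float)
    if q.ndim != 1 or q.shape[0] != X.shape[1]:
        raise ValueError(
            f"query length {q.shape} does not match feature count {X.shape[1]}"
        )
    if X.shape[0] == 0:
        raise ValueError("training set is empty")
    qn = np.linalg.norm(q)
    if qn == 0:
        raise ValueError("nearness is undefined for a zero-modulus query")
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = int(np.argmin(norms))
        raise ValueError(
            f"training sample {train.sample_ids[bad]!r} has zero modulus "
            "on the selected probes"
        )
    near = 1.0 - (X @ q) / (norms * qn)
    return str(train.labels[int(np.argmin(near))])


# ---------------------------------------------------------------------------
# Jackknife (leave-one-out) cross-validation
# ---------------------------------------------------------------------------

def loocv(matrix: CNAMatrix, probe_subset: Sequence[str] | None = None) -> ConfusionCounts:
    """One nearest-neighbor prediction per sample, that sample held out.

    Vectorized over samples via the cosine-similarity matrix; the diagonal is
    masked so no sample can be its own neighbor.  Ties in nearness break by
    training-sample order, matching :func:`predict`.
    """
    y = matrix.y
    if not y.any() or not (~y).any():
        raise ValueError("jackknife evaluation requires samples from both classes")
    if y.sum() < 2 or (~y).sum() < 2:
        warnings.warn(
            "a class has fewer than 2 samples; its member(s) can never have "
            "a same-class neighbor under leave-one-out",
            stacklevel=2,
        )
    X = matrix.subset(probe_subset) if probe_subset is not None else matrix.values
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = int(np.argmin(norms))
        raise ValueError(
            f"sample {matrix.sample_ids[bad]!r} has zero modulus on the "
            "selected probes; nearness is undefined"
        )
    cos = (X @ X.T) / np.outer(norms, norms)
    np.fill_diagonal(cos, -np.inf)  # exclude self from training
    neighbor = np.argmax(cos, axis=1)  # first max = smallest nearness, first wins
    pred_pos = y[neighbor]

    tp = int(np.sum(pred_pos & y))
    tn = int(np.sum(~pred_pos & ~y))
    fp = int(np.sum(pred_pos & ~y))
    fn = int(np.sum(~pred_pos & y))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def metrics(c: ConfusionCounts) -> PerformanceMetrics:
    """Sensitivity, specificity, accuracy, MCC from confusion counts.

    MCC is 0 by convention whenever any of its four denominator factors is 0
    (e.g. a degenerate predictor that assigns every sample to one class).
    """
    if c.total == 0:
        raise ValueError("metrics are undefined for zero evaluated samples")
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    acc = (c.tp + c.tn) / c.total
    factors = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if factors == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(factors)
    return PerformanceMetrics(sensitivity=sn, specificity=sp, accuracy=acc, mcc=mcc)
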