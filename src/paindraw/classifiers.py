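"""Profile-similarity classifiers and nearest-neighbor baselines.

Two classifiers operate on pain profiles:

* the *k-disease* classifier assigns a drawing to the group whose profile
  has the highest Ružička similarity to it;
* the *binary* classifier normalizes the two similarities to sum to 1 and
  thresholds the positive-group score (default cut-off 0.5).

Two baselines operate drawing-vs-drawing: a 1-nearest-neighbor classifier
under Ružička (= Jaccard for binary vectors) similarity, and a kernel
1-nearest-neighbor classifier under the kernel-induced distance.

Ties are broken deterministically by canonical class / training order and
flagged, so downstream confusion counts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .drawing_io import Cohort, EmptyDrawingError, PainDrawing
from .profile import PainProfile
from .similarity import (
    SimilarityVector,
    UndefinedSimilarityError,
    kernel_distance,
    median_pairwise_distance,
    ruzicka,
    similarity_vector,
)

__all__ = [
    "Prediction",
    "classify_k",
    "classify_binary",
    "classify_nn",
    "classify_kernel_nn",
]

_TIE_RTOL = 0.0  # exact ties only; scores are ratios of exact sums


@dataclass(frozen=True)
class Prediction:
    subject_id: str
    predicted: str
    scores: SimilarityVector | None  # profile classifiers
    tie_flag: bool = False
    neighbor_id: str | None = None  # NN classifiers: winning training drawing
    score: float | None = None  # binary classifier: normalized positive score


def _require_nonempty(drawing: PainDrawing) -> None:
    if drawing.is_empty:
        raise EmptyDrawingError(
            f"drawing {drawing.subject_id!r} is empty and cannot be classified"
        )


def classify_k(
    profiles: Sequence[PainProfile], drawing: PainDrawing
) -> Prediction:
    """Assign the drawing to the profile with the highest Ružička similarity.

    Ties go to the earliest profile in the given order, with ``tie_flag``.
    """
    sims = similarity_vector(profiles, drawing)
    raw = sims.raw
    best = int(np.argmax(raw))
    tie = int((raw == raw[best]).sum()) > 1
    return Prediction(
        subject_id=drawing.subject_id,
        predicted=sims.class_order[best],
        scores=sims,
        tie_flag=tie,
    )


def classify_binary(
    profile_a: PainProfile,
    profile_b: PainProfile,
    drawing: PainDrawing,
    threshold: float = 0.5,
) -> Prediction:
    """Threshold the normalized similarity to ``profile_a`` (the positive class).

    The score is s_a = S(a, y) / (S(a, y) + S(b, y)); the drawing is assigned
    to ``profile_a`` iff s_a >= threshold.  The score is retained on the
    prediction for ROC construction.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    _require_nonempty(drawing)
    sims = similarity_vector([profile_a, profile_b], drawing)
    if sims.is_degenerate:
        raise UndefinedSimilarityError(
            f"drawing {drawing.subject_id!r}: both similarities are zero"
        )
    s_a = float(sims.normalized[0])
    predicted = profile_a.label if s_a >= threshold else profile_b.label
    return Prediction(
        subject_id=drawing.subject_id,
        predicted=predicted,
        scores=sims,
        tie_flag=(s_a == threshold),
        score=s_a,
    )


def classify_nn(train: Cohort, drawing: PainDrawing) -> Prediction:
    """1-nearest-neighbor under Ružička similarity, drawing vs drawing."""
    _require_nonempty(drawing)
    sims = np.array(
        [
            0.0 if t.is_empty else ruzicka(t.y, drawing.y)
            for t in train.drawings
        ]
    )
    best = int(np.argmax(sims))
    tie = int((sims == sims[best]).sum()) > 1
    winner = train.drawings[best]
    return Prediction(
        subject_id=drawing.subject_id,
        predicted=winner.label,
        scores=None,
        tie_flag=tie,
        neighbor_id=winner.subject_id,
    )


def classify_kernel_nn(
    train: Cohort,
    drawing: PainDrawing,
    kind: str = "gaussian",
    sigma: float | None = None,
) -> Prediction:
    """1-nearest-neighbor under the kernel-induced distance.

    d_K(x, y) = sqrt(K(x,x) - 2 K(x,y) + K(y,y)).  For the Gaussian kernel
    this distance is monotone in the Euclidean distance, so predictions
    coincide with plain Euclidean 1-NN.  When ``sigma`` is omitted for the
    Gaussian kernel, the median pairwise training distance is used (median
    heuristic).
    """
    _require_nonempty(drawing)
    if kind == "gaussian" and sigma is None:
        sigma = median_pairwise_distance([t.y for t in train.drawings])
    dists = np.array(
        [kernel_distance(kind, t.y, drawing.y, sigma) for t in train.drawings]
    )
    best = int(np.argmin(dists))
    tie = int((dists == dists[best]).sum()) > 1
    winner = train.drawings[best]
    return Prediction(
        subject_id=drawing.subject_id,
        predicted=winner.label,
        scores=None,
        tie_flag=tie,
        neighbor_id=winner.subject_id,
    )
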