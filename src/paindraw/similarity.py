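"""Ružička similarity and the kernels used by the comparison classifiers.

The Ružička (min–max, weighted-Jaccard) similarity between a pain profile
``x`` and a drawing ``y`` is

    S(x, y) = sum_i min(x_i, y_i) / sum_i max(x_i, y_i)

over the m inside-body pixels.  For two binary vectors it reduces to the
Jaccard index of the marked sets.  Per-class similarities are optionally
normalized to sum to 1, which is the score the binary classifier thresholds
and the ROC analysis uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .drawing_io import EmptyDrawingError, PainDrawing
from .profile import PainProfile

__all__ = [
    "UndefinedSimilarityError",
    "SimilarityVector",
    "ruzicka",
    "kernel_value",
    "kernel_distance",
    "median_pairwise_distance",
    "similarity_vector",
]


class UndefinedSimilarityError(ZeroDivisionError):
    """Both vectors are all-zero: min/max ratio is 0/0."""


def ruzicka(x: np.ndarray, y: np.ndarray) -> float:
    """Min–max similarity ``sum(min)/sum(max)`` of two non-negative vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    denom = np.maximum(x, y).sum()
    if denom == 0:
        raise UndefinedSimilarityError("both vectors are all-zero")
    return float(np.minimum(x, y).sum() / denom)


def kernel_value(kind: str, x: np.ndarray, y: np.ndarray, sigma: float | None = None) -> float:
    """Kernel between two drawings' binary pixel vectors.

    ``gaussian``: exp(-||x-y||^2 / (2 sigma^2)) with bandwidth sigma > 0.
    ``inverse``: 1 / (1 + ||x-y||), this package's choice of a
    distance-reciprocal comparison kernel ("inverse kernel" has no single
    canonical definition; this form is documented here so results are
    reproducible).  Distances are Euclidean over the m inside-mask pixels, so for binary
    vectors ||x-y||^2 equals the Hamming distance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    d = float(np.linalg.norm(x - y))
    if kind == "gaussian":
        if sigma is None or sigma <= 0:
            raise ValueError("gaussian kernel requires bandwidth sigma > 0")
        return float(np.exp(-(d * d) / (2.0 * sigma * sigma)))
    if kind == "inverse":
        return 1.0 / (1.0 + d)
    raise ValueError(f"unknown kernel kind {kind!r}")


def kernel_distance(kind: str, x: np.ndarray, y: np.ndarray, sigma: float | None = None) -> float:
    """Kernel-induced distance ``sqrt(K(x,x) - 2 K(x,y) + K(y,y))``."""
    kxx = kernel_value(kind, x, x, sigma)
    kyy = kernel_value(kind, y, y, sigma)
    kxy = kernel_value(kind, x, y, sigma)
    return float(np.sqrt(max(kxx - 2.0 * kxy + kyy, 0.0)))


def median_pairwise_distance(vectors: Sequence[np.ndarray]) -> float:
    """Median Euclidean distance over all training pairs (bandwidth heuristic)."""
    arr = np.asarray([np.asarray(v, dtype=float) for v in vectors])
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least two vectors for the median heuristic")
    sq = ((arr[:, None, :] - arr[None, :, :]) ** 2).sum(-1)
    d = np.sqrt(sq[np.triu_indices(n, k=1)])
    med = float(np.median(d))
    return med if med > 0 else 1.0


@dataclass(frozen=True)
class SimilarityVector:
    """Raw and sum-normalized Ružička similarities of one drawing to k profiles."""

    class_order: tuple[str, ...]
    raw: np.ndarray
    normalized: np.ndarray | None  # None when all raw similarities are zero

    @property
    def is_degenerate(self) -> bool:
        return self.normalized is None

    def as_dict(self, normalized: bool = False) -> dict[str, float]:
        vals = self.normalized if normalized else self.raw
        if vals is None:
            raise UndefinedSimilarityError("normalization undefined: all raw are 0")
        return dict(zip(self.class_order, map(float, vals)))


def similarity_vector(
    profiles: Sequence[PainProfile], drawing: PainDrawing
) -> SimilarityVector:
    """Ružička similarity of one drawing to each profile, plus normalization.

    Normalized similarities divide the raw vector by its sum so the scores
    across the diagnostic groups sum to 1; if every raw similarity is zero
    the normalization is undefined and flagged (``normalized is None``).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    if drawing.is_empty:
        raise EmptyDrawingError(
            f"drawing {drawing.subject_id!r} is empty and cannot be scored"
        )
    raw = np.array([ruzicka(p.x, drawing.y) for p in profiles])
    total = raw.sum()
    normalized = raw / total if total > 0 else None
    return SimilarityVector(
        class_order=tuple(p.label for p in profiles), raw=raw, normalized=normalized
    )
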