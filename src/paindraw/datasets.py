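"""Worked-example evaluation data.

Leave-one-out cross-validated confusion matrices from a published clinical
pain-drawing cohort of four rare diseases — Ehlers-Danlos syndrome (EDS),
Guillain–Barré syndrome (GBS), facioscapulohumeral muscular dystrophy
(FSHD), proximal myotonic myopathy (PROMM) — and an unspecific chronic-pain
control group (CP); 59 + 29 + 35 + 89 + 50 = 262 drawings in total.  The
raw drawings are not public, so these matrices are the reference inputs for
the evaluation-only operations (confusion summaries and better-than-random
tests) and for the worked examples in the documentation.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix

__all__ = [
    "CLASS_ORDER",
    "rare_vs_cp_confusion",
    "binary_tasks",
    "binary_task_confusion",
    "five_group_confusion",
]

CLASS_ORDER = ("EDS", "GBS", "FSHD", "PROMM", "CP")


def rare_vs_cp_confusion() -> ConfusionMatrix:
    """2x2 matrix of the pooled rare-disease group (RARE) vs CP, threshold 0.5.

    212 rare-disease drawings (59 EDS + 29 GBS + 35 FSHD + 89 PROMM) against
    50 chronic-pain drawings; rows are the true group, columns the
    prediction.
    """
    return ConfusionMatrix(
        class_order=("RARE", "CP"),
        counts=np.array([[200, 12], [29, 21]]),
    )


def binary_tasks() -> dict[str, dict[str, int]]:
    """Per-disease binary tasks vs CP: TP / FP / FN / TN counts.

    The disease is the positive class; CP is the negative class.
    """
    return {
        "EDS": {"tp": 58, "fp": 35, "fn": 1, "tn": 15},
        "GBS": {"tp": 28, "fp": 17, "fn": 1, "tn": 33},
        "FSHD": {"tp": 34, "fp": 32, "fn": 1, "tn": 18},
        "PROMM": {"tp": 80, "fp": 24, "fn": 9, "tn": 26},
    }


def binary_task_confusion(disease: str) -> ConfusionMatrix:
    """2x2 confusion matrix of one disease-vs-CP binary task."""
    t = binary_tasks()[disease]
    return ConfusionMatrix(
        class_order=(disease, "CP"),
        counts=np.array([[t["tp"], t["fn"]], [t["fp"], t["tn"]]]),
    )


def five_group_confusion() -> ConfusionMatrix:
    """5x5 matrix of the k-disease classifier over all 262 drawings.

    Rows: true class; columns: predicted class, both in
    (EDS, GBS, FSHD, PROMM, CP) order.  Row sums are the class sizes
    (59, 29, 35, 89, 50); column sums are (61, 69, 60, 62, 10).
    """
    counts = np.array(
        [
            [38, 11, 8, 1, 1],
            [1, 25, 0, 3, 0],
            [4, 3, 22, 5, 1],
            [5, 20, 17, 46, 1],
            [13, 10, 13, 7, 7],
        ]
    )
    return ConfusionMatrix(class_order=CLASS_ORDER, counts=counts)
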