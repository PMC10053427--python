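"""Evaluation: leave-one-out cross-validation, confusion-matrix summaries,
ROC/AUC with DeLong confidence intervals and Youden thresholds, and
Fisher / chi-square better-than-random tests.

The LOOCV protocol rebuilds only the left-out drawing's own (possibly
pooled) group profile from the remaining members of that group; every other
group keeps its full membership.  This is the standard leakage-free
protocol for per-group reference profiles: the held-out drawing never
contributes to the profile it is scored against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .drawing_io import Cohort
from .similarity import ruzicka

__all__ = [
    "ConfusionMatrix",
    "ConfusionSummary",
    "RocResult",
    "EvaluationReport",
    "KDiseaseScheme",
    "BinaryScheme",
    "NearestNeighborScheme",
    "KernelNearestNeighborScheme",
    "loocv",
    "summarize_confusion",
    "roc_auc",
    "best_threshold_youden",
    "fisher_exact_2x2",
    "chi2_independence",
    "Chi2Result",
    "plot_roc",
]


# ---------------------------------------------------------------------------
# Confusion matrices


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k counts; rows = true class, columns = predicted class."""

    class_order: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.class_order)
        if counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_records(
        cls, true: Sequence[str], predicted: Sequence[str], class_order: Sequence[str]
    ) -> "ConfusionMatrix":
        order = tuple(class_order)
        idx = {c: i for i, c in enumerate(order)}
        counts = np.zeros((len(order), len(order)), dtype=np.int64)
        for t, p in zip(true, predicted, strict=True):
            counts[idx[t], idx[p]] += 1
        return cls(class_order=order, counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class ConfusionSummary:
    class_order: tuple[str, ...]
    sensitivity: dict[str, float]  # NaN where a true class has zero members
    specificity: dict[str, float]
    accuracy: float
    undefined: tuple[str, ...] = ()  # classes with zero row (no true members)


def summarize_confusion(cm: ConfusionMatrix) -> ConfusionSummary:
    """Per-class sensitivity and specificity plus overall accuracy.

    sensitivity_c = cm[c,c] / (true c);  specificity_c = true negatives for c
    divided by (total - true c); accuracy = trace / total.  Rates are kept at
    full precision — rounding belongs to presentation, not computation.
    """
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    diag = np.diag(counts)
    sens: dict[str, float] = {}
    spec: dict[str, float] = {}
    undefined: list[str] = []
    for i, c in enumerate(cm.class_order):
        if rows[i] == 0:
            sens[c] = float("nan")
            undefined.append(c)
        else:
            sens[c] = float(diag[i] / rows[i])
        neg = total - rows[i]
        fp = cols[i] - diag[i]
        spec[c] = float((neg - fp) / neg) if neg > 0 else float("nan")
    return ConfusionSummary(
        class_order=cm.class_order,
        sensitivity=sens,
        specificity=spec,
        accuracy=float(diag.sum() / total),
        undefined=tuple(undefined),
    )


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC of a score with the '>= cut-off -> positive' rule.

    ``thresholds`` are the distinct observed scores in ascending order, so
    sensitivity is non-increasing along the array.  ``auc`` is the
    trapezoidal area, identical to the Mann-Whitney probability with ties
    counted 1/2; ``auc_ci`` is the 95 % DeLong interval.  ``sens_band``
    (optional) holds per-threshold stratified-bootstrap 2.5/97.5 percentiles
    of sensitivity.
    """

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    best_threshold: float
    sens_band: np.ndarray | None = None  # shape (2, n_thresholds): low, high


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via the midrank formulation."""
    m, n = pos.size, neg.size
    tz = _midranks(np.concatenate([pos, neg]))
    tx = _midranks(pos)
    ty = _midranks(neg)
    v10 = (tz[:m] - tx) / n  # placement of each positive among negatives
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return auc, float(s10 / m + s01 / n)


def roc_auc(
    scores: np.ndarray,
    truth: np.ndarray,
    n_boot: int = 0,
    seed: int = 0,
    ci_level: float = 0.95,
) -> RocResult:
    """Empirical ROC/AUC of ``scores`` against binary ``truth`` (1 = positive).

    Cut-offs run over all distinct scores; a sample is predicted positive iff
    its score is >= the cut-off.  The AUC confidence interval uses the
    DeLong variance with a normal approximation, clipped to [0, 1]; with
    ``n_boot`` > 0 a per-threshold sensitivity band is added by stratified
    bootstrap (resampling positives and negatives separately).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must align")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    pos = scores[truth]
    neg = scores[~truth]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")

    thresholds = np.unique(scores)  # ascending
    sens = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] < thresholds[:, None]).mean(axis=1)

    auc, var = _delong_variance(pos, neg)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    half = z * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    j = sens + spec - 1.0
    best = float(thresholds[int(np.argmax(j))])  # first max = smallest cut-off

    band = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, thresholds.size))
        for b in range(n_boot):
            p = rng.choice(pos, size=pos.size, replace=True)
            boot[b] = (p[None, :] >= thresholds[:, None]).mean(axis=1)
        band = np.percentile(boot, [2.5, 97.5], axis=0)

    return RocResult(
        thresholds=thresholds,
        sens=sens,
        spec=spec,
        auc=auc,
        auc_ci=ci,
        best_threshold=best,
        sens_band=band,
    )


def best_threshold_youden(roc: RocResult) -> float:
    """Cut-off maximizing the Youden index J = sens + spec - 1 (ties: smallest)."""
    j = roc.sens + roc.spec - 1.0
    return float(roc.thresholds[int(np.argmax(j))])


# ---------------------------------------------------------------------------
# Better-than-random tests


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table (zero margin -> p = 1)."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any() or table.sum() == 0:
        raise ValueError("table must be non-negative with positive total")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    pvalue: float
    low_expected: bool  # any expected count < 5 (approximation warning)
    dropped: tuple[str, ...] = ()  # labels of all-zero rows/columns removed


def chi2_independence(
    table: np.ndarray, labels: Sequence[str] | None = None
) -> Chi2Result:
    """Pearson chi-square test of independence (no continuity correction).

    All-zero rows/columns are dropped (with their labels recorded) before
    testing; degrees of freedom are (r-1)(c-1) on the reduced table.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.sum() <= 0:
        raise ValueError("table total must be positive")
    labels = list(labels) if labels is not None else [str(i) for i in range(max(table.shape))]
    rows_ok = table.sum(axis=1) > 0
    cols_ok = table.sum(axis=0) > 0
    dropped = tuple(
        lab
        for lab, r, c in zip(labels, rows_ok, cols_ok)
        if not (r and c)
    ) if table.shape[0] == table.shape[1] else ()
    reduced = table[np.ix_(rows_ok, cols_ok)]
    if reduced.shape[0] < 2 or reduced.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping empty margins")
    res = stats.chi2_contingency(reduced, correction=False)
    return Chi2Result(
        statistic=float(res.statistic),
        df=int(res.dof),
        pvalue=float(res.pvalue),
        low_expected=bool((res.expected_freq < 5).any()),
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# LOOCV schemes


@dataclass(frozen=True)
class KDiseaseScheme:
    """One profile per class; assign to the most similar profile."""


@dataclass(frozen=True)
class BinaryScheme:
    """Two (possibly pooled) profiles; threshold the normalized positive score."""

    positive_members: tuple[str, ...]
    negative_members: tuple[str, ...]
    positive_label: str = "POS"
    negative_label: str = "NEG"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "positive_members", tuple(self.positive_members))
        object.__setattr__(self, "negative_members", tuple(self.negative_members))
        if set(self.positive_members) & set(self.negative_members):
            raise ValueError("positive and negative members overlap")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")


@dataclass(frozen=True)
class NearestNeighborScheme:
    """1-NN under Ružička (Jaccard) similarity, drawing vs drawing."""


@dataclass(frozen=True)
class KernelNearestNeighborScheme:
    """1-NN under the kernel-induced distance.

    For both supported kernels (gaussian, inverse) the induced distance is a
    strictly increasing function of the Euclidean distance, so predictions
    reduce to Euclidean 1-NN; the scheme is kept distinct so reports name
    the classifier that was requested.
    """

    kind: str = "gaussian"
    sigma: float | None = None


Scheme = KDiseaseScheme | BinaryScheme | NearestNeighborScheme | KernelNearestNeighborScheme


@dataclass(frozen=True)
class EvaluationReport:
    scheme: str
    confusion: ConfusionMatrix
    summary: ConfusionSummary
    tests: dict[str, float]
    predictions: pd.DataFrame
    roc: RocResult | None = None
    params: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return self.summary.accuracy

    def to_json_dict(self) -> dict:
        out = {
            "scheme": self.scheme,
            "params": self.params,
            "class_order": list(self.confusion.class_order),
            "confusion": self.confusion.counts.tolist(),
            "accuracy": self.summary.accuracy,
            "sensitivity": self.summary.sensitivity,
            "specificity": self.summary.specificity,
            "tests": self.tests,
        }
        if self.roc is not None:
            out["roc"] = {
                "auc": self.roc.auc,
                "auc_ci": list(self.roc.auc_ci),
                "best_threshold": self.roc.best_threshold,
            }
        return out

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(), indent=1))


# ---------------------------------------------------------------------------
# LOOCV core


def _check_no_empty(cohort: Cohort) -> None:
    empty = [d.subject_id for d in cohort.drawings if d.is_empty]
    if empty:
        raise ValueError(f"cohort contains empty drawings: {empty}")


def _loocv_profile(
    cohort: Cohort, groups: Mapping[str, Sequence[str]]
) -> tuple[list[str], list[str], np.ndarray, list[bool]]:
    """Shared LOOCV loop for profile-based schemes.

    ``groups`` maps group label -> member class labels.  Returns true group,
    raw similarity matrix (n_drawings x n_groups), and tie flags.  The
    left-out drawing's own group profile is rebuilt from the remaining
    members; other groups keep full membership.
    """
    _check_no_empty(cohort)
    label_to_group: dict[str, str] = {}
    for g, members in groups.items():
        for c in members:
            if c not in cohort.classes:
                raise ValueError(f"group {g!r} references unknown class {c!r}")
            if c in label_to_group:
                raise ValueError(f"class {c!r} assigned to two groups")
            label_to_group[c] = g
    uncovered = set(cohort.classes) - set(label_to_group)
    if uncovered:
        raise ValueError(
            f"classes {sorted(uncovered)} belong to no group; restrict the "
            "cohort or extend the scheme"
        )

    group_order = list(groups)
    y = np.stack([d.y for d in cohort.drawings]).astype(np.float64)
    member_idx = {
        g: [i for i, d in enumerate(cohort.drawings) if label_to_group[d.label] == g]
        for g in group_order
    }
    for g, idx in member_idx.items():
        if len(idx) < 2:
            raise ValueError(
                f"group {g!r} has {len(idx)} drawing(s); LOOCV needs >= 2"
            )
    counts = {g: y[idx].sum(axis=0) for g, idx in member_idx.items()}
    sizes = {g: len(idx) for g, idx in member_idx.items()}

    n = len(cohort.drawings)
    raw = np.zeros((n, len(group_order)))
    true_groups: list[str] = []
    for i, d in enumerate(cohort.drawings):
        own = label_to_group[d.label]
        true_groups.append(own)
        for j, g in enumerate(group_order):
            if g == own:
                prof = (counts[g] - d.y) / (sizes[g] - 1)
            else:
                prof = counts[g] / sizes[g]
            raw[i, j] = ruzicka(prof, d.y)
    subject_ids = [d.subject_id for d in cohort.drawings]
    ties = [(row == row.max()).sum() > 1 for row in raw]
    return subject_ids, true_groups, raw, ties


def _nn_similarity_matrix(cohort: Cohort) -> np.ndarray:
    """Pairwise Jaccard similarity between all drawings."""
    y = np.stack([d.y for d in cohort.drawings]).astype(np.float64)
    inter = y @ y.T
    sums = y.sum(axis=1)
    union = sums[:, None] + sums[None, :] - inter
    with np.errstate(invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), np.nan)
    return sim


def loocv(
    cohort: Cohort,
    scheme: Scheme,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvaluationReport:
    """Leave-one-out cross-validation of a classification scheme.

    Every drawing is classified with its own group's profile rebuilt from
    the remaining drawings of that group (profile schemes), or against all
    other drawings (nearest-neighbor schemes).  Returns the confusion
    matrix, per-class rates, a better-than-random test (Fisher exact for
    binary, chi-square otherwise) and, for the binary scheme, the ROC of
    the normalized positive scores with DeLong CI, Youden threshold and a
    seeded stratified-bootstrap sensitivity band.
    """
    if isinstance(scheme, KDiseaseScheme):
        groups = {c: [c] for c in cohort.classes}
        subj, true, raw, ties = _loocv_profile(cohort, groups)
        order = tuple(groups)
        norm_sum = raw.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(norm_sum > 0, raw / norm_sum, np.nan)
        pred = [order[int(np.argmax(row))] for row in raw]
        cm = ConfusionMatrix.from_records(true, pred, order)
        chi = chi2_independence(cm.counts, labels=order)
        tests = {"chi2_statistic": chi.statistic, "chi2_p": chi.pvalue}
        table = pd.DataFrame(
            {"subject_id": subj, "true": true, "predicted": pred, "tie_flag": ties}
        )
        for j, g in enumerate(order):
            table[f"raw_{g}"] = raw[:, j]
            table[f"norm_{g}"] = norm[:, j]
        return EvaluationReport(
            scheme="k_disease",
            confusion=cm,
            summary=summarize_confusion(cm),
            tests=tests,
            predictions=table,
        )

    if isinstance(scheme, BinaryScheme):
        groups = {
            scheme.positive_label: list(scheme.positive_members),
            scheme.negative_label: list(scheme.negative_members),
        }
        subj, true, raw, _ = _loocv_profile(cohort, groups)
        order = (scheme.positive_label, scheme.negative_label)
        totals = raw.sum(axis=1)
        if (totals == 0).any():
            bad = [s for s, t in zip(subj, totals) if t == 0]
            raise ValueError(f"undefined normalized score for drawings: {bad}")
        s_pos = raw[:, 0] / totals
        pred = [
            order[0] if s >= scheme.threshold else order[1] for s in s_pos
        ]
        cm = ConfusionMatrix.from_records(true, pred, order)
        truth = np.array([t == order[0] for t in true])
        roc = roc_auc(s_pos, truth, n_boot=n_boot, seed=seed)
        tests = {"fisher_p": fisher_exact_2x2(cm.counts)}
        table = pd.DataFrame(
            {
                "subject_id": subj,
                "true": true,
                "predicted": pred,
                "tie_flag": [s == scheme.threshold for s in s_pos],
                "score_positive": s_pos,
                "raw_positive": raw[:, 0],
                "raw_negative": raw[:, 1],
            }
        )
        return EvaluationReport(
            scheme="binary",
            confusion=cm,
            summary=summarize_confusion(cm),
            tests=tests,
            predictions=table,
            roc=roc,
            params={
                "threshold": scheme.threshold,
                "positive": scheme.positive_label,
                "positive_members": list(scheme.positive_members),
                "negative": scheme.negative_label,
                "negative_members": list(scheme.negative_members),
            },
        )

    if isinstance(scheme, (NearestNeighborScheme, KernelNearestNeighborScheme)):
        _check_no_empty(cohort)
        if len(cohort.drawings) < 2:
            raise ValueError("LOOCV with a nearest-neighbor scheme needs >= 2 drawings")
        if isinstance(scheme, KernelNearestNeighborScheme):
            if scheme.kind not in ("gaussian", "inverse"):
                raise ValueError(f"unknown kernel kind {scheme.kind!r}")
            if scheme.kind == "gaussian" and scheme.sigma is not None and scheme.sigma <= 0:
                raise ValueError("gaussian kernel requires sigma > 0")
            # Both kernel-induced distances are strictly increasing in the
            # Euclidean distance, so 1-NN reduces to Euclidean 1-NN.
            y = np.stack([d.y for d in cohort.drawings]).astype(np.float64)
            inter = y @ y.T
            sums = y.sum(axis=1)
            d2 = sums[:, None] + sums[None, :] - 2 * inter  # Hamming = squared L2
            score = -d2  # larger is closer
            name = "kernel_nn"
            params = {"kind": scheme.kind, "sigma": scheme.sigma}
        else:
            score = _nn_similarity_matrix(cohort)
            name = "nn"
            params = {}
        np.fill_diagonal(score, -np.inf)
        best = np.argmax(score, axis=1)
        ties = [
            (row == row[b]).sum() > 1 for row, b in zip(score, best)
        ]
        pred = [cohort.drawings[int(b)].label for b in best]
        neighbor = [cohort.drawings[int(b)].subject_id for b in best]
        true = [d.label for d in cohort.drawings]
        cm = ConfusionMatrix.from_records(true, pred, cohort.classes)
        if len(cohort.classes) == 2:
            tests = {"fisher_p": fisher_exact_2x2(cm.counts)}
        else:
            chi = chi2_independence(cm.counts, labels=cohort.classes)
            tests = {"chi2_statistic": chi.statistic, "chi2_p": chi.pvalue}
        table = pd.DataFrame(
            {
                "subject_id": [d.subject_id for d in cohort.drawings],
                "true": true,
                "predicted": pred,
                "tie_flag": ties,
                "neighbor_id": neighbor,
            }
        )
        return EvaluationReport(
            scheme=name,
            confusion=cm,
            summary=summarize_confusion(cm),
            tests=tests,
            predictions=table,
            params=params,
        )

    raise TypeError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Plotting


def plot_roc(roc: RocResult, path: str | Path, title: str = "ROC") -> None:
    """ROC curve with the bootstrap sensitivity band and Youden crosshair."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fpr = 1.0 - roc.spec
    order = np.argsort(fpr, kind="stable")
    fig, ax = plt.subplots(figsize=(5, 5))
    if roc.sens_band is not None:
        ax.fill_between(
            fpr[order], roc.sens_band[0][order], roc.sens_band[1][order],
            color="lightblue", alpha=0.6, label="95% sensitivity band",
        )
    ax.plot(fpr[order], roc.sens[order], color="black", lw=1.5)
    ax.plot([0, 1], [0, 1], ls="--", color="gray", lw=0.8)
    i = int(np.argmin(np.abs(roc.thresholds - roc.best_threshold)))
    ax.axvline(1 - roc.spec[i], color="tab:blue", lw=0.8)
    ax.axhline(roc.sens[i], color="tab:blue", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(
        f"{title}  AUC = {roc.auc:.3f} "
        f"(CI {roc.auc_ci[0]:.3f}-{roc.auc_ci[1]:.3f}), "
        f"best threshold {roc.best_threshold:.2f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
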