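"""Single-gene biomarker evaluation: ROC curves, AUC, cutoffs, confusion.

A candidate biomarker is treated as a binary ETP vs non-ETP classifier on
its expression values. Genes elevated in ETP use direction
``HIGH_IN_ETP``; genes depressed in ETP (CDH2 is the canonical case) use
``LOW_IN_ETP``, which negates scores before the ROC so that the AUC and the
confusion-matrix annotation flip together. AUC equals the probability that
a random ETP sample outscores a random non-ETP sample, ties half-credited.
Cutoffs are chosen by Youden's J (TPR - FPR) over midpoints between
adjacent distinct scores; closest-to-(0,1) selection is available as an
alternative. Confusion matrices are reported as percentages of each truth
class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics

from .cohort import CohortLabels
from .errors import DataFormatError

HIGH_IN_ETP = "HIGH_IN_ETP"
LOW_IN_ETP = "LOW_IN_ETP"
Direction = Literal["HIGH_IN_ETP", "LOW_IN_ETP"]


def _check_classes(truth: np.ndarray) -> None:
    if truth.all() or not truth.any():
        raise DataFormatError(
            "both classes must be present (got a single-class truth vector)"
        )


def _aligned(scores: np.ndarray, direction: Direction) -> np.ndarray:
    if direction == HIGH_IN_ETP:
        return scores
    if direction == LOW_IN_ETP:
        return -scores
    raise DataFormatError(f"unknown direction {direction!r}")


def auc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """Area under the ROC curve of ``scores`` against binary ``truth``.

    Equals the normalized rank-sum statistic: the fraction of
    (positive, negative) pairs where the positive outscores the negative,
    ties counting one half.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise DataFormatError("scores and truth differ in length")
    _check_classes(truth)
    return float(metrics.roc_auc_score(truth, scores))


def roc_curve(
    scores: Sequence[float],
    truth: Sequence[bool],
    direction: Direction = HIGH_IN_ETP,
) -> np.ndarray:
    """Ordered (FPR, TPR) points from (0, 0) to (1, 1).

    ``LOW_IN_ETP`` negates scores first, so an anti-marker yields the same
    curve as the negated marker.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    _check_classes(truth)
    s = _aligned(scores, direction)
    fpr, tpr, _ = metrics.roc_curve(truth, s, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def optimal_cutoff(
    scores: Sequence[float],
    truth: Sequence[bool],
    direction: Direction = HIGH_IN_ETP,
    rule: Literal["youden", "closest01"] = "youden",
) -> float:
    """Cutoff maximizing Youden's J over midpoints of adjacent distinct
    scores (or minimizing distance to the (0, 1) ROC corner).

    Predictions call ETP when the direction-aligned score strictly exceeds
    the aligned cutoff. Ties prefer the lower aligned cutoff. The returned
    cutoff is on the original expression scale (negated back for
    ``LOW_IN_ETP``).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    _check_classes(truth)
    s = _aligned(scores, direction)
    distinct = np.unique(s)
    if distinct.size < 2:
        best = float(distinct[0])
        return best if direction == HIGH_IN_ETP else -best
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n_pos = truth.sum()
    n_neg = (~truth).sum()
    best_mid, best_obj = None, None
    for c in mids:
        pred = s > c
        tpr = (pred & truth).sum() / n_pos
        fpr = (pred & ~truth).sum() / n_neg
        if rule == "youden":
            obj = tpr - fpr
        elif rule == "closest01":
            obj = -np.hypot(fpr, 1.0 - tpr)
        else:
            raise DataFormatError(f"unknown cutoff rule {rule!r}")
        if best_obj is None or obj > best_obj:  # ties keep the lower cutoff
            best_mid, best_obj = float(c), obj
    return best_mid if direction == HIGH_IN_ETP else -best_mid


@dataclass(frozen=True)
class ClassifierEval:
    """Per-gene classifier summary in the confusion-matrix convention of
    percentage-of-truth-class rows (TP + FN = 100, FP + TN = 100)."""

    gene: str
    direction: Direction
    auc: float
    cutoff: float
    tp_pct: float
    fn_pct: float
    fp_pct: float
    tn_pct: float


def evaluate_biomarker(
    expr: pd.DataFrame,
    labels: CohortLabels,
    gene: str,
    direction: Direction | None = None,
    rule: Literal["youden", "closest01"] = "youden",
) -> ClassifierEval:
    """ROC evaluation of one gene as an ETP / non-ETP classifier.

    ``direction=None`` infers the direction from the group means (higher
    ETP mean -> ``HIGH_IN_ETP``); the AUC is computed on direction-aligned
    scores, so an informative anti-marker still scores above 0.5.
    """
    gene = str(gene).upper()
    if gene not in expr.index:
        raise DataFormatError(f"gene {gene!r} not in matrix")
    labels.require_two_groups(min_per_group=1)
    samples = [s for s in expr.columns if s in labels.assignment]
    scores = expr.loc[gene, samples].to_numpy(float)
    truth = np.array(
        [labels.assignment[s] == "ETP" for s in samples], dtype=bool
    )
    _check_classes(truth)
    if direction is None:
        direction = (
            HIGH_IN_ETP
            if scores[truth].mean() >= scores[~truth].mean()
            else LOW_IN_ETP
        )
    s = _aligned(scores, direction)
    auc_val = auc(s, truth)
    cutoff = optimal_cutoff(scores, truth, direction=direction, rule=rule)
    c_aligned = cutoff if direction == HIGH_IN_ETP else -cutoff
    pred = s > c_aligned
    n_pos = truth.sum()
    n_neg = (~truth).sum()
    tp = (pred & truth).sum() / n_pos * 100.0
    fp = (pred & ~truth).sum() / n_neg * 100.0
    return ClassifierEval(
        gene=gene,
        direction=direction,
        auc=auc_val,
        cutoff=float(cutoff),
        tp_pct=float(tp),
        fn_pct=float(100.0 - tp),
        fp_pct=float(fp),
        tn_pct=float(100.0 - fp),
    )


def evaluation_table(evals: Sequence[ClassifierEval]) -> pd.DataFrame:
    """Stack ClassifierEval records into a gene-indexed DataFrame."""
    return pd.DataFrame(
        [
            {
                "gene": e.gene,
                "direction": e.direction,
                "auc": e.auc,
                "cutoff": e.cutoff,
                "tp_pct": e.tp_pct,
                "fn_pct": e.fn_pct,
                "fp_pct": e.fp_pct,
                "tn_pct": e.tn_pct,
            }
            for e in evals
        ]
    ).set_index("gene")
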