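"""Diagnostic accuracy of crowd grades against expert labels, plus task economics.

Accuracy is reported at two levels:

* **individual** — every grading instance (one rater, one image) is scored
  against the expert grade;
* **consensus** — the aggregated per-image grade is scored.

Percent-correct compares grades exactly on the working scale; sensitivity and
specificity always collapse every disease grade to "abnormal" first (normal
versus any disease level).  An image with no strict mode counts as incorrect
for percent-correct but is recoded as abnormal for sensitivity/specificity —
the conservative screening interpretation of an unresolved crowd.

The ROC area is the tie-corrected Mann–Whitney statistic: the probability
that a randomly chosen abnormal image scores higher than a randomly chosen
normal one, with half-credit for ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_model import (
    NO_CONSENSUS,
    ConsensusTable,
    EconomicsConfig,
    ExpertLabels,
    FOUR_CAT,
    RatingTable,
)
from .exceptions import (
    AlignmentError,
    DomainError,
    EmptyInputError,
    UndefinedAUCError,
)

__all__ = [
    "DiagSummary",
    "binarize",
    "round_half_up",
    "consensus_accuracy",
    "individual_accuracy",
    "auc_mann_whitney",
    "severity_contrast_auc",
    "hourly_wage",
    "cost_per_image",
]

NORMAL, ABNORMAL = 0, 1


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as in the published tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def binarize(grade: Union[int, object]) -> int:
    """Collapse a grade to normal (0) / abnormal (1).

    Any disease grade (> 0) is abnormal; a NO_CONSENSUS sentinel is recoded
    as abnormal, so an unresolved crowd never produces a false negative.
    """
    if grade is NO_CONSENSUS or (grade is not None and pd.isna(grade)):
        return ABNORMAL
    return NORMAL if int(grade) == 0 else ABNORMAL


@dataclass(frozen=True)
class DiagSummary:
    """Confusion counts and derived accuracy metrics at one analysis level."""

    tp: int
    fp: int
    tn: int
    fn: int
    percent_correct: float  # proportion in [0, 1], exact-grade agreement
    n: int
    level: str  # 'individual' or 'consensus'

    @property
    def sensitivity(self) -> float:
        """NaN when the truth contains no abnormal unit."""
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        """NaN when the truth contains no normal unit."""
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    def report(self) -> dict:
        """Percentages rounded to one decimal (half-up), as reported."""
        return {
            "level": self.level,
            "n": self.n,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "percent_correct": round_half_up(100 * self.percent_correct, 1),
            "sensitivity": (None if np.isnan(self.sensitivity)
                            else round_half_up(100 * self.sensitivity, 1)),
            "specificity": (None if np.isnan(self.specificity)
                            else round_half_up(100 * self.specificity, 1)),
        }


def _confusion(pred_bin: np.ndarray, truth_bin: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((pred_bin == 1) & (truth_bin == 1)))
    fp = int(np.sum((pred_bin == 1) & (truth_bin == 0)))
    tn = int(np.sum((pred_bin == 0) & (truth_bin == 0)))
    fn = int(np.sum((pred_bin == 0) & (truth_bin == 1)))
    return tp, fp, tn, fn


def consensus_accuracy(
    consensus: ConsensusTable,
    experts: ExpertLabels,
    exact_level: bool = True,
) -> DiagSummary:
    """Score per-image consensus grades against expert grades.

    ``exact_level=True`` counts an image correct only when the consensus code
    equals the expert code on the consensus table's scale (NO_CONSENSUS is
    always incorrect); ``False`` scores agreement after binarization.
    Sensitivity/specificity are always computed on binarized grades, with
    NO_CONSENSUS recoded as abnormal.
    """
    cset, eset = set(consensus.image_ids), set(experts.image_ids)
    if cset != eset:
        diff = sorted(cset.symmetric_difference(eset))
        raise AlignmentError(f"image sets differ; symmetric difference: {diff}")
    images = consensus.image_ids
    expert = experts.grades(consensus.scale).loc[images].to_numpy()
    raw = consensus.df.loc[images, "consensus_grade"]
    pred_bin = np.array([binarize(g) for g in raw])
    truth_bin = (expert > 0).astype(int)
    if exact_level:
        correct = (raw.to_numpy() == expert)  # NA compares False
        correct = np.asarray([bool(c) and not pd.isna(r)
                              for c, r in zip(correct, raw)])
    else:
        correct = pred_bin == truth_bin
    tp, fp, tn, fn = _confusion(pred_bin, truth_bin)
    return DiagSummary(tp, fp, tn, fn, float(correct.mean()), len(images),
                       "consensus")


def individual_accuracy(table: RatingTable, experts: ExpertLabels) -> DiagSummary:
    """Score every grading instance against the expert grade for its image."""
    if len(table) == 0:
        raise EmptyInputError("rating table is empty")
    unknown = set(table.image_ids) - set(experts.image_ids)
    if unknown:
        raise AlignmentError(f"ratings for unknown image(s): {sorted(unknown)}")
    expert = experts.grades(table.scale).loc[table.df["image_id"]].to_numpy()
    pred = table.df["grade"].to_numpy()
    pred_bin = (pred > 0).astype(int)
    truth_bin = (expert > 0).astype(int)
    tp, fp, tn, fn = _confusion(pred_bin, truth_bin)
    return DiagSummary(tp, fp, tn, fn, float((pred == expert).mean()),
                       len(table), "individual")


def auc_mann_whitney(
    scores: Sequence[float], truth: Sequence[int]
) -> float:
    """Tie-corrected ROC area via the Mann–Whitney U statistic.

    Equals the fraction of (abnormal, normal) image pairs in which the
    abnormal image scores strictly higher, counting tied pairs as half;
    identical to the trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape:
        raise DomainError("scores and truth must have the same length")
    n_pos = int(truth.sum())
    n_neg = int(len(truth) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(
            f"AUC undefined: {n_pos} abnormal and {n_neg} normal images"
        )
    ranks = rankdata(scores)  # average ranks: half-credit for ties
    u = ranks[truth == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def severity_contrast_auc(
    scores: Mapping[str, float],
    experts: ExpertLabels,
    severity: int,
) -> float:
    """ROC area for normal versus one disease severity level.

    Restricts the image set to expert-normal images plus images of the given
    severity on the four-category scale, scoring each image by its crowd mean.
    """
    FOUR_CAT.validate_grade(severity)
    if severity == 0:
        raise DomainError("severity must be a disease grade (> 0)")
    g4 = experts.grades(FOUR_CAT)
    keep = [img for img in experts.image_ids if g4[img] in (0, severity)]
    missing = [img for img in keep if img not in scores]
    if missing:
        raise AlignmentError(f"no crowd score for image(s): {missing}")
    s = [scores[img] for img in keep]
    t = [1 if g4[img] == severity else 0 for img in keep]
    return auc_mann_whitney(s, t)


def hourly_wage(pay_per_rating: float, mean_duration_s: float) -> float:
    """Effective worker wage in USD/hour, rounded half-up to cents.

    Uses the payment to the worker only; the platform commission is a cost to
    the requester, not income to the rater.
    """
    if mean_duration_s <= 0:
        raise DomainError("mean_duration_s must be positive")
    return round_half_up(3600.0 * pay_per_rating / mean_duration_s, 2)


def cost_per_image(cfg: EconomicsConfig) -> float:
    """Requester cost per image in USD, commission included."""
    return round_half_up(
        cfg.raters_per_image * cfg.pay_per_rating * (1.0 + cfg.commission_rate), 2
    )
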