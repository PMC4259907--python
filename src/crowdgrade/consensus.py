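"""Consensus aggregation of per-image ordinal grades.

Two aggregation rules are supported:

* **mean-threshold** — the arithmetic mean of the crowd's grades, binned to
  the nearest grade with half-integer cut points (0.5, 1.5, 2.5); a mean
  exactly on a cut point is assigned the higher (more severe) grade.
* **mode** — the most frequent grade.  When the top frequency is shared by
  several grades there is no unique mode: the *strict* policy reports
  NO_CONSENSUS (the bookkeeping used when tabulating percent-correct), while
  the *clinical* policy returns the most severe tied grade, the conservative
  choice for a screening instrument.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .data_model import (
    NO_CONSENSUS,
    ConsensusTable,
    GradingScale,
    RatingTable,
)
from .exceptions import DomainError, EmptyInputError

__all__ = ["mean_score", "mean_consensus", "mode_consensus", "build_consensus"]

logger = logging.getLogger(__name__)


def mean_score(grades: Sequence[int]) -> float:
    """Arithmetic mean of a non-empty collection of grade codes."""
    arr = np.asarray(list(grades), dtype=float)
    if arr.size == 0:
        raise EmptyInputError("mean_score of an empty grade list")
    return float(arr.mean())


def mean_consensus(mean: float, scale: GradingScale) -> int:
    """Bin a mean crowd score into a grade on ``scale``.

    The grade ``k`` covers the half-open interval ``[k - 0.5, k + 0.5)``; the
    top grade's interval is closed above at the maximum code.  Boundary values
    go to the higher bin (a mean of exactly 0.5 is abnormal).
    """
    if not (0.0 <= mean <= scale.max_code):
        raise DomainError(
            f"mean {mean!r} outside [0, {scale.max_code}] for scale {scale.name!r}"
        )
    return int(np.searchsorted(scale.bin_edges, mean, side="right"))


def mode_consensus(
    grades: Sequence[int], tie_policy: str = "strict"
) -> Union[int, object]:
    """Most frequent grade, with an explicit policy for tied top frequencies.

    strict
        a shared top frequency yields :data:`~crowdgrade.data_model.NO_CONSENSUS`.
    clinical
        the most severe of the tied grades is returned (a tie is escalated,
        never downgraded).
    """
    grades = list(grades)
    if not grades:
        raise EmptyInputError("mode_consensus of an empty grade list")
    if tie_policy not in ("strict", "clinical"):
        raise DomainError(f"unknown tie policy {tie_policy!r}")
    counts = Counter(int(g) for g in grades)
    top = max(counts.values())
    tied = sorted(g for g, c in counts.items() if c == top)
    if len(tied) == 1:
        return tied[0]
    return NO_CONSENSUS if tie_policy == "strict" else tied[-1]


def build_consensus(
    table: RatingTable,
    method: str = "mode",
    tie_policy: str = "strict",
) -> ConsensusTable:
    """Aggregate a rating table into one consensus grade per image.

    Deterministic given its inputs; one row per distinct ``image_id`` in
    first-appearance order, with the number of ratings aggregated.
    """
    if method not in ("mean", "mode"):
        raise DomainError(f"unknown consensus method {method!r}")
    rows = []
    for image_id, grades in table.grades_by_image().items():
        if grades.size == 0:  # pragma: no cover - groupby yields no empty groups
            logger.warning("image %s has no ratings; excluded", image_id)
            continue
        if method == "mean":
            grade: Union[int, object] = mean_consensus(
                mean_score(grades), table.scale
            )
        else:
            grade = mode_consensus(grades, tie_policy)
        rows.append(
            {
                "image_id": image_id,
                "consensus_grade": pd.NA if grade is NO_CONSENSUS else int(grade),
                "n_ratings": int(grades.size),
            }
        )
    if not rows:
        raise EmptyInputError("rating table contains no images")
    df = pd.DataFrame(rows)
    return ConsensusTable(table.scale, df, method, tie_policy)
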