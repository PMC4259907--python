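"""Accuracy as a function of crowd size, by repeated random sub-crowds.

Given a deep pool of ratings per image (hundreds of independent raters), the
experiment repeatedly draws random sub-crowds of size k without replacement,
scores each image by the sub-crowd's mean grade, and measures the ROC area of
those scores against the binarized expert labels.  Repeating over a grid of k
yields the accuracy-versus-crowd-size curve and its Monte-Carlo variance, from
which the *plateau* crowd size — the smallest crowd whose mean AUC is within a
tolerance of the best achieved at any size — is read off.

Randomness is counter-based: every (k, draw, image) triple gets its own RNG
substream derived from the master seed, so results do not depend on the order
in which the grid is traversed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import ExpertLabels, RatingTable
from .diagnostics import auc_mann_whitney
from .exceptions import (
    AlignmentError,
    EmptyInputError,
    SamplingError,
    UndefinedAUCError,
)

__all__ = ["CrowdCurveResult", "draw_subcrowd", "crowd_curve", "plateau_k"]


@dataclass
class CrowdCurveResult:
    """All draw-level AUCs over a grid of crowd sizes, plus summaries."""

    k_values: np.ndarray          # (n_k,)
    aucs: np.ndarray              # (n_k, n_draws)
    n_draws: int
    seed: int
    pool_depth: int

    @property
    def mean_auc(self) -> np.ndarray:
        return self.aucs.mean(axis=1)

    @property
    def var_auc(self) -> np.ndarray:
        return self.aucs.var(axis=1, ddof=1) if self.n_draws > 1 else \
            np.zeros(len(self.k_values))

    def draws_frame(self) -> pd.DataFrame:
        """Long format: one row per (k, draw_index)."""
        n_k, n_d = self.aucs.shape
        return pd.DataFrame({
            "k": np.repeat(self.k_values, n_d),
            "draw_index": np.tile(np.arange(n_d), n_k),
            "auc": self.aucs.ravel(),
        })

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k_values,
            "mean_auc": self.mean_auc,
            "var_auc": self.var_auc,
        })


def draw_subcrowd(
    pool: Sequence[int],
    k: int,
    rng: np.random.Generator,
    replace: bool = False,
) -> np.ndarray:
    """Sample a sub-crowd of k ratings from one image's pool.

    The pool is canonically sorted before a seeded shuffle, so the draw
    depends only on the pool's multiset of grades and the RNG state, never on
    input order.  Default is without replacement; ``replace=True`` gives a
    bootstrap draw instead.
    """
    pool = np.sort(np.asarray(pool))
    if k < 1:
        raise SamplingError(f"sub-crowd size must be >= 1, got {k}")
    if not replace and k > pool.size:
        raise SamplingError(
            f"cannot draw {k} distinct ratings from a pool of {pool.size}"
        )
    if replace:
        idx = rng.integers(0, pool.size, size=k)
    else:
        idx = rng.permutation(pool.size)[:k]
    return pool[idx]


def crowd_curve(
    table: RatingTable,
    experts: ExpertLabels,
    k_range: Iterable[int] = range(1, 51),
    n_draws: int = 50,
    seed: int = 0,
    replace: bool = False,
) -> CrowdCurveResult:
    """Mean-score AUC versus crowd size over repeated random sub-crowds.

    For every crowd size k and every draw, a sub-crowd of k ratings is drawn
    independently for each image; the image's score is the sub-crowd mean and
    the draw's AUC compares scores of expert-abnormal versus expert-normal
    images.  Each (k, draw, image) triple uses its own seed-derived RNG
    substream.
    """
    k_values = np.array(sorted(set(int(k) for k in k_range)))
    if k_values.size == 0:
        raise EmptyInputError("k_range is empty")
    pools = table.grades_by_image()
    images = list(pools)
    unknown = set(images) - set(experts.image_ids)
    if unknown:
        raise AlignmentError(f"ratings for unknown image(s): {sorted(unknown)}")
    depth = min(len(g) for g in pools.values())
    if not replace and k_values.max() > depth:
        shallow = next(img for img, g in pools.items()
                       if len(g) < k_values.max())
        raise SamplingError(
            f"image {shallow!r} has only {len(pools[shallow])} ratings; "
            f"max k requested is {k_values.max()}"
        )
    truth_bin = (experts.grades(table.scale).loc[images].to_numpy() > 0).astype(int)
    if truth_bin.min() == truth_bin.max():
        raise UndefinedAUCError("expert labels contain only one class")

    aucs = np.empty((k_values.size, n_draws))
    for ki, k in enumerate(k_values):
        for d in range(n_draws):
            scores = np.empty(len(images))
            for j, img in enumerate(images):
                rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(int(k), d, j))
                )
                scores[j] = draw_subcrowd(pools[img], int(k), rng,
                                          replace=replace).mean()
            aucs[ki, d] = auc_mann_whitney(scores, truth_bin)
    return CrowdCurveResult(
        k_values=k_values,
        aucs=aucs,
        n_draws=n_draws,
        seed=seed,
        pool_depth=depth,
    )


def plateau_k(result: CrowdCurveResult, tolerance: float = 0.01) -> int:
    """Smallest crowd size whose mean AUC is within ``tolerance`` of the best.

    A flat curve yields the smallest k; tolerance 0 yields the first k
    attaining the maximum.
    """
    if result.k_values.size == 0:
        raise EmptyInputError("empty crowd curve")
    mean = result.mean_auc
    cutoff = mean.max() - tolerance
    return int(result.k_values[np.flatnonzero(mean >= cutoff)[0]])
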