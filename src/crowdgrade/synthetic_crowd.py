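"""Simulated crowds of ordinal raters with known error structure.

Each simulated rater is an *archetype*: a row-stochastic confusion matrix over
the four-category scale (rows = true grade, columns = reported grade) plus a
log-normal per-rating duration model.  Crowds are mixtures of archetypes;
reported grades are drawn from the confusion row of each image's true
four-category grade and then projected onto the working scale (four→three:
mild and moderate merge; four→two: any disease grade becomes abnormal).

Builtin archetypes
------------------
``accurate``
    A conscientious rater: every diagonal entry is its row maximum, binary
    sensitivity 94% and specificity 70%, close to the observed marginal rates
    of real crowd workers on this task.
``moderate_biased``
    Pulls every abnormality toward grade 2 (moderate) and often misses mild
    disease — the dominant error pattern observed when untrained raters are
    asked to stage severity: moderate disease is resolved well, mild and
    severe poorly.
``severity_inflating``
    Systematically reports higher grades than the truth, the signature of the
    one outlying rater seen in practice.
``random_bot``
    Uniform responses over the options presented, regardless of the image,
    emulating a bot or spammer rapidly completing tasks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    ExpertLabels,
    FOUR_CAT,
    GradingScale,
    RatingTable,
    get_scale,
)
from .exceptions import SpecError, ValidationError

__all__ = [
    "RaterArchetype",
    "CrowdSpec",
    "builtin_archetypes",
    "project_grade",
    "simulate_crowd",
    "recover_confusion",
    "screen_outlier_raters",
    "prototype_truth",
    "calibrate_accuracy_weight",
    "phase2_spec",
]

#: Median task time of a genuine rater, seconds (two-category batches).
_RATER_MEDIAN_S = 25.16
#: Median task time of a bot, seconds.
_BOT_MEDIAN_S = 4.0


@dataclass(frozen=True)
class RaterArchetype:
    """A simulated rater type: confusion matrix plus duration model.

    ``uniform_over_scale=True`` marks a rater who clicks uniformly among the
    response options actually presented (a bot): on a two-category task such
    a rater answers normal/abnormal with probability ½ each, which no
    projection of a four-category confusion row can express.
    """

    name: str
    confusion: np.ndarray  # (4, 4), rows = true grade, cols = reported
    duration_log_mean: float = math.log(_RATER_MEDIAN_S)
    duration_log_sd: float = 0.35
    uniform_over_scale: bool = False

    def __post_init__(self) -> None:
        conf = np.asarray(self.confusion, dtype=float)
        if conf.shape != (4, 4):
            raise ValidationError(f"{self.name}: confusion matrix must be 4x4")
        if (conf < 0).any():
            raise ValidationError(f"{self.name}: negative confusion entries")
        if not np.allclose(conf.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError(f"{self.name}: confusion rows must sum to 1")
        if self.duration_log_sd < 0:
            raise ValidationError(f"{self.name}: duration_log_sd must be >= 0")
        object.__setattr__(self, "confusion", conf)

    def binary_accuracy(
        self,
        true_grades_4cat: Sequence[int],
        scale: GradingScale | None = None,
    ) -> float:
        """Expected normal/abnormal accuracy over a set of true grades.

        For ordinary archetypes this is scale-free (binarization commutes
        with scale projection); a uniform-over-scale rater's chance of
        reporting "normal" is 1/n_categories of the working ``scale``.
        """
        probs = []
        for g in true_grades_4cat:
            if self.uniform_over_scale:
                if scale is None:
                    raise ValidationError(
                        "binary accuracy of a uniform-over-scale rater "
                        "requires the working scale"
                    )
                p_normal = 1.0 / len(scale.codes)
            else:
                p_normal = self.confusion[int(g), 0]
            probs.append(p_normal if g == 0 else 1.0 - p_normal)
        return float(np.mean(probs))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "confusion": self.confusion.tolist(),
            "duration_log_mean": self.duration_log_mean,
            "duration_log_sd": self.duration_log_sd,
            "uniform_over_scale": self.uniform_over_scale,
        }


def builtin_archetypes() -> dict[str, RaterArchetype]:
    """The four documented rater archetypes, keyed by name."""
    return {
        "accurate": RaterArchetype(
            "accurate",
            np.array([
                [0.70, 0.15, 0.10, 0.05],
                [0.06, 0.55, 0.29, 0.10],
                [0.06, 0.12, 0.67, 0.15],
                [0.06, 0.09, 0.25, 0.60],
            ]),
        ),
        "moderate_biased": RaterArchetype(
            "moderate_biased",
            np.array([
                [0.60, 0.15, 0.20, 0.05],
                [0.30, 0.20, 0.45, 0.05],
                [0.04, 0.06, 0.82, 0.08],
                [0.03, 0.05, 0.62, 0.30],
            ]),
        ),
        "severity_inflating": RaterArchetype(
            "severity_inflating",
            np.array([
                [0.30, 0.20, 0.25, 0.25],
                [0.05, 0.15, 0.30, 0.50],
                [0.03, 0.07, 0.30, 0.60],
                [0.02, 0.03, 0.15, 0.80],
            ]),
        ),
        "random_bot": RaterArchetype(
            "random_bot",
            np.full((4, 4), 0.25),
            duration_log_mean=math.log(_BOT_MEDIAN_S),
            duration_log_sd=0.30,
            uniform_over_scale=True,
        ),
    }


_PROJECTION_3CAT = np.array([0, 1, 1, 2])
_PROJECTION_2CAT = np.array([0, 1, 1, 1])


def project_grade(grade: int, scale: GradingScale) -> int:
    """Project a four-category grade onto a coarser scale.

    four→three merges mild and moderate; four→two collapses every disease
    grade to abnormal; projection onto four_cat is the identity.
    """
    g = FOUR_CAT.validate_grade(grade)
    if scale.name == "four_cat":
        return g
    if scale.name == "three_cat":
        return int(_PROJECTION_3CAT[g])
    if scale.name == "two_cat":
        return int(_PROJECTION_2CAT[g])
    raise ValidationError(f"unknown scale {scale.name!r}")


def _project_array(grades: np.ndarray, scale: GradingScale) -> np.ndarray:
    if scale.name == "four_cat":
        return grades
    table = _PROJECTION_3CAT if scale.name == "three_cat" else _PROJECTION_2CAT
    return table[grades]


@dataclass(frozen=True)
class CrowdSpec:
    """Specification of a simulated crowd.

    ``shared_raters=True`` builds a persistent roster in which every rater
    grades every image (the regime of small posted batches, and what
    per-rater outlier screening assumes); ``False`` draws a fresh set of
    raters for each image (the regime of very deep per-image pools).
    """

    mixture: tuple[tuple[RaterArchetype, float], ...]
    n_raters_per_image: int
    scale: GradingScale
    seed: int
    shared_raters: bool = True

    def __post_init__(self) -> None:
        mixture = tuple((a, float(w)) for a, w in self.mixture)
        if not mixture:
            raise SpecError("mixture must contain at least one archetype")
        weights = np.array([w for _, w in mixture])
        if (weights < 0).any() or not math.isclose(weights.sum(), 1.0,
                                                   abs_tol=1e-9):
            raise SpecError("mixture weights must be non-negative and sum to 1")
        if self.n_raters_per_image < 1:
            raise SpecError("n_raters_per_image must be >= 1")
        object.__setattr__(self, "mixture", mixture)

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.mixture])

    @property
    def archetypes(self) -> list[RaterArchetype]:
        return [a for a, _ in self.mixture]

    def to_dict(self) -> dict:
        return {
            "mixture": [
                {"archetype": a.to_dict(), "weight": w} for a, w in self.mixture
            ],
            "n_raters_per_image": self.n_raters_per_image,
            "scale": self.scale.name,
            "seed": self.seed,
            "shared_raters": self.shared_raters,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CrowdSpec":
        builtins = builtin_archetypes()
        mixture = []
        try:
            for entry in d["mixture"]:
                a = entry["archetype"]
                if isinstance(a, str):
                    arch = builtins[a]
                else:
                    arch = RaterArchetype(
                        name=a["name"],
                        confusion=np.asarray(a["confusion"], dtype=float),
                        duration_log_mean=a.get("duration_log_mean",
                                                math.log(_RATER_MEDIAN_S)),
                        duration_log_sd=a.get("duration_log_sd", 0.35),
                        uniform_over_scale=a.get("uniform_over_scale", False),
                    )
                mixture.append((arch, float(entry["weight"])))
            return cls(
                mixture=tuple(mixture),
                n_raters_per_image=int(d["n_raters_per_image"]),
                scale=get_scale(d.get("scale", "four_cat")),
                seed=int(d["seed"]),
                shared_raters=bool(d.get("shared_raters", True)),
            )
        except KeyError as exc:
            raise SpecError(f"crowd spec missing key: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "CrowdSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sample_grades(rng: np.random.Generator, conf_rows: np.ndarray) -> np.ndarray:
    """Draw one categorical sample per row of a stack of probability rows."""
    cum = np.cumsum(conf_rows, axis=1)
    u = rng.random(len(conf_rows))
    return (u[:, None] >= cum).sum(axis=1)


def simulate_crowd(truth: ExpertLabels, spec: CrowdSpec) -> RatingTable:
    """Simulate a crowd rating every image in ``truth``.

    For each rater an archetype is drawn from the mixture; each reported
    grade is drawn from the archetype's confusion row for the image's true
    four-category grade and projected onto ``spec.scale``.  Durations are
    log-normal.  Output is fully reproducible from ``spec.seed`` and is
    emitted image-major in the truth table's image order.
    """
    if len(truth) == 0:
        raise SpecError("truth table is empty")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    images = truth.image_ids
    true4 = truth.grades(FOUR_CAT).loc[images].to_numpy()
    n = spec.n_raters_per_image
    archs = spec.archetypes
    confusions = np.stack([a.confusion for a in archs])

    n_codes = len(spec.scale.codes)
    uniform = np.array([a.uniform_over_scale for a in archs])

    if spec.shared_raters:
        # one archetype per rater, every rater grades every image
        a_idx = rng.choice(len(archs), size=n, p=spec.weights)
        grades = np.empty((len(images), n), dtype=int)
        durations = np.empty((len(images), n), dtype=float)
        for r in range(n):
            a = archs[a_idx[r]]
            if a.uniform_over_scale:
                grades[:, r] = rng.integers(0, n_codes, len(images))
            else:
                g4 = _sample_grades(rng, a.confusion[true4])
                grades[:, r] = _project_array(g4, spec.scale)
            durations[:, r] = rng.lognormal(a.duration_log_mean,
                                            a.duration_log_sd, len(images))
        rater_ids = [f"r{r:04d}" for r in range(n)]
        rows = {
            "image_id": np.repeat(images, n),
            "rater_id": rater_ids * len(images),
            "grade": grades.ravel(),
            "duration_s": durations.ravel(),
        }
    else:
        # a fresh anonymous pool per image (deep-pool regime)
        img_col, rater_col, grade_col, dur_col = [], [], [], []
        for j, img in enumerate(images):
            a_idx = rng.choice(len(archs), size=n, p=spec.weights)
            conf_rows = confusions[a_idx, true4[j], :]
            g = _project_array(_sample_grades(rng, conf_rows), spec.scale)
            bots = uniform[a_idx]
            if bots.any():
                g = g.copy()
                g[bots] = rng.integers(0, n_codes, int(bots.sum()))
            mus = np.array([archs[i].duration_log_mean for i in a_idx])
            sds = np.array([archs[i].duration_log_sd for i in a_idx])
            d = rng.lognormal(mus, sds)
            img_col.append(np.repeat(img, n))
            rater_col.extend(f"{img}_r{r:04d}" for r in range(n))
            grade_col.append(g)
            dur_col.append(d)
        rows = {
            "image_id": np.concatenate(img_col),
            "rater_id": rater_col,
            "grade": np.concatenate(grade_col),
            "duration_s": np.concatenate(dur_col),
        }
    df = pd.DataFrame(rows)
    df["batch_id"] = "sim"
    return RatingTable(spec.scale, df)


def recover_confusion(table: RatingTable, truth: ExpertLabels) -> np.ndarray:
    """Empirical reported-given-true matrix from a rating table.

    Rows are true four-category grades (0–3), columns the codes of the
    table's scale; each row is normalized to sum to 1.  A true grade with no
    ratings yields a NaN row and a warning.
    """
    true4 = truth.grades(FOUR_CAT)
    n_cols = len(table.scale.codes)
    counts = np.zeros((4, n_cols))
    t = true4.loc[table.df["image_id"]].to_numpy()
    np.add.at(counts, (t, table.df["grade"].to_numpy()), 1)
    totals = counts.sum(axis=1, keepdims=True)
    missing = np.flatnonzero(totals.ravel() == 0)
    if missing.size:
        warnings.warn(
            f"no ratings for true grade(s) {missing.tolist()}; "
            "returning NaN rows",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = counts / totals
    out[missing] = np.nan
    return out


def screen_outlier_raters(
    table: RatingTable,
    threshold: float = 3.5,
    min_ratings: int = 5,
    min_deviation: float = 0.5,
) -> list[str]:
    """Flag raters whose mean grade is a robust outlier within the cohort.

    A rater is flagged when both conditions hold for their mean grade:

    * the modified z-score 0.6745·(x − median)/MAD exceeds ``threshold``
      (default 3.5, the customary cut-off for this statistic); and
    * the absolute shift from the cohort median is at least ``min_deviation``
      grade units (default 0.5, half the distance between adjacent grades) —
      a shift smaller than half a grade step is within rounding distance of
      the cohort and is not systematic over- or under-grading, however small
      the cohort's MAD happens to be.

    Raters with fewer than ``min_ratings`` ratings are skipped, and a zero
    MAD (a degenerate, perfectly homogeneous cohort) flags nobody.
    """
    means = table.df.groupby("rater_id")["grade"].agg(["mean", "size"])
    means = means[means["size"] >= min_ratings]["mean"]
    if len(means) < 3:
        return []
    med = float(means.median())
    mad = float((means - med).abs().median())
    if mad == 0.0:
        return []
    dev = (means - med).abs()
    z = 0.6745 * dev / mad
    return sorted(means.index[(z > threshold) & (dev >= min_deviation)])


# ---------------------------------------------------------------------------
# Deep-pool experiment helpers
# ---------------------------------------------------------------------------

def screening_truth(
    n_normal: int = 60,
    n_mild: int = 15,
    n_moderate: int = 10,
    n_severe: int = 15,
    prefix: str = "img",
) -> ExpertLabels:
    """A synthetic screening stream's expert labels.

    Defaults emulate the composition of a screening population: mostly
    normal fundi with a minority of disease at each severity.
    """
    g4 = np.repeat([0, 1, 2, 3], [n_normal, n_mild, n_moderate, n_severe])
    if g4.size == 0:
        raise SpecError("screening truth needs at least one image")
    return ExpertLabels(pd.DataFrame({
        "image_id": [f"{prefix}{i:04d}" for i in range(g4.size)],
        "grade_2cat": (g4 > 0).astype(int),
        "grade_3cat": _PROJECTION_3CAT[g4],
        "grade_4cat": g4,
    }))


def prototype_truth() -> ExpertLabels:
    """Four prototypical images, one per four-category grade."""
    return ExpertLabels(pd.DataFrame({
        "image_id": ["proto_normal", "proto_mild", "proto_moderate",
                     "proto_severe"],
        "grade_2cat": [0, 1, 1, 1],
        "grade_3cat": [0, 1, 1, 2],
        "grade_4cat": [0, 1, 2, 3],
    }))


def calibrate_accuracy_weight(
    truth: ExpertLabels,
    target_accuracy: float,
    primary: RaterArchetype,
    contaminant: RaterArchetype,
    scale: GradingScale | None = None,
) -> float:
    """Mixture weight of ``primary`` giving a target binary per-rating accuracy.

    Expected accuracy is linear in the weight, so the solution is closed-form;
    raises if the target lies outside the span of the two archetypes.
    ``scale`` is the working scale of the task (needed when either archetype
    responds uniformly over the presented options); defaults to two-category.
    """
    from .data_model import TWO_CAT

    scale = scale or TWO_CAT
    g4 = truth.grades(FOUR_CAT).to_numpy()
    acc_p = primary.binary_accuracy(g4, scale)
    acc_c = contaminant.binary_accuracy(g4, scale)
    if math.isclose(acc_p, acc_c):
        raise SpecError("archetypes have equal accuracy; weight is undetermined")
    w = (target_accuracy - acc_c) / (acc_p - acc_c)
    if not (0.0 <= w <= 1.0):
        raise SpecError(
            f"target accuracy {target_accuracy} outside the archetype span "
            f"[{min(acc_p, acc_c):.3f}, {max(acc_p, acc_c):.3f}]"
        )
    return float(w)


def phase2_spec(
    seed: int,
    n_per_image: int = 500,
    target_accuracy: float = 0.813,
    scale: GradingScale | None = None,
) -> CrowdSpec:
    """Crowd spec for the deep-pool crowd-size experiment.

    A mixture of the accurate and random_bot archetypes, with the weight
    solved so the per-rating normal/abnormal accuracy on the four prototype
    images matches the rate observed for individual crowd raters (81.3%).
    Pools are 500 independent raters deep per image and, by default, graded
    on the two-category scale (the normal-versus-abnormal arm).
    """
    from .data_model import TWO_CAT

    archs = builtin_archetypes()
    scale = scale or TWO_CAT
    w = calibrate_accuracy_weight(prototype_truth(), target_accuracy,
                                  archs["accurate"], archs["random_bot"],
                                  scale=scale)
    return CrowdSpec(
        mixture=((archs["accurate"], w), (archs["random_bot"], 1.0 - w)),
        n_raters_per_image=n_per_image,
        scale=scale,
        seed=seed,
        shared_raters=False,
    )
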