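"""Domain types, CSV readers/writers and embedded reference fixtures.

The package analyses crowdsourced ordinal grades of retinal fundus photographs
for diabetic retinopathy.  Images are graded on one of three nested ordinal
scales — normal/abnormal (2 categories), normal / mild-to-moderate / severe
(3 categories), or normal / mild / moderate / severe (4 categories) — always
coded as consecutive integers starting at 0, with 0 = normal.

Two reference fixtures are shipped as package data:

``table1``
    19 teaching images with expert grades on all three scales and the
    mode-consensus grade assigned by crowds of 10 anonymous raters.
``table2``
    Per-batch task economics: mean seconds per rating, payment per rating and
    the platform commission rate for six posted batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

__all__ = [
    "GradingScale",
    "TWO_CAT",
    "THREE_CAT",
    "FOUR_CAT",
    "SCALES",
    "get_scale",
    "NO_CONSENSUS",
    "RatingTable",
    "ExpertLabels",
    "ConsensusTable",
    "EconomicsConfig",
    "read_ratings",
    "write_ratings",
    "read_expert_labels",
    "load_fixture",
    "Table1Fixture",
]


class _NoConsensus:
    """Sentinel for a mode with a tied top frequency under the strict policy."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "NO_CONSENSUS"

    def __reduce__(self):
        return (_NoConsensus, ())


#: Returned by the strict mode rule when no unique most-frequent grade exists.
NO_CONSENSUS = _NoConsensus()


@dataclass(frozen=True)
class GradingScale:
    """An ordinal grading scale with integer codes ``0 .. n-1``.

    ``bin_edges`` are the thresholds used to convert a mean crowd score into a
    grade: the edge between codes ``k-1`` and ``k`` sits at ``k - 0.5``, and a
    mean exactly on an edge belongs to the higher (more severe) grade.
    """

    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValidationError("a grading scale needs at least two categories")
        if self.labels[0] != "normal":
            raise ValidationError("code 0 must be labelled 'normal'")

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(range(len(self.labels)))

    @property
    def max_code(self) -> int:
        return len(self.labels) - 1

    @property
    def bin_edges(self) -> tuple[float, ...]:
        return tuple(k - 0.5 for k in range(1, len(self.labels)))

    def validate_grade(self, grade: int) -> int:
        g = int(grade)
        if g != grade or not (0 <= g <= self.max_code):
            raise ValidationError(
                f"grade {grade!r} is not a valid code on scale {self.name!r} "
                f"(valid codes: 0..{self.max_code})"
            )
        return g

    def label(self, grade: int) -> str:
        return self.labels[self.validate_grade(grade)]


TWO_CAT = GradingScale("two_cat", ("normal", "abnormal"))
THREE_CAT = GradingScale("three_cat", ("normal", "mild/moderate", "severe"))
FOUR_CAT = GradingScale("four_cat", ("normal", "mild", "moderate", "severe"))

SCALES: dict[str, GradingScale] = {s.name: s for s in (TWO_CAT, THREE_CAT, FOUR_CAT)}


def get_scale(name: str) -> GradingScale:
    """Look up a builtin scale by name (``two_cat``, ``three_cat``, ``four_cat``)."""
    try:
        return SCALES[name]
    except KeyError:
        raise LookupError(
            f"unknown grading scale {name!r}; choose from {sorted(SCALES)}"
        ) from None


_RATING_COLUMNS = ["image_id", "rater_id", "grade", "duration_s", "batch_id"]


class RatingTable:
    """Long-format individual ratings: one row per (image, rater) grading.

    Backed by a :class:`pandas.DataFrame` with columns ``image_id``,
    ``rater_id``, ``grade``, ``duration_s`` (optional, NaN when absent) and
    ``batch_id`` (optional).  Row order is preserved.
    """

    def __init__(self, scale: GradingScale, df: pd.DataFrame):
        self.scale = scale
        df = df.copy()
        for col in ("duration_s", "batch_id"):
            if col not in df.columns:
                df[col] = np.nan
        missing = [c for c in ("image_id", "rater_id", "grade") if c not in df.columns]
        if missing:
            raise SchemaError(f"rating table missing column(s): {', '.join(missing)}")
        df = df[_RATING_COLUMNS]
        df["image_id"] = df["image_id"].astype(str)
        df["rater_id"] = df["rater_id"].astype(str)
        self.df = df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.df
        grades = df["grade"]
        bad = ~grades.isin(self.scale.codes)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"row {row}: grade {grades.iloc[row]!r} outside scale "
                f"{self.scale.name!r} codes 0..{self.scale.max_code}"
            )
        df["grade"] = grades.astype(int)
        dur = df["duration_s"]
        if (dur.dropna() < 0).any():
            row = int(np.flatnonzero((dur < 0).fillna(False).to_numpy())[0])
            raise ValidationError(f"row {row}: negative duration_s")
        # one grading per (image, rater) within a batch
        key = df[["image_id", "rater_id"]].copy()
        key["batch_id"] = df["batch_id"].fillna("")
        dup = key.duplicated()
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValidationError(
                f"row {row}: duplicate (image_id, rater_id) within a batch"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def image_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["image_id"]))

    def grades_by_image(self) -> dict[str, np.ndarray]:
        """Per-image grade vectors, in first-appearance image order."""
        groups = self.df.groupby("image_id", sort=False)["grade"]
        return {img: g.to_numpy() for img, g in groups}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RatingTable):
            return NotImplemented
        if self.scale != other.scale or len(self) != len(other):
            return False
        a, b = self.df, other.df
        for col in ("image_id", "rater_id", "grade"):
            if not (a[col] == b[col]).all():
                return False
        for col in ("duration_s",):
            x, y = a[col].to_numpy(float), b[col].to_numpy(float)
            if not np.array_equal(x, y, equal_nan=True):
                return False
        return (a["batch_id"].fillna("") == b["batch_id"].fillna("")).all()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<RatingTable scale={self.scale.name} n={len(self)} "
            f"images={len(self.image_ids)}>"
        )


class ExpertLabels:
    """Per-image expert (criterion standard) grades on all three scales.

    Invariant: an image is normal on one scale iff it is normal on all —
    ``grade_2cat == 0`` iff ``grade_3cat == 0`` iff ``grade_4cat == 0``.
    """

    _GRADE_COLS = {"two_cat": "grade_2cat", "three_cat": "grade_3cat", "four_cat": "grade_4cat"}

    def __init__(self, df: pd.DataFrame):
        missing = [
            c for c in ("image_id", "grade_2cat", "grade_3cat", "grade_4cat")
            if c not in df.columns
        ]
        if missing:
            raise SchemaError(f"expert labels missing column(s): {', '.join(missing)}")
        df = df.copy()
        df["image_id"] = df["image_id"].astype(str)
        if df["image_id"].duplicated().any():
            raise ValidationError("duplicate image_id in expert labels")
        for scale, col in self._GRADE_COLS.items():
            bad = ~df[col].isin(get_scale(scale).codes)
            if bad.any():
                raise ValidationError(
                    f"{col}: invalid code {df.loc[bad, col].iloc[0]!r} on {scale}"
                )
            df[col] = df[col].astype(int)
        norm2 = df["grade_2cat"] == 0
        for col in ("grade_3cat", "grade_4cat"):
            if not (norm2 == (df[col] == 0)).all():
                img = df.loc[norm2 != (df[col] == 0), "image_id"].iloc[0]
                raise ValidationError(
                    f"image {img}: normal/abnormal status differs between "
                    f"grade_2cat and {col}"
                )
        self.df = df.set_index("image_id", drop=False)

    def grades(self, scale: GradingScale) -> pd.Series:
        """Expert grades on ``scale`` as a Series indexed by image_id."""
        return self.df[self._GRADE_COLS[scale.name]]

    @property
    def image_ids(self) -> list[str]:
        return list(self.df["image_id"])

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExpertLabels":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


class ConsensusTable:
    """Per-image consensus grade for one aggregation method and tie policy.

    ``consensus_grade`` is a nullable integer column; ``pd.NA`` encodes
    NO_CONSENSUS, which can arise only with ``method='mode'`` and
    ``tie_policy='strict'``.
    """

    def __init__(self, scale: GradingScale, df: pd.DataFrame,
                 method: str, tie_policy: str):
        if method not in ("mean", "mode"):
            raise ValidationError(f"unknown consensus method {method!r}")
        if tie_policy not in ("strict", "clinical"):
            raise ValidationError(f"unknown tie policy {tie_policy!r}")
        missing = [c for c in ("image_id", "consensus_grade", "n_ratings")
                   if c not in df.columns]
        if missing:
            raise SchemaError(f"consensus table missing column(s): {', '.join(missing)}")
        df = df.copy()
        df["image_id"] = df["image_id"].astype(str)
        df["consensus_grade"] = df["consensus_grade"].astype("Int64")
        df["n_ratings"] = df["n_ratings"].astype(int)
        has_na = df["consensus_grade"].isna().any()
        if has_na and not (method == "mode" and tie_policy == "strict"):
            raise ValidationError(
                "NO_CONSENSUS entries are only valid for method='mode', "
                "tie_policy='strict'"
            )
        valid = df["consensus_grade"].dropna()
        if not valid.isin(scale.codes).all():
            raise ValidationError(f"consensus grade outside scale {scale.name!r}")
        self.scale = scale
        self.method = method
        self.tie_policy = tie_policy
        self.df = df.set_index("image_id", drop=False)

    @property
    def image_ids(self) -> list[str]:
        return list(self.df["image_id"])

    def grade(self, image_id: str):
        """Consensus grade for one image: an int, or NO_CONSENSUS."""
        g = self.df.loc[image_id, "consensus_grade"]
        return NO_CONSENSUS if pd.isna(g) else int(g)

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path: str | Path) -> None:
        out = self.df.copy()
        out["method"] = self.method
        out["tie_policy"] = self.tie_policy
        out = out[["image_id", "method", "tie_policy", "n_ratings", "consensus_grade"]]
        out.to_csv(path, index=False, na_rep="NA")


@dataclass(frozen=True)
class EconomicsConfig:
    """Task economics: worker payment, platform commission, crowd size."""

    pay_per_rating: float
    commission_rate: float
    raters_per_image: int = 10

    def __post_init__(self) -> None:
        if self.pay_per_rating < 0 or self.raters_per_image < 0:
            raise ValidationError("payment and crowd size must be non-negative")
        if not (0 <= self.commission_rate < 1):
            raise ValidationError("commission_rate must lie in [0, 1)")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_ratings(path: str | Path, scale: GradingScale) -> RatingTable:
    """Read a long-format ratings CSV and validate it against ``scale``.

    Required columns: ``image_id``, ``rater_id``, ``grade``; optional:
    ``duration_s``, ``batch_id``.  Row order is preserved.
    """
    try:
        df = pd.read_csv(path, dtype={"image_id": str, "rater_id": str,
                                      "batch_id": str},
                         float_precision="round_trip")
    except FileNotFoundError:
        raise
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in ("image_id", "rater_id", "grade") if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    if len(df):
        grades = pd.to_numeric(df["grade"], errors="coerce")
        bad = grades.isna() | (grades != grades.round())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(f"{path}: row {row}: non-integer grade")
        df["grade"] = grades.astype(int)
        if "duration_s" in df.columns:
            dur = pd.to_numeric(df["duration_s"], errors="coerce")
            bad = dur.isna() & df["duration_s"].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValidationError(f"{path}: row {row}: non-numeric duration_s")
            df["duration_s"] = dur
    else:
        df["grade"] = df.get("grade", pd.Series(dtype=int)).astype(int)
    return RatingTable(scale, df)


def write_ratings(table: RatingTable, path: str | Path) -> None:
    """Write a RatingTable to CSV; read_ratings(write_ratings(t)) == t."""
    out = table.df.copy()
    out.to_csv(path, index=False)


read_expert_labels = ExpertLabels.from_csv


# ---------------------------------------------------------------------------
# Embedded fixtures
# ---------------------------------------------------------------------------

@dataclass
class Table1Fixture:
    """The 19 reference images: expert grades and 10-rater mode consensus."""

    experts: ExpertLabels
    consensus: dict[str, ConsensusTable]  # keyed by scale name
    provenance: dict = field(default_factory=dict)


def _data_path(name: str):
    return resources.files("crowdgrade.data").joinpath(name)


def load_fixture(name: str):
    """Load an embedded reference fixture.

    ``table1`` → :class:`Table1Fixture` (expert grades on all three scales and
    the mode-consensus grade per scale, 19 images, 10 ratings each).
    ``table2`` → DataFrame of six rating batches with mean seconds per rating,
    payment, commission rate and the published wage/cost figures.
    """
    if name == "table1":
        df = pd.read_csv(_data_path("table1_grades.csv"), dtype={"image_id": str})
        experts = ExpertLabels(
            df[["image_id", "grade_2cat", "grade_3cat", "grade_4cat"]]
        )
        consensus = {}
        for scale_name, col in (("two_cat", "consensus_2cat"),
                                ("three_cat", "consensus_3cat"),
                                ("four_cat", "consensus_4cat")):
            scale = get_scale(scale_name)
            cdf = pd.DataFrame({
                "image_id": df["image_id"],
                "consensus_grade": df[col],
                "n_ratings": 10,
            })
            consensus[scale_name] = ConsensusTable(scale, cdf, "mode", "strict")
        provenance = {
            "image_8_three_cat": (
                "published three-category expert rating reads 'severe', "
                "contradicting the image's normal rating on the two- and "
                "four-category scales and the published consensus specificity "
                "5/7; the fixture stores normal on all three scales"
            ),
        }
        return Table1Fixture(experts=experts, consensus=consensus,
                             provenance=provenance)
    if name == "table2":
        return pd.read_csv(_data_path("table2_batches.csv"))
    raise LookupError(f"unknown fixture {name!r}; choose 'table1' or 'table2'")
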