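import numpy as np
import pandas as pd
import pytest

from crowdgrade.data_model import (
    FOUR_CAT,
    GradingScale,
    RatingTable,
    load_fixture,
)
from crowdgrade.synthetic_crowd import RaterArchetype, builtin_archetypes


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def archetypes():
    return builtin_archetypes()


@pytest.fixture(scope="session")
def identity_archetype():
    """A rater who always reports the true grade."""
    return RaterArchetype("identity", np.eye(4))


@pytest.fixture(scope="session")
def constant_severe_archetype():
    """A degenerate severity inflator who grades everything severe."""
    conf = np.zeros((4, 4))
    conf[:, 3] = 1.0
    return RaterArchetype("constant_severe", conf)


def make_ratings(scale: GradingScale, per_image_grades: dict) -> RatingTable:
    """Build a RatingTable from {image_id: [grades]}; one rater per grade."""
    rows = []
    for image_id, grades in per_image_grades.items():
        for i, g in enumerate(grades):
            rows.append({"image_id": image_id, "rater_id": f"r{i:03d}",
                         "grade": int(g)})
    return RatingTable(scale, pd.DataFrame(rows))
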