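"""Rater archetypes, crowd simulation, parameter recovery, outlier screening."""

import io

import numpy as np
import pandas as pd
import pytest

from crowdgrade.consensus import build_consensus
from crowdgrade.data_model import (
    FOUR_CAT,
    RatingTable,
    THREE_CAT,
    TWO_CAT,
    write_ratings,
)
from crowdgrade.diagnostics import binarize, consensus_accuracy
from crowdgrade.exceptions import SpecError, ValidationError
from crowdgrade.synthetic_crowd import (
    CrowdSpec,
    RaterArchetype,
    builtin_archetypes,
    calibrate_accuracy_weight,
    phase2_spec,
    project_grade,
    prototype_truth,
    recover_confusion,
    screen_outlier_raters,
    screening_truth,
    simulate_crowd,
)


class TestArchetypes:
    def test_builtins_present_and_stochastic(self, archetypes):
        assert {"accurate", "moderate_biased", "severity_inflating",
                "random_bot"} <= set(archetypes)
        for a in archetypes.values():
            assert a.confusion.shape == (4, 4)
            assert np.all(a.confusion >= 0)
            np.testing.assert_allclose(a.confusion.sum(axis=1), 1.0,
                                       atol=1e-9)

    def test_random_bot_uniform(self, archetypes):
        assert np.all(archetypes["random_bot"].confusion == 0.25)

    def test_accurate_diagonal_dominant(self, archetypes):
        conf = archetypes["accurate"].confusion
        assert np.all(np.argmax(conf, axis=1) == np.arange(4))

    def test_moderate_bias_pulls_toward_grade_two(self, archetypes):
        biased = archetypes["moderate_biased"].confusion
        accurate = archetypes["accurate"].confusion
        for true_grade in (1, 3):
            assert biased[true_grade, 2] > accurate[true_grade, 2]

    def test_invalid_confusion_rejected(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            RaterArchetype("bad", np.full((4, 4), 0.2))
        with pytest.raises(ValidationError, match="4x4"):
            RaterArchetype("bad", np.eye(3))


@pytest.mark.parametrize("scale", [TWO_CAT, THREE_CAT, FOUR_CAT])
def test_projection_commutes_with_binarization(scale):
    for g in range(4):
        assert binarize(project_grade(g, scale)) == binarize(g)


def test_projection_merges_mild_and_moderate():
    assert [project_grade(g, THREE_CAT) for g in range(4)] == [0, 1, 1, 2]
    assert [project_grade(g, TWO_CAT) for g in range(4)] == [0, 1, 1, 1]


class TestSimulateCrowd:
    def test_identity_crowd_is_perfect(self, table1, identity_archetype):
        spec = CrowdSpec(((identity_archetype, 1.0),), 10, FOUR_CAT, seed=3)
        table = simulate_crowd(table1.experts, spec)
        expert = table1.experts.grades(FOUR_CAT)
        assert all((g == expert[img]).all()
                   for img, g in table.grades_by_image().items())
        ctab = build_consensus(table, method="mode")
        assert consensus_accuracy(ctab, table1.experts).percent_correct == 1.0

    def test_random_bot_two_cat_mean_near_half(self, archetypes):
        truth = screening_truth(2, 2, 0, 0)
        n = 2000
        spec = CrowdSpec(((archetypes["random_bot"], 1.0),), n, TWO_CAT,
                         seed=8, shared_raters=False)
        table = simulate_crowd(truth, spec)
        se = np.sqrt(0.25 / n)  # binomial SE of the mean at p=0.5
        for img, grades in table.grades_by_image().items():
            assert abs(grades.mean() - 0.5) <= 3 * se

    def test_mostly_accurate_crowd_keeps_full_sensitivity(
            self, table1, archetypes):
        """Mode consensus keeps 100% sensitivity in >=95% of seeds."""
        mixture = ((archetypes["accurate"], 0.9),
                   (archetypes["random_bot"], 0.1))
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            spec = CrowdSpec(mixture, 10, TWO_CAT, seed=seed)
            table = simulate_crowd(table1.experts, spec)
            ctab = build_consensus(table, method="mode", tie_policy="clinical")
            if consensus_accuracy(ctab, table1.experts).sensitivity == 1.0:
                hits += 1
        assert hits >= 95

    def test_durations_positive_and_lognormal_scale(self, archetypes):
        spec = CrowdSpec(((archetypes["accurate"], 1.0),), 200, FOUR_CAT,
                         seed=5, shared_raters=False)
        table = simulate_crowd(prototype_truth(), spec)
        dur = table.df["duration_s"]
        assert (dur > 0).all()
        # log-normal median parameterized at ~25 s for genuine raters
        assert 20 < dur.median() < 32

    def test_seed_fixes_output_bytes(self, tmp_path, archetypes):
        mixture = ((archetypes["accurate"], 0.8),
                   (archetypes["random_bot"], 0.2))
        out = []
        for run in range(2):
            spec = CrowdSpec(mixture, 10, FOUR_CAT, seed=99)
            table = simulate_crowd(prototype_truth(), spec)
            p = tmp_path / f"run{run}.csv"
            write_ratings(table, p)
            out.append(p.read_bytes())
        assert out[0] == out[1]
        spec2 = CrowdSpec(mixture, 10, FOUR_CAT, seed=100)
        other = io.StringIO()
        write_ratings(simulate_crowd(prototype_truth(), spec2), other)
        assert other.getvalue().encode() != out[0]

    def test_invalid_mixture(self, archetypes):
        with pytest.raises(SpecError, match="sum to 1"):
            CrowdSpec(((archetypes["accurate"], 0.5),), 10, FOUR_CAT, 0)

    def test_output_passes_validation(self, archetypes):
        # RatingTable construction re-validates grades, durations, uniqueness
        spec = CrowdSpec(((archetypes["severity_inflating"], 1.0),), 7,
                         THREE_CAT, seed=1)
        table = simulate_crowd(prototype_truth(), spec)
        assert isinstance(table, RatingTable)
        assert set(table.df["grade"]) <= set(THREE_CAT.codes)


class TestRecoverConfusion:
    def test_identity_crowd(self, identity_archetype):
        spec = CrowdSpec(((identity_archetype, 1.0),), 50, FOUR_CAT, seed=2,
                         shared_raters=False)
        table = simulate_crowd(prototype_truth(), spec)
        est = recover_confusion(table, prototype_truth())
        np.testing.assert_array_equal(est, np.eye(4))

    def test_recovers_generating_matrix(self, archetypes):
        arch = archetypes["moderate_biased"]
        truth = prototype_truth()
        spec = CrowdSpec(((arch, 1.0),), 2500, FOUR_CAT, seed=12,
                         shared_raters=False)
        est = recover_confusion(simulate_crowd(truth, spec), truth)
        assert np.abs(est - arch.confusion).max() <= 0.05

    def test_missing_true_grade_gives_nan_row(self, identity_archetype):
        truth = screening_truth(2, 2, 2, 0)  # no severe image
        spec = CrowdSpec(((identity_archetype, 1.0),), 10, FOUR_CAT, seed=0)
        table = simulate_crowd(truth, spec)
        with pytest.warns(UserWarning, match="true grade"):
            est = recover_confusion(table, truth)
        assert np.isnan(est[3]).all()
        assert not np.isnan(est[:3]).any()


class TestOutlierScreening:
    def test_planted_severity_inflator_flagged(
            self, archetypes, constant_severe_archetype):
        truth = screening_truth()
        honest = simulate_crowd(
            truth, CrowdSpec(((archetypes["accurate"], 1.0),), 19, FOUR_CAT,
                             seed=77)).df
        planted = simulate_crowd(
            truth, CrowdSpec(((constant_severe_archetype, 1.0),), 1, FOUR_CAT,
                             seed=78)).df
        planted["rater_id"] = "inflator"
        table = RatingTable(FOUR_CAT,
                            pd.concat([honest, planted], ignore_index=True))
        assert screen_outlier_raters(table) == ["inflator"]

    def test_homogeneous_crowd_clean(self, archetypes):
        table = simulate_crowd(
            screening_truth(),
            CrowdSpec(((archetypes["accurate"], 1.0),), 20, FOUR_CAT, seed=5))
        assert screen_outlier_raters(table) == []

    def test_constant_graders_zero_mad_guard(self):
        rows = [{"image_id": f"i{j}", "rater_id": f"r{i}", "grade": 2}
                for i in range(10) for j in range(8)]
        table = RatingTable(FOUR_CAT, pd.DataFrame(rows))
        assert screen_outlier_raters(table) == []

    def test_min_ratings_skips_sparse_raters(self):
        rows = [{"image_id": f"i{j}", "rater_id": "busy", "grade": 1}
                for j in range(10)]
        rows += [{"image_id": "i0", "rater_id": "oneoff", "grade": 3}]
        rows += [{"image_id": f"i{j}", "rater_id": f"r{i}", "grade": 1}
                 for i in range(5) for j in range(10)]
        table = RatingTable(FOUR_CAT, pd.DataFrame(rows))
        assert screen_outlier_raters(table, min_ratings=5) == []


class TestCalibration:
    def test_weight_reproduces_target_accuracy(self, archetypes):
        truth = prototype_truth()
        target = 0.813
        w = calibrate_accuracy_weight(truth, target, archetypes["accurate"],
                                      archetypes["random_bot"])
        mix = ((archetypes["accurate"], w), (archetypes["random_bot"], 1 - w))
        n = 3000
        spec = CrowdSpec(mix, n, TWO_CAT, seed=19, shared_raters=False)
        table = simulate_crowd(truth, spec)
        binary_truth = truth.grades(TWO_CAT).loc[table.df["image_id"]]
        correct = (table.df["grade"].to_numpy() == binary_truth.to_numpy())
        se = np.sqrt(target * (1 - target) / len(table))
        assert abs(correct.mean() - target) <= 3 * se

    def test_unreachable_target(self, archetypes):
        with pytest.raises(SpecError, match="outside"):
            calibrate_accuracy_weight(prototype_truth(), 0.99,
                                      archetypes["accurate"],
                                      archetypes["random_bot"])

    def test_phase2_spec_shape(self):
        spec = phase2_spec(seed=1)
        assert spec.n_raters_per_image == 500
        assert spec.scale is TWO_CAT
        assert not spec.shared_raters


def test_crowdspec_yaml_roundtrip(tmp_path, archetypes):
    spec = CrowdSpec(((archetypes["accurate"], 0.7),
                      (archetypes["random_bot"], 0.3)),
                     12, THREE_CAT, seed=42, shared_raters=False)
    p = tmp_path / "spec.yaml"
    spec.to_yaml(p)
    loaded = CrowdSpec.from_yaml(p)
    assert loaded.n_raters_per_image == 12
    assert loaded.scale is THREE_CAT
    assert loaded.seed == 42
    assert not loaded.shared_raters
    np.testing.assert_allclose(loaded.weights, [0.7, 0.3])
    np.testing.assert_allclose(loaded.archetypes[0].confusion,
                               archetypes["accurate"].confusion)
    a = simulate_crowd(prototype_truth(), spec).df
    b = simulate_crowd(prototype_truth(), loaded).df
    assert a.equals(b)
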