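"""Instance framing, the classifier bank, CV partition, and the metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppgfuzz import classify
from ppgfuzz.classify import (
    CLASSIFIERS,
    FRAME_LENGTH,
    VECTOR_LENGTH,
    InstanceSet,
    cross_validate,
    fit_predict,
    frame_instances,
    metric_formulas,
)


def separated_instances(rng, n_per_class=30, gap=3.0):
    """Two Gaussian clouds with class means ``gap`` SDs apart."""
    x0 = rng.standard_normal((n_per_class, FRAME_LENGTH))
    x1 = rng.standard_normal((n_per_class, FRAME_LENGTH)) + gap
    X = np.vstack([x0, x1])
    y = np.array(["normal"] * n_per_class + ["cvd"] * n_per_class)
    pids = np.array([f"p{i}" for i in range(2 * n_per_class)])
    return InstanceSet(X, y, pids)


class TestFrameInstances:
    def test_42_patients_yield_210_instances(self, rng):
        vectors = {f"p{i}": rng.random(VECTOR_LENGTH) for i in range(42)}
        labels = {k: ("cvd" if i < 28 else "normal") for i, k in enumerate(vectors)}
        inst = frame_instances(vectors, labels)
        assert len(inst) == 210

    def test_first_frame_is_first_75_values_in_order(self, rng):
        v = rng.random(VECTOR_LENGTH)
        inst = frame_instances({"p0": v}, {"p0": "cvd"})
        np.testing.assert_array_equal(inst.X[0], v[:75])

    def test_frames_concatenate_back_to_vector(self, rng):
        v = rng.random(VECTOR_LENGTH)
        inst = frame_instances({"p0": v}, {"p0": "cvd"})
        np.testing.assert_array_equal(inst.X.ravel(), v)
        assert (inst.patient_ids == "p0").all()

    def test_wrong_length_rejected(self, rng):
        with pytest.raises(ValueError):
            frame_instances({"p0": rng.random(100)}, {"p0": "cvd"})


class TestMetricFormulas:
    def test_perfect_counts(self):
        assert metric_formulas(100, 0, 0) == (100.0, 100.0, 100.0, 100.0, 100.0)

    def test_published_formula_worked_example(self):
        sens, spec, acc, pi, gdr = metric_formulas(90, 10, 10)
        assert sens == pytest.approx(90.0)
        assert spec == pytest.approx(90.0)
        assert acc == pytest.approx(90.0)
        assert pi == pytest.approx((90 - 10 - 10) / 90 * 100, abs=1e-9)  # 77.78
        assert pi == pytest.approx(77.78, abs=0.005)
        assert gdr == pytest.approx(80.0)

    def test_half_missed_with_no_false_alarms_zeroes_gdr(self):
        *_, gdr = metric_formulas(50, 50, 0)
        assert gdr == 0.0

    def test_performance_index_can_be_negative(self):
        _, _, _, pi, _ = metric_formulas(10, 20, 20)
        assert pi == pytest.approx(-300.0)

    def test_zero_denominators_report_nan(self):
        sens, spec, acc, pi, gdr = metric_formulas(0, 0, 0)
        assert np.isnan([sens, spec, acc, pi, gdr]).all()

    @given(
        pc=st.integers(1, 500), mc=st.integers(0, 500), fa=st.integers(0, 500)
    )
    @settings(max_examples=100, deadline=None)
    def test_accuracy_is_always_mean_of_sensitivity_and_specificity(
        self, pc, mc, fa
    ):
        sens, spec, acc, *_ = metric_formulas(pc, mc, fa)
        assert acc == (sens + spec) / 2


class TestFitPredict:
    @pytest.mark.parametrize("name", CLASSIFIERS)
    def test_every_classifier_on_separated_clouds(self, name, rng):
        train = separated_instances(rng, 40)
        test = separated_instances(np.random.default_rng(99), 15)
        pred = fit_predict(name, train, test, seed=0)
        acc = (pred == test.y).mean()
        assert acc >= 0.95, f"{name} accuracy {acc}"

    def test_knn_memorizes_duplicated_training_point(self, rng):
        X = np.vstack([np.zeros((5, FRAME_LENGTH)), np.ones((5, FRAME_LENGTH))])
        y = np.array(["cvd"] * 5 + ["normal"] * 5)
        train = InstanceSet(X, y, np.array([f"p{i}" for i in range(10)]))
        test = InstanceSet(
            np.zeros((1, FRAME_LENGTH)), np.array(["cvd"]), np.array(["q"])
        )
        assert fit_predict("KNN", train, test, seed=0)[0] == "cvd"

    def test_flda_with_identical_class_means_is_chance_level(self, rng):
        X = rng.standard_normal((120, FRAME_LENGTH))
        y = np.array(["cvd", "normal"] * 60)
        train = InstanceSet(X, y, np.array([f"p{i}" for i in range(120)]))
        test = InstanceSet(
            rng.standard_normal((400, FRAME_LENGTH)),
            np.array(["cvd", "normal"] * 200),
            np.array([f"q{i}" for i in range(400)]),
        )
        acc = (fit_predict("FLDA", train, test, seed=0) == test.y).mean()
        assert 0.3 < acc < 0.7

    def test_single_class_training_rejected(self, rng):
        X = rng.standard_normal((10, FRAME_LENGTH))
        inst = InstanceSet(X, np.array(["cvd"] * 10), np.array(["p"] * 10))
        with pytest.raises(ValueError):
            fit_predict("LR", inst, inst)

    def test_unknown_classifier_rejected(self, rng):
        inst = separated_instances(rng, 10)
        with pytest.raises(ValueError):
            fit_predict("RF", inst, inst)

    def test_scores_are_probability_like(self, rng):
        train = separated_instances(rng, 30)
        test = separated_instances(np.random.default_rng(5), 10)
        for name in CLASSIFIERS:
            _, scores = fit_predict(name, train, test, seed=0, return_scores=True)
            assert (scores >= 0).all() and (scores <= 1).all(), name


class TestCrossValidate:
    def test_reports_cover_both_classes_and_average(self, rng):
        inst = separated_instances(rng, 25)
        reports = cross_validate(inst, "LR", folds=5, seed=0)
        assert set(reports) == {"cvd", "normal", "average"}

    def test_perfectly_separated_data_scores_100(self, rng):
        inst = separated_instances(rng, 25, gap=6.0)
        reports = cross_validate(inst, "FLDA", folds=5, seed=0)
        for label in ("cvd", "normal"):
            rep = reports[label]
            assert rep.MC == 0 and rep.FA == 0
            assert rep.sensitivity == rep.specificity == rep.accuracy == 100.0
            assert rep.PI == rep.GDR == 100.0

    def test_fold_assignment_is_a_partition(self, rng):
        # the internal assertion verifies each instance is predicted once;
        # PC+MC per class must equal the class size
        inst = separated_instances(rng, 20, gap=0.5)
        reports = cross_validate(inst, "KNN", folds=4, seed=1)
        for label in ("cvd", "normal"):
            assert reports[label].PC + reports[label].MC == 20

    def test_mse_uses_class_targets_on_code_value_scale(self, rng):
        inst = separated_instances(rng, 25, gap=6.0)
        targets = {"normal": 0.1, "cvd": 0.4}
        reports = cross_validate(inst, "LR", folds=5, seed=0, targets=targets)
        # near-perfect separation: mapped outputs sit at the class targets
        assert reports["cvd"].MSE < 0.01
        assert reports["normal"].MSE < 0.01

    def test_insufficient_instances_rejected(self, rng):
        inst = separated_instances(rng, 5)
        with pytest.raises(ValueError):
            cross_validate(inst, "LR", folds=10, seed=0)

    def test_grouped_folds_keep_patients_together(self, rng):
        # 12 patients x 5 frames; grouped CV must not split a patient
        vectors = {f"p{i}": rng.random(VECTOR_LENGTH) + (i % 2) for i in range(12)}
        labels = {k: ("cvd" if i % 2 else "normal") for i, k in enumerate(vectors)}
        inst = frame_instances(vectors, labels)
        reports = cross_validate(
            inst, "KNN", folds=3, seed=0, group_by_patient=True
        )
        assert reports["cvd"].PC + reports["cvd"].MC == 30

    def test_deterministic_given_seed(self, rng):
        inst = separated_instances(rng, 20, gap=1.0)
        r1 = cross_validate(inst, "RBF", folds=4, seed=3)
        r2 = cross_validate(inst, "RBF", folds=4, seed=3)
        assert r1 == r2
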