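"""Tests for folds, classifiers, MCC scoring and the experiment runner."""

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from hemiconn import classify as clf
from hemiconn import pipeline as pl
from hemiconn import synthetic as syn
from hemiconn.synthetic import EhiModel
from tests.conftest import cohort_datasets, small_spec


def textbook_binary_mcc(cm: np.ndarray) -> float:
    """Independent oracle: the TP/TN/FP/FN formula with the 0 convention."""
    (tn, fp), (fn, tp) = cm.astype(float)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


class TestMcc:
    def test_perfect_and_hand_examples(self):
        assert clf.mcc(np.array([[50, 0], [0, 50]])) == 1.0
        assert clf.mcc(np.array([[45, 5], [5, 45]])) == pytest.approx(0.8)

    def test_all_majority_prediction_scores_zero(self):
        # 90/10 split, everything predicted as the majority class
        cm = np.array([[90, 0], [10, 0]])
        assert clf.mcc(cm) == 0.0
        assert clf.accuracy(cm) == pytest.approx(0.90)

    def test_accuracy_examples(self):
        assert clf.accuracy(np.array([[45, 5], [5, 45]])) == pytest.approx(0.9)
        assert clf.accuracy(np.eye(3, dtype=int) * 7) == 1.0

    def test_errors(self):
        with pytest.raises(ValueError):
            clf.mcc(np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError):
            clf.mcc(np.array([[1, -1], [0, 1]]))
        with pytest.raises(ValueError):
            clf.accuracy(np.zeros((2, 2)))

    def test_oracle_equivalence_on_random_matrices(self):
        """mcc() matches the textbook formula (binary) and sklearn's
        label-level computation (multiclass) on 1,000 random matrices."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = rng.integers(2, 5)
            cm = rng.integers(0, 30, size=(k, k))
            if cm.sum() == 0:
                continue
            ours = clf.mcc(cm)
            if k == 2:
                assert ours == pytest.approx(textbook_binary_mcc(cm), abs=1e-12)
            y_true = np.repeat(np.repeat(np.arange(k), k), cm.ravel())
            y_pred = np.repeat(np.tile(np.arange(k), k), cm.ravel())
            if len(np.unique(y_true)) < 2 or len(np.unique(y_pred)) < 2:
                assert ours == 0.0
            else:
                assert ours == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-12)


class TestFolds:
    def test_equal_fold_sizes_for_875_dextrals(self):
        ids = [f"s{i}" for i in range(875)]
        plan = clf.make_folds(ids, ["dextral"] * 875, n_folds=5, seed=0)
        sizes = [len(plan.test_subjects(f)) for f in range(5)]
        assert sizes == [175] * 5

    def test_stratification_within_one_subject(self):
        ids = [f"s{i}" for i in range(97)]
        hands = ["dextral"] * 87 + ["sinistral"] * 10
        plan = clf.make_folds(ids, hands, n_folds=5, seed=1)
        for f in range(5):
            test = plan.test_subjects(f)
            n_sin = sum(1 for s in test if int(s[1:]) >= 87)
            assert 1 <= n_sin <= 3

    def test_determinism_and_partition(self):
        ids = [f"s{i}" for i in range(40)]
        hands = ["dextral"] * 30 + ["sinistral"] * 10
        a = clf.make_folds(ids, hands, seed=9)
        b = clf.make_folds(ids, hands, seed=9)
        assert a.assignment == b.assignment
        assert sorted(a.assignment) == sorted(ids)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer subjects"):
            clf.make_folds(["a", "b", "c"], ["d", "d", "s"], n_folds=2)


class TestTrainAndPredict:
    @pytest.mark.parametrize("model_kind", clf.MODEL_KINDS)
    def test_separable_clouds_are_perfect(self, model_kind):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-5, 0.3, (30, 4)), rng.normal(5, 0.3, (30, 4))])
        y = np.array(["a"] * 30 + ["b"] * 30)
        preds, _ = clf.train_and_predict(X, y, X, model_kind=model_kind)
        assert clf.mcc(clf.confusion(y, preds)) == 1.0

    def test_null_labels_score_near_zero(self):
        rng = np.random.default_rng(1)
        vals = []
        for rep in range(20):
            X = rng.normal(size=(60, 10))
            y = rng.permutation(np.array(["a", "b"] * 30))
            preds, _ = clf.train_and_predict(X[:40], y[:40], X[40:], "LDA")
            vals.append(clf.mcc(clf.confusion(y[40:], preds)))
        assert abs(np.mean(vals)) < 0.15

    def test_single_class_training_rejected(self):
        X = np.zeros((4, 2))
        with pytest.raises(ValueError, match="single class"):
            clf.train_and_predict(X, ["a"] * 4, X)

    def test_unknown_model_kind(self):
        with pytest.raises(ValueError, match="unknown model kind"):
            clf.build_model("forest")


class TestBootstrapCI:
    def test_perfect_predictions(self):
        y = np.array([0, 1] * 20)
        assert clf.bootstrap_mcc_ci(y, y, reps=200, seed=0) == (1.0, 1.0, 1.0)

    def test_null_interval_straddles_zero(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 400)
        y_pred = rng.integers(0, 2, 400)
        _, lo, hi = clf.bootstrap_mcc_ci(y, y_pred, reps=1000, seed=0)
        assert lo < 0 < hi

    def test_determinism(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        y_pred = np.array([0, 1, 1, 1, 0, 0])
        assert clf.bootstrap_mcc_ci(y, y_pred, seed=5) == clf.bootstrap_mcc_ci(y, y_pred, seed=5)

    def test_coverage_of_true_mcc(self, bootstrap_coverage):
        """95% CI covers the long-run MCC in >= 90% of 200 simulations."""
        assert bootstrap_coverage >= 0.90


class TestCalibration:
    def test_balanced_binary_closed_form(self):
        out = clf.mcc_accuracy_calibration([500, 500], 0.8, reps=2000, seed=1)
        assert out["mean"] == pytest.approx(2 * 0.8 - 1, abs=0.02)

    def test_perfect_accuracy_is_exactly_one(self):
        out = clf.mcc_accuracy_calibration([50, 50], 1.0, reps=100, seed=1)
        assert out["mean"] == 1.0 and out["p97.5"] == 1.0

    def test_imbalanced_cohort_reproduces_critical_value_mapping(self):
        """At the study's 875/92 class sizes, 80% and 90% per-class accuracy
        map to MCC ~ 0.4 and ~ 0.6 — the 'good'/'excellent' thresholds."""
        at80 = clf.mcc_accuracy_calibration([875, 92], 0.8, reps=2000, seed=1)
        at90 = clf.mcc_accuracy_calibration([875, 92], 0.9, reps=2000, seed=1)
        assert at80["mean"] == pytest.approx(0.4, abs=0.05)
        assert at90["mean"] == pytest.approx(0.6, abs=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clf.mcc_accuracy_calibration([10, 0], 0.8)
        with pytest.raises(ValueError):
            clf.mcc_accuracy_calibration([10, 10], 0.0)


class TestResampling:
    def test_oversample_to_majority_count(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(967, 3))
        y = np.array(["dextral"] * 875 + ["sinistral"] * 92)
        X2, y2 = clf.oversample_minority(X, y, seed=1)
        _, counts = np.unique(y2, return_counts=True)
        assert counts.tolist() == [875, 875]
        # every added row copies an existing minority row
        added = X2[len(X):]
        minority = X[875:]
        assert all(any(np.array_equal(row, m) for m in minority) for row in added[:10])

    def test_balanced_input_unchanged(self):
        X = np.arange(8.0).reshape(4, 2)
        y = np.array(["a", "a", "b", "b"])
        X2, y2 = clf.oversample_minority(X, y, seed=0)
        assert np.array_equal(X2, X) and np.array_equal(y2, y)

    def test_subsample_defaults_and_errors(self):
        assert clf.default_subsample_target(92) == 74
        subjects = [f"s{i}" for i in range(100)]
        picked = clf.subsample_training(subjects, target_n=74, seed=3)
        assert len(picked) == 74 and len(set(picked)) == 74
        assert picked == clf.subsample_training(subjects, target_n=74, seed=3)
        assert clf.subsample_training(subjects, target_n=0, seed=0) == []
        with pytest.raises(ValueError):
            clf.subsample_training(subjects[:10], target_n=74)


class TestFourway:
    def test_label_construction(self):
        assert clf.fourway_label("LH", "dextral") == "rightyLH"
        assert clf.fourway_label("RH", "sinistral") == "leftyRH"
        with pytest.raises(ValueError):
            clf.fourway_label("LH", "ambidextrous")

    def test_decompose_inverts_construction(self):
        combos = [(h, d) for h in ("LH", "RH") for d in ("dextral", "sinistral")]
        labels = [clf.fourway_label(h, d) for h, d in combos]
        hemi, hand = clf.decompose_fourway(labels)
        assert list(zip(hemi, hand)) == combos

    def test_four_class_lda_has_three_axes(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4]])
        X = np.vstack([rng.normal(c, 0.5, (20, 3)) for c in centers])
        y = np.repeat(["rightyLH", "rightyRH", "leftyLH", "leftyRH"], 20)
        _, model = clf.train_and_predict(X, y, X, "LDA")
        assert model.scalings_.shape[1] == 3


class TestPairedComparison:
    def test_identical_lists(self):
        out = clf.compare_mcc_paired([0.9, 0.8, 0.7], [0.9, 0.8, 0.7])
        assert out["t"] == 0.0 and out["p"] == 1.0 and out["mean_diff"] == 0.0

    def test_hand_computed_three_pairs(self):
        a, b = np.array([0.5, 0.7, 0.9]), np.array([0.4, 0.65, 0.7])
        out = clf.compare_mcc_paired(a, b)
        diff = a - b
        se = diff.std(ddof=1) / np.sqrt(3)
        assert out["t"] == pytest.approx(diff.mean() / se, abs=1e-12)
        assert out["df"] == 2
        assert out["d"] == pytest.approx(diff.mean() / diff.std(ddof=1), abs=1e-12)

    def test_constant_shift_recovered(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0.95, 1.0, 15)
        b = a - 0.012 + rng.normal(0, 1e-4, 15)
        out = clf.compare_mcc_paired(b, a)
        assert out["mean_diff"] == pytest.approx(-0.012, abs=1e-3)
        assert out["p"] < 0.001

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            clf.compare_mcc_paired([0.5, 0.6], [0.4, 0.5])


class TestCrossValidatedRun:
    def test_confusion_totals_and_ci_ordering(self, desk_dextral_run):
        run = desk_dextral_run["run"]
        n_samples = len(desk_dextral_run["data"]["y"])
        assert sum(cm.sum() for cm in run.fold_confusions) == n_samples
        assert run.mcc_ci_low <= run.mcc_point <= run.mcc_ci_high
        assert -1 <= run.mcc_point <= 1

    def test_chirality_signal_ordering_across_cohort_types(self):
        """Mean chirality MCC: dextral-trained >= sinistral-trained >= null,
        averaged over 10 seeds (the planted asymmetry scales with EHI)."""
        means = {}
        for name, overrides in (
            ("dextral", dict(ehi_model=EhiModel(dextral_mass=1.0))),
            ("sinistral", dict(ehi_model=EhiModel(dextral_mass=0.0))),
            ("null", dict(asymmetry_map={}, ehi_model=EhiModel(dextral_mass=1.0))),
        ):
            vals = []
            for seed in range(10):
                spec = small_spec(n_subjects=30, seed=7000 + seed, **overrides)
                cohort = syn.generate_cohort(spec)
                matrices, handedness = cohort_datasets(cohort)
                data = pl.chirality_dataset(matrices, cohort.atlas)
                run = clf.cross_validated_run(
                    data["X"], data["y"], data["subjects"], handedness,
                    model_kind="LDA", n_folds=5, seed=seed, bootstrap_reps=100,
                )
                vals.append(np.mean(run.fold_mcc))
            means[name] = np.mean(vals)
        assert means["dextral"] >= means["sinistral"] >= means["null"]
        assert means["dextral"] > 0.9
        assert abs(means["null"]) < 0.2

    def test_subsampled_training_never_leaks(self, tiny_dextral_cohort):
        cohort = tiny_dextral_cohort
        matrices, handedness = cohort_datasets(cohort)
        data = pl.chirality_dataset(matrices, cohort.atlas)
        run = clf.cross_validated_run(
            data["X"], data["y"], data["subjects"], handedness,
            model_kind="LDA", n_folds=5, seed=0, subsample_train=10,
            bootstrap_reps=100,
        )
        # every sample predicted exactly once
        assert len(run.y_true) == len(data["y"])
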