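"""Tests for the linear-SVM subgroup prediction and permutation test."""

import numpy as np
import pandas as pd
import pytest

from dmnstrat.group_stats import ClinicalTable
from dmnstrat.prediction import (
    PREDICTOR_SETS,
    LinearSVM,
    inspect_weights,
    permutation_test,
    predict_subgroups,
    svm_loocv_accuracy,
)
from dmnstrat.simulate import simulate_clinical


def separable_data(rng, n=37, p=3, gap=10.0):
    y = np.array([1] * (n // 2 + n % 2) + [2] * (n // 2))
    x = rng.normal(size=(n, p))
    x[y == 2, 0] += gap  # one predictor carries a 10-pooled-sd separation
    return x, y


class TestSolver:
    def test_agrees_with_svc_reference(self):
        # independent oracle: sklearn's libsvm solver on the same problems.
        # Residual differences come from the regularized vs free intercept;
        # on z-scored data they are small and predictions agree.
        from sklearn.svm import SVC

        mismatches, total = 0, 0
        for seed in range(60):
            r = np.random.default_rng(seed)
            n, p = int(r.integers(10, 30)), int(r.integers(1, 6))
            x = r.normal(size=(n, p))
            y = np.where(r.random(n) < 0.5, 1, 2)
            if len(np.unique(y)) < 2:
                continue
            x[y == 2] += r.normal(0, 1.5, size=p)
            x = (x - x.mean(0)) / x.std(0)
            ours = LinearSVM(C=1.0).fit(x, y)
            ref = SVC(kernel="linear", C=1.0).fit(x, y)
            grid = r.normal(size=(50, p))
            mismatches += int(np.sum(ours.predict(grid) != ref.predict(grid)))
            total += 50
            assert np.abs(ours.coef_ - ref.coef_).max() < 0.7
        assert mismatches / total < 0.05

    def test_solution_is_primal_optimal(self, rng):
        # the dual solution must (weakly) beat the SVC solution under the
        # regularized-bias primal objective it optimizes
        from sklearn.svm import SVC

        x, y = separable_data(rng, n=24, gap=2.0)
        x = (x - x.mean(0)) / x.std(0)

        def primal(w, b):
            t = np.where(y == 2, 1.0, -1.0)
            hinge = np.clip(1 - t * (x @ w + b), 0, None).sum()
            return 0.5 * (w @ w + b * b) + hinge

        ours = LinearSVM(C=1.0).fit(x, y)
        ref = SVC(kernel="linear", C=1.0).fit(x, y)
        assert primal(ours.coef_[0], ours.intercept_[0]) <= primal(
            ref.coef_[0], ref.intercept_[0]
        ) + 1e-6


class TestLoocv:
    def test_fully_separable_classes(self, rng):
        x, y = separable_data(rng)
        accuracy, _ = svm_loocv_accuracy(x, y)
        assert accuracy == 1.0

    def test_matches_hand_rolled_fold_loop(self, rng):
        x = rng.normal(size=(12, 3))
        y = np.array([1, 2] * 6)
        x[y == 2] += 0.8
        _, preds = svm_loocv_accuracy(x, y)
        expected = np.empty(12, dtype=int)
        for i in range(12):
            mask = np.ones(12, dtype=bool)
            mask[i] = False
            mu, sd = x[mask].mean(0), x[mask].std(0)
            clf = LinearSVM().fit((x[mask] - mu) / sd, y[mask])
            expected[i] = clf.predict((x[i : i + 1] - mu) / sd)[0]
        assert np.array_equal(preds, expected)

    def test_uninformative_labels_never_beat_chance(self, rng):
        # LOOCV on permuted labels is pessimistic (the held-out class is
        # always underrepresented in training), so the null mean sits at or
        # slightly below the majority-class rate -- never above it
        x, y = separable_data(rng)
        accs = []
        for rep in range(500):
            perm = np.random.default_rng(rep).permutation(y)
            acc, _ = svm_loocv_accuracy(x, perm)
            accs.append(acc)
        majority = max(np.mean(y == 1), np.mean(y == 2))
        assert np.mean(accs) <= majority + 0.01
        assert np.mean(accs) >= majority - 0.10

    def test_scaling_never_leaks_from_held_out_row(self, rng):
        # a huge outlier in the held-out row would shift the z-scoring if the
        # whole data set were standardized before the split; the correct
        # per-fold scaling is immune to it
        x = rng.normal(size=(14, 2))
        y = np.array([1, 2] * 7)
        x[y == 2] += 1.2
        x_outlier = x.copy()
        x_outlier[5] += 8.0  # row 5 becomes an outlier along both axes

        def leaky_loocv(xx, yy):
            z = (xx - xx.mean(0)) / xx.std(0)  # scaled once, on everything
            preds = np.empty(len(yy), dtype=int)
            for i in range(len(yy)):
                mask = np.ones(len(yy), dtype=bool)
                mask[i] = False
                preds[i] = LinearSVM().fit(z[mask], yy[mask]).predict(z[i : i + 1])[0]
            return preds

        def correct_loocv(xx, yy):
            preds = np.empty(len(yy), dtype=int)
            for i in range(len(yy)):
                mask = np.ones(len(yy), dtype=bool)
                mask[i] = False
                mu, sd = xx[mask].mean(0), xx[mask].std(0)
                clf = LinearSVM().fit((xx[mask] - mu) / sd, yy[mask])
                preds[i] = clf.predict((xx[i : i + 1] - mu) / sd)[0]
            return preds

        _, outlier_preds = svm_loocv_accuracy(x_outlier, y)
        assert np.array_equal(outlier_preds, correct_loocv(x_outlier, y))
        # whole-data scaling lets the held-out outlier distort every fold's
        # standardization: the leaky variant visibly diverges on this input
        assert not np.array_equal(leaky_loocv(x_outlier, y), outlier_preds)

    def test_missing_values_rejected(self, rng):
        x = rng.normal(size=(10, 2))
        x[3, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            svm_loocv_accuracy(x, np.array([1, 2] * 5))


class TestPermutation:
    def test_uninformative_features_give_unit_p(self, rng):
        x = np.ones((12, 2))  # constant features: every accuracy ties
        y = np.array([1, 2] * 6)
        _, p, _ = permutation_test(x, y, n_permutations=30, seed=0)
        assert p == 1.0

    def test_floor_at_one_over_m_plus_one(self, rng):
        x, y = separable_data(rng, n=16, gap=50.0)
        observed, p, perm = permutation_test(x, y, n_permutations=100, seed=0)
        assert observed == 1.0
        if not np.any(perm >= 1.0):
            assert p == pytest.approx(1 / 101)

    def test_p_on_permutation_lattice(self, rng):
        x, y = separable_data(rng, n=14, gap=1.0)
        m = 40
        _, p, _ = permutation_test(x, y, n_permutations=m, seed=1)
        lattice = [(b + 1) / (m + 1) for b in range(m + 1)]
        assert any(abs(p - v) < 1e-12 for v in lattice)

    def test_invariant_to_class_relabeling(self, rng):
        x, y = separable_data(rng, n=15, gap=1.5)
        swapped = np.where(y == 1, 2, 1)
        _, p1, _ = permutation_test(x, y, n_permutations=60, seed=4)
        _, p2, _ = permutation_test(x, swapped, n_permutations=60, seed=4)
        assert p1 == p2

    def test_null_p_values_roughly_uniform(self):
        # a light null check (the full 200-dataset type-I calibration runs
        # in the acceptance suite): null p values should not pile up low
        ps = []
        for seed in range(25):
            r = np.random.default_rng(seed)
            x = r.normal(size=(14, 3))
            y = np.array([1] * 7 + [2] * 7)
            _, p, _ = permutation_test(x, y, n_permutations=60, seed=500 + seed)
            ps.append(p)
        assert np.mean(np.asarray(ps) < 0.2) <= 0.45

    def test_zero_permutations_rejected(self, rng):
        x, y = separable_data(rng, n=10)
        with pytest.raises(ValueError, match="n_permutations"):
            permutation_test(x, y, n_permutations=0)


class TestWeights:
    def test_informative_predictor_dominates(self, rng):
        x, y = separable_data(rng, p=4)
        w = inspect_weights(x, y, feature_names=["a", "b", "c", "d"])
        assert max(w, key=lambda k: abs(w[k])) == "a"
        assert w["a"] > 0  # pushes toward the higher label (subgroup 2)

    def test_class_swap_flips_signs(self, rng):
        x, y = separable_data(rng, n=20, gap=2.0)
        w1 = inspect_weights(x, y)
        w2 = inspect_weights(x, np.where(y == 1, 2, 1))
        for k in w1:
            assert w1[k] == pytest.approx(-w2[k], abs=1e-6)

    def test_duplicated_predictor_splits_weight(self, rng):
        # in the margin-dominated (separable) regime the L2 penalty splits
        # the weight equally and the two copies sum to the original
        # hard-margin regime (large C, wide gap): the hinge is inactive at
        # the optimum and duplication only re-parameterizes the penalty
        x, y = separable_data(rng, n=20, p=1, gap=8.0)
        w_single = inspect_weights(x, y, C=100.0)["x0"]
        xx = np.hstack([x, x])
        w_dup = inspect_weights(xx, y, C=100.0)
        assert w_dup["x0"] == pytest.approx(w_dup["x1"], rel=1e-3)
        assert w_dup["x0"] + w_dup["x1"] == pytest.approx(w_single, rel=1e-3)


class TestPredictSubgroups:
    labels = {f"sz{i:03d}": (1 if i < 19 else 2) for i in range(37)}

    def test_panss_rows_with_missing_values_dropped(self):
        table = simulate_clinical(self.labels, {"panss_neg": 1.5}, seed=0)
        table.data.loc[table.data["participant_id"] == "sz004", "panss_pos"] = np.nan
        result = predict_subgroups(self.labels, table, "panss", n_permutations=30, seed=0)
        assert result.n_dropped_missing == 1
        assert result.n_total == 36

    def test_predictor_set_variables(self):
        assert len(PREDICTOR_SETS["panss"]) == 3
        assert len(PREDICTOR_SETS["cognition"]) == 5

    def test_strong_clinical_signal_detected(self):
        table = simulate_clinical(self.labels, {"panss_neg": 2.5}, seed=3)
        result = predict_subgroups(self.labels, table, "panss", n_permutations=200, seed=1)
        assert result.accuracy > 0.7
        assert result.permutation_p < 0.05
        assert max(result.weights, key=lambda k: abs(result.weights[k])) == "panss_neg"

    def test_unknown_predictor_set_rejected(self):
        table = simulate_clinical(self.labels, {}, seed=0)
        with pytest.raises(ValueError, match="unknown predictor set"):
            predict_subgroups(self.labels, table, "demography")
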