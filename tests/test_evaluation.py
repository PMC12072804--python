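"""Evaluation: folds, OLS report, AUC, threshold sweep, metrics, McNemar."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icterus.cohort import CohortConfig, SubjectRecord, simulate_cohort
from icterus.errors import (
    ConfigurationError,
    UndefinedAUCError,
    UndefinedMetricError,
    ZeroVarianceError,
)
from icterus.evaluation import (
    auc,
    classification_report,
    cross_validate,
    f1_score,
    mcnemar_exact,
    regression_report,
    stratified_folds,
    threshold_sweep,
)
from icterus.models import ModelSpec


def subjects(bilirubins):
    return [
        SubjectRecord(
            subject_id=f"S{i:03d}",
            group="case" if b > 3 else "control",
            total_bilirubin=float(b),
            direct_bilirubin=float(b) / 2,
            jaundice_label=b > 3,
        )
        for i, b in enumerate(bilirubins)
    ]


# --- oracles ---------------------------------------------------------------


def auc_pairwise_oracle(scores, labels):
    """O(n^2) definition: mean over pos x neg pairs, ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def ols_normal_equations_oracle(x, y):
    """Simple linear regression of y on x from first principles."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (n - 2)
    cov = s2 * np.linalg.inv(X.T @ X)
    se_slope = math.sqrt(cov[1, 1])
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1 - (resid @ resid) / ss_tot
    return beta[1], se_slope, r2


def mcnemar_binomial_oracle(b, c):
    """Two-sided exact binomial via explicit pmf summation (math.comb)."""
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    tail = sum(math.comb(n, i) for i in range(k + 1)) * 0.5**n
    return min(1.0, 2.0 * tail)


# --- stratified folds ------------------------------------------------------


class TestStratifiedFolds:
    def test_perfectly_divisible_cohort(self):
        cohort = subjects([5, 6, 7, 8, 9, 1, 1.5, 2, 2.5, 0.5])
        folds = stratified_folds(cohort, k=5, seed=0)
        for fold in range(5):
            members = folds.members(fold)
            abnormal = sum(1 for r in cohort if r.subject_id in members and r.total_bilirubin > 3)
            assert len(members) == 2 and abnormal == 1

    def test_default_cohort_mix_balanced_within_one(self, default_cohort):
        folds = stratified_folds(default_cohort, k=5, seed=3)
        abnormal_ids = {r.subject_id for r in default_cohort if r.total_bilirubin > 3}
        counts = [
            sum(1 for sid in folds.members(f) if sid in abnormal_ids) for f in range(5)
        ]
        assert max(counts) - min(counts) <= 1
        assert sum(len(folds.members(f)) for f in range(5)) == len(default_cohort)

    def test_fixed_seed_reproducible(self, default_cohort):
        a = stratified_folds(default_cohort, k=5, seed=9)
        b = stratified_folds(default_cohort, k=5, seed=9)
        assert a.fold_of == b.fold_of

    def test_more_folds_than_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            stratified_folds(subjects([1, 2, 5]), k=5)


class TestCrossValidate:
    def test_leave_one_out_degenerate(self, rng):
        from icterus.features import FEATURE_LENGTH, FeatureVector

        cohort = subjects([1.0, 2.0, 5.0, 8.0])
        inputs = {
            r.subject_id: FeatureVector(values=rng.uniform(0, 1, FEATURE_LENGTH))
            for r in cohort
        }
        folds = stratified_folds(cohort, k=4, seed=0)
        preds = cross_validate(ModelSpec(kind="decision_tree"), cohort, inputs, folds)
        assert set(preds) == {r.subject_id for r in cohort}

    def test_memorizing_tree_out_of_fold_worse_than_training(self, rng):
        from icterus.features import FEATURE_LENGTH, FeatureVector
        from icterus.models import predict_many, train

        cohort = subjects(np.exp(rng.normal(1.2, 0.8, 40)))
        # features only weakly informative: target + noise in one coordinate
        inputs = {}
        for r in cohort:
            v = rng.uniform(0, 1, FEATURE_LENGTH)
            v[0] = r.total_bilirubin + rng.normal(0, 2.0)
            inputs[r.subject_id] = FeatureVector(values=v)
        spec = ModelSpec(kind="decision_tree", hyperparams={"max_depth": None}, seed=0)
        folds = stratified_folds(cohort, k=5, seed=1)
        oof = cross_validate(spec, cohort, inputs, folds)
        X = [inputs[r.subject_id] for r in cohort]
        y = np.array([r.total_bilirubin for r in cohort])
        train_preds = predict_many(train(spec, X, y), X)
        r2 = lambda p: 1 - np.sum((p - y) ** 2) / np.sum((y - y.mean()) ** 2)
        assert r2(train_preds) > r2(np.array([oof[r.subject_id] for r in cohort]))

    def test_missing_inputs_rejected(self):
        cohort = subjects([1, 2, 5, 8])
        folds = stratified_folds(cohort, k=2, seed=0)
        with pytest.raises(ConfigurationError):
            cross_validate(ModelSpec(kind="decision_tree"), cohort, {}, folds)


# --- regression report -----------------------------------------------------


class TestRegressionReport:
    def test_identity_predictions(self):
        pred = [1.0, 2.0, 3.0, 4.0, 5.0]
        rep = regression_report(pred, pred)
        assert rep.slope_B == pytest.approx(1.0)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.mean_difference == 0.0 and rep.diff_sd == 0.0

    def test_fixture_matches_normal_equations_oracle(self):
        pred = [1.2, 3.4, 2.2, 5.6, 4.1]
        truth = [1.0, 3.9, 2.0, 6.2, 4.0]
        rep = regression_report(pred, truth)
        slope, se, r2 = ols_normal_equations_oracle(pred, truth)
        assert rep.slope_B == pytest.approx(slope, abs=1e-10)
        assert rep.slope_se == pytest.approx(se, abs=1e-10)
        assert rep.r_squared == pytest.approx(r2, abs=1e-10)
        assert rep.pearson_r**2 == pytest.approx(rep.r_squared, abs=1e-12)

    def test_exact_linear_scaling(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0])
        rep = regression_report(pred, 2 * pred)
        assert rep.slope_B == pytest.approx(2.0)
        assert rep.r_squared == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        x = rng.normal(5, 3, n)
        y = 0.8 * x + rng.normal(0, 1, n)
        if np.ptp(x) == 0:
            return
        rep = regression_report(x, y)
        slope, se, r2 = ols_normal_equations_oracle(x, y)
        assert rep.slope_B == pytest.approx(slope, abs=1e-10)
        assert rep.slope_se == pytest.approx(se, abs=1e-10)
        assert rep.r_squared == pytest.approx(r2, abs=1e-10)

    def test_zero_variance_predictions_rejected(self):
        with pytest.raises(ZeroVarianceError):
            regression_report([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


# --- AUC -------------------------------------------------------------------


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11], [False, False, False, True, True]) == 1.0

    def test_null_behavior_near_half(self, rng):
        scores = rng.permutation(np.arange(4000, dtype=float))
        labels = np.arange(4000) % 2 == 0
        assert abs(auc(scores, labels) - 0.5) < 0.03

    def test_six_point_instance_matches_pairwise_count(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.9]
        labels = [False, True, False, True, True, False]
        assert auc(scores, labels) == pytest.approx(auc_pairwise_oracle(scores, labels))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_random_instances_match_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        scores = rng.choice([0.1, 0.25, 0.5, 0.8, 1.3], size=n)  # force ties
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            return
        assert auc(scores, labels) == pytest.approx(
            auc_pairwise_oracle(scores, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            auc([1.0, 2.0], [True, True])


# --- threshold sweep -------------------------------------------------------


class TestThresholdSweep:
    def test_perfect_predictions_best_at_lowest_defined(self):
        truth = np.array([0.5, 0.8, 1.2, 2.0, 3.5, 5.0, 9.0])
        res = threshold_sweep(truth, truth)
        defined = [t for t, a in res.auc_at.items() if a is not None]
        assert all(res.auc_at[t] == 1.0 for t in defined)
        assert res.best_threshold == min(defined)
        assert res.best_auc == 1.0

    def test_noisy_predictions_keep_high_best_auc(self, rng):
        cohort = simulate_cohort(CohortConfig(n_cases=130, n_controls=70, seed=8))
        truth = np.array([r.total_bilirubin for r in cohort])
        pred = truth + rng.normal(0, 0.5, truth.size)
        assert threshold_sweep(pred, truth).best_auc >= 0.95

    def test_singleton_grid_reduces_to_single_auc(self):
        pred = [1.0, 2.0, 3.0, 4.0]
        truth = [1.0, 2.0, 3.0, 4.0]
        res = threshold_sweep(pred, truth, grid=[2.6])
        assert res.best_threshold == 2.6
        assert res.best_auc == auc(pred, np.array(truth) > 2.6)

    def test_all_undefined_rejected(self):
        with pytest.raises(UndefinedAUCError):
            threshold_sweep([1.0, 2.0], [9.0, 9.5])  # all abnormal everywhere

    def test_added_noise_does_not_help_in_expectation(self, rng):
        """Mean best AUC over 20 seeds: extra prediction noise never raises it."""
        cohort = simulate_cohort(CohortConfig(n_cases=60, n_controls=40, seed=2))
        truth = np.array([r.total_bilirubin for r in cohort])
        base, noisy = [], []
        for s in range(20):
            r = np.random.default_rng(s)
            p = truth + r.normal(0, 0.3, truth.size)
            base.append(threshold_sweep(p, truth).best_auc)
            noisy.append(threshold_sweep(p + r.normal(0, 2.0, truth.size), truth).best_auc)
        assert np.mean(noisy) <= np.mean(base) + 1e-9


# --- classification metrics ------------------------------------------------


class TestClassificationReport:
    def test_f1_harmonic_mean_worked_values(self):
        # inputs are themselves printed to 3 decimals, so the harmonic mean
        # can differ from the tabulated value by a unit in the last digit
        assert f1_score(0.902, 0.881) == pytest.approx(0.891, abs=1e-3)
        assert f1_score(0.860, 0.881) == pytest.approx(0.871, abs=1e-3)

    def test_trivial_two_subject_report(self):
        rep = classification_report([5.0, 1.0], [5.0, 1.0], threshold=3.0)
        assert rep.matrix.as_dict() == {"TP": 1, "TN": 1, "FP": 0, "FN": 0}
        assert rep.accuracy == 1.0 and rep.f1 == 1.0

    def test_cells_are_integers_summing_to_n(self, rng):
        pred = rng.uniform(0, 10, 37)
        truth = rng.uniform(0, 10, 37)
        rep = classification_report(pred, truth, threshold=3.0)
        m = rep.matrix
        assert m.total == 37
        assert rep.accuracy == pytest.approx((m.tp + m.tn) / 37)

    def test_f1_between_precision_and_recall(self, rng):
        for _ in range(20):
            pred = rng.uniform(0, 10, 50)
            truth = rng.uniform(0, 10, 50)
            try:
                rep = classification_report(pred, truth, threshold=5.0)
            except UndefinedMetricError:
                continue
            assert min(rep.precision, rep.recall) - 1e-12 <= rep.f1
            assert rep.f1 <= max(rep.precision, rep.recall) + 1e-12

    def test_undefined_metrics_raise(self):
        with pytest.raises(UndefinedMetricError):
            classification_report([1.0, 1.0], [5.0, 1.0], threshold=3.0)  # no pred pos
        with pytest.raises(UndefinedMetricError):
            classification_report([5.0, 1.0], [1.0, 1.0], threshold=3.0)  # no true pos


# --- McNemar ---------------------------------------------------------------


class TestMcNemar:
    def test_four_zero_discordance(self):
        a = [True] * 4 + [True] * 6
        b = [False] * 4 + [True] * 6
        res = mcnemar_exact(a, b)
        assert (res.discordant_b, res.discordant_c) == (4, 0)
        assert res.p_value == pytest.approx(0.125)

    def test_symmetric_discordance_caps_at_one(self):
        a = [True, False, True, True]
        b = [False, True, True, True]
        assert mcnemar_exact(a, b).p_value == 1.0

    def test_no_discordance(self):
        assert mcnemar_exact([True, False], [True, False]).p_value == 1.0

    def test_all_small_tables_match_binomial_oracle(self):
        for b in range(13):
            for c in range(13 - b):
                va = [True] * b + [False] * c + [True] * 3
                vb = [False] * b + [True] * c + [True] * 3
                res = mcnemar_exact(va, vb)
                assert res.p_value == pytest.approx(
                    mcnemar_binomial_oracle(b, c), abs=1e-12
                )
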