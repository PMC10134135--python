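"""Classifier fitting, ROC-AUC, cross-validation and the sim-to-exp protocol."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irsim import (
    DegenerateLabelsError,
    LeakageError,
    SpectralCohort,
    UnsplittableError,
    assert_no_leakage,
    fit_l2_logistic,
    repeated_kfold_cv,
    roc_auc,
    train_sim_test_exp,
)


def pairwise_auc(scores, labels):
    """O(n^2) concordance oracle: mean over case-control pairs of
    [s_case > s_ctrl] + 1/2 [s_case == s_ctrl]."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])) == 1.0

    def test_all_ties(self):
        assert roc_auc(np.ones(10), np.array([1] * 5 + [0] * 5)) == 0.5

    def test_matches_pairwise_oracle_exactly(self, rng):
        """200 random scores (with forced ties) equal the O(n^2) oracle."""
        scores = rng.integers(0, 40, size=200).astype(float)  # coarse grid -> ties
        labels = rng.integers(0, 2, size=200)
        if labels.sum() in (0, 200):
            labels[0] = 1 - labels[0]
        assert roc_auc(scores, labels) == pairwise_auc(scores, labels)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.standard_normal(300)
        labels = rng.integers(0, 2, size=300)
        assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(DegenerateLabelsError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_antisymmetry_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.standard_normal(30), 1)
        labels = np.concatenate([np.ones(10, int), np.zeros(20, int)])
        auc = roc_auc(scores, labels)
        assert auc + roc_auc(-scores, labels) == 1.0
        assert roc_auc(np.exp(scores) + 3.0, labels) == pytest.approx(auc, abs=1e-12)


class TestFitL2Logistic:
    def test_separable_one_dimensional(self):
        features = np.concatenate([np.full(10, -1.0), np.full(10, 1.0)])[:, None]
        labels = np.array([0] * 10 + [1] * 10)
        scorer = fit_l2_logistic(features, labels, penalty_strength=0.1)
        assert scorer.weights[0] > 0
        assert roc_auc(scorer.score(features), labels) == 1.0
        # decision boundary between the clusters
        assert scorer.score(np.array([[-1.0]]))[0] < 0 < scorer.score(np.array([[1.0]]))[0]

    def test_ridge_limit_shrinks_weights(self, rng):
        X = rng.standard_normal((60, 5))
        y = (X[:, 0] + 0.3 * rng.standard_normal(60) > 0).astype(int)
        norms = [
            np.linalg.norm(fit_l2_logistic(X, y, penalty_strength=c).weights)
            for c in (10.0, 1.0, 0.1, 0.01, 0.001)
        ]
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 0.05 * norms[0]

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateLabelsError):
            fit_l2_logistic(np.ones((4, 2)), np.zeros(4, int))
        bad = np.ones((4, 2))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_l2_logistic(bad, np.array([0, 0, 1, 1]))


def make_cohort(X, y):
    labels = np.where(np.asarray(y) == 1, "case", "control").astype(object)
    return SpectralCohort(
        wavenumbers=np.arange(X.shape[1], dtype=float) + 1000.0,
        absorbance=X,
        labels=labels,
        sample_ids=np.array([f"s{i}" for i in range(len(y))], dtype=object),
    )


class TestRepeatedKfoldCV:
    def test_separable_feature_gives_auc_one(self, rng):
        n = 100
        y = np.array([0, 1] * (n // 2))
        X = rng.standard_normal((n, 4)) * 0.01
        X[:, 0] += 10.0 * y
        result = repeated_kfold_cv(make_cohort(X, y), k=5, repeats=2, seed=0)
        assert result.mean_auc == 1.0

    def test_null_distribution_centered(self, rng):
        """Two interleaved identical distributions -> mean AUC near 0.5.

        The CV mean for a single null dataset fluctuates with the dataset's
        own chance separability (sd ~ 0.6/sqrt(n)), so the check averages
        over independent datasets, as the evaluation protocol does.
        """
        n = 400
        aucs = []
        for ds in range(8):
            X = rng.standard_normal((n, 5))
            y = np.array([0, 1] * (n // 2))
            aucs.append(repeated_kfold_cv(make_cohort(X, y), k=10, repeats=1, seed=ds).mean_auc)
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_permutation_null(self, small_simulated, rng):
        """Randomly permuted labels destroy the signal: mean AUC in
        [0.45, 0.55] over 20 permutations."""
        X = small_simulated.absorbance
        aucs = []
        for rep in range(20):
            y = rng.permutation((small_simulated.labels == "case").astype(int))
            res = repeated_kfold_cv(make_cohort(X, y), k=5, repeats=1, seed=rep)
            aucs.append(res.mean_auc)
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_unsplittable_error(self, rng):
        X = rng.standard_normal((12, 3))
        y = np.array([1] * 4 + [0] * 8)
        with pytest.raises(UnsplittableError):
            repeated_kfold_cv(make_cohort(X, y), k=5, repeats=1)

    def test_determinism_and_result_consistency(self, small_simulated):
        a = repeated_kfold_cv(small_simulated, k=5, repeats=2, seed=3)
        b = repeated_kfold_cv(small_simulated, k=5, repeats=2, seed=3)
        np.testing.assert_array_equal(a.fold_aucs, b.fold_aucs)
        assert a.config_digest == b.config_digest
        assert a.mean_auc == pytest.approx(np.mean(a.fold_aucs))
        assert a.std_auc == pytest.approx(np.std(a.fold_aucs, ddof=1))
        assert len(a.fold_aucs) == 10
        # averaged ROC polyline: monotone from (0,0) to (1,1)
        fpr, tpr = a.roc_points[:, 0], a.roc_points[:, 1]
        assert fpr[0] == tpr[0] == 0.0 and fpr[-1] == tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= -1e-12)

    def test_stratified_partition_properties(self, rng):
        """Every sample appears exactly once per repeat and per-fold class
        ratios stay within one sample of the global ratio."""
        from sklearn.model_selection import StratifiedKFold

        from irsim.rng import child_seed

        n, k = 115, 5
        y = (rng.random(n) < 0.4).astype(int)
        X = rng.standard_normal((n, 2))
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=child_seed(0, 0))
        seen = np.zeros(n, int)
        for _, test_idx in splitter.split(X, y):
            seen[test_idx] += 1
            fold_ratio = y[test_idx].mean()
            expect = y.mean() * len(test_idx)
            assert abs(y[test_idx].sum() - expect) <= 1.0
        assert np.all(seen == 1)


class TestTrainSimTestExp:
    def test_leakage_guard(self):
        with pytest.raises(LeakageError, match="leaked"):
            assert_no_leakage(["a", "b"], ["b", "c"])
        assert_no_leakage(["a"], ["b", "c"])  # disjoint: no raise

    def test_null_reference_gives_chance(self, rng):
        """Zero-signal references average to chance over independent draws."""
        aucs = []
        for ds in range(5):
            X = rng.standard_normal((400, 6))
            y = np.array([0, 1] * 200)
            res = train_sim_test_exp(make_cohort(X, y), None, folds=5, sim_repeats=1, seed=ds)
            aucs.append(res.mean_auc)
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_protocol_consistency_on_fixture(self, small_reference, small_models):
        """Training on simulated data only performs like within-reference CV."""
        controls, cases = small_reference[0], small_reference[1]
        reference = SpectralCohort.concat([controls, cases])
        within = repeated_kfold_cv(reference, k=5, repeats=4, seed=5)
        sim_trained = train_sim_test_exp(
            reference, small_models["noise"], folds=5, sim_repeats=4, seed=5
        )
        assert abs(sim_trained.mean_auc - within.mean_auc) <= 0.05

    def test_larger_simulated_training_does_not_hurt(self, small_reference, small_models):
        controls, cases = small_reference[0], small_reference[1]
        reference = SpectralCohort.concat([controls, cases])
        at_ref = train_sim_test_exp(
            reference, small_models["noise"], folds=5, sim_repeats=3, seed=6
        )
        at_large = train_sim_test_exp(
            reference, small_models["noise"], folds=5, sim_repeats=3,
            sim_sizes=(2000, 2000), seed=6,
        )
        spread = max(at_ref.std_auc, at_large.std_auc)
        assert at_large.mean_auc >= at_ref.mean_auc - 2 * spread
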