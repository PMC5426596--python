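import numpy as np
import pytest

from vgrfgait.classify import (ClassifierSpec, compare_classifiers, default_specs,
                               kernel_value, loo_evaluate, metrics_frame, pca_reduce)


def separable_1d(n=20):
    """Disjoint class ranges on one feature."""
    X = np.concatenate([np.linspace(0, 1, n // 2), np.linspace(5, 6, n // 2)])[:, None]
    y = np.repeat([0, 1], n // 2)
    return X, y


class TestKernelValue:
    linear = ClassifierSpec(name="l", family="svm", kernel="linear")
    rbf = ClassifierSpec(name="r", family="svm", kernel="rbf")
    quad = ClassifierSpec(name="q", family="svm", kernel="quadratic")
    cubic = ClassifierSpec(name="c", family="svm", kernel="cubic")

    def test_rbf_at_zero_distance_is_one(self):
        u = np.array([1.0, -2.0, 3.0])
        for gamma in (0.1, 1.0, 10.0):
            assert kernel_value(u, u, self.rbf, gamma=gamma) == pytest.approx(1.0)

    def test_cubic_unit_inner_product(self):
        u = np.array([1.0, 0.0])
        v = np.array([1.0, 5.0])  # u.v = 1
        assert kernel_value(u, v, self.cubic) == pytest.approx(8.0)

    def test_quadratic_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            u, v = rng.normal(size=(2, 4))
            assert kernel_value(u, v, self.quad) == \
                pytest.approx(kernel_value(v, u, self.quad), abs=1e-12)

    def test_linear_is_inner_product(self):
        assert kernel_value([1.0, 2.0], [3.0, 4.0], self.linear) == 11.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kernel_value([1.0], [1.0, 2.0], self.linear)


class TestSpecValidation:
    def test_kernel_requires_svm(self):
        with pytest.raises(ValueError):
            ClassifierSpec(name="x", family="knn", kernel="linear")
        with pytest.raises(ValueError):
            ClassifierSpec(name="x", family="svm")

    def test_pca_variance_bounds(self):
        with pytest.raises(ValueError):
            ClassifierSpec(name="x", family="knn", pca_variance=1.5)


class TestLOOEvaluate:
    def test_separable_fixture_is_perfect(self):
        X, y = separable_1d()
        spec = ClassifierSpec(name="l", family="svm", kernel="linear")
        res = loo_evaluate(X, y, spec)
        assert (res.accuracy, res.sensitivity, res.specificity, res.auc) == \
            (1.0, 1.0, 1.0, 1.0)

    def test_metric_identities_on_confusion_counts(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = np.repeat([0, 1], 15)
        res = loo_evaluate(X, y, ClassifierSpec(name="k", family="knn", k=3))
        n = len(y)
        assert res.tp + res.tn + res.fp + res.fn == n
        assert res.accuracy == (res.tp + res.tn) / n
        assert res.sensitivity == res.tp / (res.tp + res.fn)
        assert res.specificity == res.tn / (res.tn + res.fp)
        assert len(res.y_pred) == n  # one fold per subject

    def test_knn_k1_matches_hand_enumeration(self):
        # 4 points on a line; nearest neighbour of each is its adjacent point
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        y = np.array([0, 0, 1, 1])
        spec = ClassifierSpec(name="k1", family="knn", k=1, standardize=False)
        res = loo_evaluate(X, y, spec)
        np.testing.assert_array_equal(res.y_pred, [0, 0, 1, 1])
        assert res.accuracy == 1.0

    def test_permutation_null_is_chance_level(self):
        """Permuting labels destroys the signal: accuracy falls from 1.0 to
        chance.  Leave-one-out on balanced classes carries a small
        pessimistic bias (the held-out subject's class is always the
        training minority), so the permutation mean sits slightly below
        0.5 rather than exactly on it."""
        X, y = separable_1d(n=40)
        spec = ClassifierSpec(name="l", family="svm", kernel="linear")
        rng = np.random.default_rng(17)
        accs = [loo_evaluate(X, rng.permutation(y), spec).accuracy
                for _ in range(200)]
        assert abs(np.mean(accs) - 0.5) < 0.06

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 4))
        y = np.repeat([0, 1], 10)
        spec = ClassifierSpec(name="ada", family="boosted_ensemble")
        a = loo_evaluate(X, y, spec, seed=5)
        b = loo_evaluate(X, y, spec, seed=5)
        np.testing.assert_array_equal(a.y_pred, b.y_pred)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_no_leakage_from_held_out_subject(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        y = np.repeat([0, 1], 10)
        spec = ClassifierSpec(name="l", family="svm", kernel="linear",
                              pca_variance=0.95)
        X2 = X.copy()
        X2[0] *= 1e6  # arbitrarily scale one held-out subject
        # the fold-0 transform is fit on subjects 1..19 only, so scaling
        # subject 0 must leave it (and the transformed training fold)
        # bit-identical
        from vgrfgait.classify import _fit_fold, pca_reduce
        t_base = _fit_fold(X[1:], spec)
        t_shift = _fit_fold(X2[1:], spec)
        np.testing.assert_array_equal(t_base(X[1:]), t_shift(X2[1:]))
        Z_base, _, k_base = pca_reduce(t_base(X[1:]), t_base(X[:1]), 0.95)
        Z_shift, _, k_shift = pca_reduce(t_shift(X2[1:]), t_shift(X2[:1]), 0.95)
        assert k_base == k_shift
        np.testing.assert_array_equal(Z_base, Z_shift)

    def test_constant_score_auc_is_half(self):
        from vgrfgait.classify import EvaluationResult
        res = EvaluationResult(spec_name="c", y_true=np.array([0, 1, 0, 1]),
                               y_pred=np.array([0, 0, 0, 0]),
                               scores=np.zeros(4))
        assert res.auc == 0.5

    def test_perfect_ordering_auc_is_one(self):
        from vgrfgait.classify import EvaluationResult
        res = EvaluationResult(spec_name="c", y_true=np.array([0, 0, 1, 1]),
                               y_pred=np.array([0, 0, 1, 1]),
                               scores=np.array([-2.0, -1.0, 1.0, 2.0]))
        assert res.auc == 1.0


class TestPCAReduce:
    def test_variance_on_one_axis_keeps_one_component(self):
        rng = np.random.default_rng(4)
        X = np.zeros((30, 5))
        X[:, 2] = rng.normal(size=30)
        _, _, k = pca_reduce(X, X[:1], 0.95)
        assert k == 1

    def test_full_fraction_keeps_all_nonzero_components(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 4))
        Ztr, _, k = pca_reduce(X, X[:1], 1.0)
        assert k == 4
        # projection onto all components preserves pairwise distances
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(Ztr), pdist(X - X.mean(0)), atol=1e-8)

    def test_isotropic_gaussian_needs_most_components(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(500, 10))
        _, _, k = pca_reduce(X, X[:1], 0.95)
        assert k >= 9

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            pca_reduce(np.eye(3), np.eye(3), 0.0)


class TestCompareClassifiers:
    def test_one_result_per_default_spec(self):
        X, y = separable_1d(n=30)
        results = compare_classifiers(X, y, seed=0)
        assert set(results) == {s.name for s in default_specs()}
        frame = metrics_frame(results)
        assert len(frame) == len(default_specs())
        assert (frame["accuracy"] >= 0.9).all()  # trivially separable

    def test_failing_spec_reported_not_fatal(self):
        X, y = separable_1d(n=30)
        bad = ClassifierSpec(name="tiny_knn", family="knn", k=200)  # k > n
        results = compare_classifiers(X, y, specs=[bad] + default_specs()[:1])
        assert results["tiny_knn"].fold_errors
        assert results["svm_linear"].accuracy == 1.0

    def test_same_seed_same_table(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(24, 5))
        y = np.repeat([0, 1], 12)
        a = metrics_frame(compare_classifiers(X, y, seed=3))
        b = metrics_frame(compare_classifiers(X, y, seed=3))
        assert a.equals(b)
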