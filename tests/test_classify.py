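"""Discriminant scores, decision rules, and the support-vector machine."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.svm import SVC

import fibrospec as fs
from fibrospec.classify import DiscriminantModel, SvmModel, discriminant_scores


def _manual_model(means, pooled, class_covs, priors, labels=("a", "b")):
    return DiscriminantModel(
        class_labels=list(labels[: len(means)]),
        class_means=np.atleast_2d(np.asarray(means, dtype=float)),
        pooled_covariance=np.asarray(pooled, dtype=float),
        class_covariances=np.asarray(class_covs, dtype=float),
        priors=np.asarray(priors, dtype=float),
    )


class TestFitDiscriminant:
    def test_balanced_priors(self):
        X = np.vstack([np.zeros((4, 2)), np.ones((4, 2))])
        y = ["a"] * 4 + ["b"] * 4
        model = fs.fit_discriminant(X + np.random.default_rng(0).normal(0, 0.1, X.shape), y)
        np.testing.assert_allclose(model.priors, [0.5, 0.5])

    def test_pooled_equals_weighted_average_oracle(self):
        """2-class 2-D fixture: pooled covariance vs hand-computed weighting."""
        rng = np.random.default_rng(1)
        Xa, Xb = rng.normal(size=(5, 2)), rng.normal(size=(9, 2))
        model = fs.fit_discriminant(np.vstack([Xa, Xb]), ["a"] * 5 + ["b"] * 9)
        Ca = np.cov(Xa, rowvar=False, ddof=1)
        Cb = np.cov(Xb, rowvar=False, ddof=1)
        expected = (4 * Ca + 8 * Cb) / (14 - 2)
        np.testing.assert_allclose(model.pooled_covariance, expected, atol=1e-12)

    def test_identical_class_covariances_pool_to_themselves(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 2))
        X2 = X + 10.0  # same covariance, shifted mean
        model = fs.fit_discriminant(np.vstack([X, X2]), ["a"] * 6 + ["b"] * 6)
        np.testing.assert_allclose(
            model.pooled_covariance, model.class_covariances[0], atol=1e-12
        )

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            fs.fit_discriminant(np.ones((3, 2)), ["a", "a", "b"])


class TestLdaScore:
    def test_zero_at_class_mean_with_unit_prior(self):
        model = _manual_model([[1.0, 2.0]], np.eye(2), [np.eye(2)], [1.0], labels=("a",))
        assert fs.lda_score([1.0, 2.0], model, "a") == 0.0

    def test_identity_covariance_is_squared_euclidean(self):
        model = _manual_model([[0.0, 0.0]], np.eye(2), [np.eye(2)], [1.0], labels=("a",))
        assert fs.lda_score([3.0, 4.0], model, "a") == pytest.approx(25.0)

    def test_hand_inverted_2x2_oracle(self):
        """C = ((2,1),(1,2)), diff = (1,1), prior 1/2:
        C^-1 = ((2,-1),(-1,2))/3 so the Mahalanobis term is 2/3."""
        model = _manual_model(
            [[0.0, 0.0]], [[2.0, 1.0], [1.0, 2.0]], [[[2.0, 1.0], [1.0, 2.0]]], [0.5], ("a",)
        )
        expected = 2.0 / 3.0 - 2.0 * np.log(0.5)
        assert fs.lda_score([1.0, 1.0], model, "a") == pytest.approx(expected, abs=1e-10)


class TestQdaScore:
    def test_identity_covariance_reduces_to_lda(self):
        model = _manual_model(
            [[0.0, 1.0], [2.0, 3.0]],
            np.eye(2),
            [np.eye(2), np.eye(2)],
            [0.5, 0.5],
        )
        x = [0.7, -0.3]
        for k in ("a", "b"):
            assert fs.qda_score(x, model, k) == pytest.approx(fs.lda_score(x, model, k))

    def test_diagonal_covariance_oracle(self):
        """C = diag(4, 1), diff = (2, 0), prior 1 -> 4/4 + ln 4."""
        model = _manual_model(
            [[0.0, 0.0]], np.diag([4.0, 1.0]), [np.diag([4.0, 1.0])], [1.0], ("a",)
        )
        assert fs.qda_score([2.0, 0.0], model, "a") == pytest.approx(1.0 + np.log(4.0), abs=1e-10)

    def test_score_strictly_decreasing_in_prior(self):
        scores = []
        for prior in (0.2, 0.5, 0.9):
            model = _manual_model([[0.0, 0.0]], np.eye(2), [np.eye(2)], [prior], ("a",))
            scores.append(fs.qda_score([1.0, 1.0], model, "a"))
        assert scores[0] > scores[1] > scores[2]

    @pytest.mark.parametrize("seed", range(5))
    def test_equal_covariances_rank_like_lda(self, seed):
        """With every C_k equal to C_pooled the QDA ordering of classes
        equals the LDA ordering (the log-determinant is constant)."""
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        C = A @ A.T + 0.5 * np.eye(3)
        model = _manual_model(
            rng.normal(size=(3, 3)), C, [C, C, C], [0.2, 0.3, 0.5], ("a", "b", "c")
        )
        X = rng.normal(size=(10, 3))
        lda = discriminant_scores(X, model, "lda")
        qda = discriminant_scores(X, model, "qda")
        np.testing.assert_array_equal(np.argsort(lda, axis=1), np.argsort(qda, axis=1))


class TestMahalanobisInvariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_under_linear_transforms(self, seed):
        """Applying one invertible 3x3 transform to x, the means and the
        covariances leaves both scores unchanged."""
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        means = rng.normal(size=(2, 3))
        B = rng.normal(size=(3, 3))
        C = B @ B.T + np.eye(3)
        x = rng.normal(size=3)
        model = _manual_model(means, C, [C, C], [0.5, 0.5])
        tmodel = _manual_model(
            means @ A.T, A @ C @ A.T, [A @ C @ A.T] * 2, [0.5, 0.5]
        )
        for k in ("a", "b"):
            mahal = fs.lda_score(x, model, k)
            mahal_t = fs.lda_score(A @ x, tmodel, k)
            assert mahal_t == pytest.approx(mahal, abs=1e-8)


class TestPredictDiscriminant:
    def test_class_mean_goes_to_its_class(self):
        model = _manual_model([[0.0, 0.0], [4.0, 4.0]], np.eye(2), [np.eye(2)] * 2, [0.5, 0.5])
        pred = fs.predict_discriminant(np.array([[0.0, 0.0], [4.0, 4.0]]), model)
        assert pred.tolist() == ["a", "b"]

    def test_midpoint_tie_breaks_to_first_class(self):
        model = _manual_model([[0.0, 0.0], [4.0, 4.0]], np.eye(2), [np.eye(2)] * 2, [0.5, 0.5])
        assert fs.predict_discriminant(np.array([[2.0, 2.0]]), model)[0] == "a"

    def test_separable_gaussian_toy_high_accuracy(self):
        rng = np.random.default_rng(12)
        X = np.vstack(
            [rng.normal([0, 0], 1, (100, 2)), rng.normal([5, 5], 1, (100, 2))]
        )
        y = np.array(["a"] * 100 + ["b"] * 100, dtype=object)
        model = fs.fit_discriminant(X, y)
        acc = np.mean(fs.predict_discriminant(X, model) == y)
        assert acc >= 0.95

    @pytest.mark.parametrize("rule", ["lda", "qda"])
    def test_matches_sklearn_discriminant_analysis(self, rule):
        """Independent oracle: sklearn's LDA/QDA predict the same labels."""
        rng = np.random.default_rng(21)
        X = np.vstack(
            [rng.multivariate_normal([0, 0], [[1, 0.3], [0.3, 2]], 60),
             rng.multivariate_normal([1.5, 1.0], [[2, -0.2], [-0.2, 1]], 60)]
        )
        y = np.array(["a"] * 60 + ["b"] * 60, dtype=object)
        model = fs.fit_discriminant(X, y)
        mine = fs.predict_discriminant(X, model, rule=rule)
        ref = (
            LinearDiscriminantAnalysis() if rule == "lda" else QuadraticDiscriminantAnalysis()
        ).fit(X, y.astype(str)).predict(X)
        assert np.mean(mine == ref) > 0.99


class TestSvm:
    def test_analytic_two_point_maximum_margin(self):
        """x = -1 (y=-1) and x = +1 (y=+1): boundary at 0, both points are
        support vectors with equal multipliers 1/2."""
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1, 1])
        model = fs.fit_svm(X, y, kernel="linear", C=1e6)
        assert model.n_sv == 2
        np.testing.assert_allclose(model.alphas, [0.5, 0.5], atol=1e-6)
        assert abs(model.bias) < 1e-6
        assert fs.svm_decision([-0.5], model) == -1
        assert fs.svm_decision([0.5], model) == 1
        # every training point classified correctly
        np.testing.assert_array_equal(fs.predict_svm(X, model), y)

    def test_contradictory_points_tolerated_by_soft_margin(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array([-1, 1, 1, -1])
        model = fs.fit_svm(X, y, kernel="linear", C=0.1)
        assert model.n_sv >= 2  # converges without error

    def test_decision_arithmetic(self):
        model = SvmModel(
            support_vectors=np.array([[1.0], [2.0]]),
            alphas=np.array([1.0, 0.5]),
            sv_labels=np.array([1, -1]),
            bias=-0.5,
            kernel="linear",
        )
        # sum = 1*1*1 + 0.5*(-1)*2 - 0.5 = -0.5 -> negative side
        assert fs.svm_decision([1.0], model) == -1

    def test_sign_zero_is_positive(self):
        model = SvmModel(
            support_vectors=np.array([[1.0]]),
            alphas=np.array([1.0]),
            sv_labels=np.array([1]),
            bias=-1.0,
            kernel="linear",
        )
        assert fs.svm_decision([1.0], model) == 1  # sum exactly 0

    def test_linear_dual_scaling_invariance(self):
        """Scaling inputs by 10 and the box constraint by 1/100 leaves
        linear-kernel predictions unchanged."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 3))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=40) > 0, 1, -1)
        if len(set(y)) < 2:
            pytest.skip("degenerate draw")
        m1 = fs.fit_svm(X, y, kernel="linear", C=1.0)
        m2 = fs.fit_svm(10 * X, y, kernel="linear", C=0.01)
        Z = rng.normal(size=(20, 3))
        np.testing.assert_array_equal(fs.predict_svm(Z, m1), fs.predict_svm(10 * Z, m2))

    def test_rbf_translation_invariance(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(40, 2))
        y = np.where(np.linalg.norm(X, axis=1) > 1.2, 1, -1)
        shift = np.array([100.0, -50.0])
        m1 = fs.fit_svm(X, y, kernel="rbf", params={"gamma": 0.5}, C=10.0)
        m2 = fs.fit_svm(X + shift, y, kernel="rbf", params={"gamma": 0.5}, C=10.0)
        Z = rng.normal(size=(25, 2))
        np.testing.assert_array_equal(fs.predict_svm(Z, m1), fs.predict_svm(Z + shift, m2))

    @pytest.mark.parametrize("kernel", ["linear", "rbf"])
    def test_decision_rule_matches_sklearn_predict(self, kernel):
        """The kernel-expansion decision reproduces SVC.predict exactly
        (dual-route check of the stored expansion)."""
        rng = np.random.default_rng(30)
        X = rng.normal(size=(60, 4))
        y = np.where(X[:, 0] - X[:, 1] > 0, 1, -1)
        gamma = 0.3
        model = fs.fit_svm(X, y, kernel=kernel, params={"gamma": gamma}, C=5.0)
        ref = SVC(C=5.0, kernel=kernel, gamma=gamma).fit(X, y)
        Z = rng.normal(size=(50, 4))
        np.testing.assert_array_equal(fs.predict_svm(Z, model), ref.predict(Z))

    def test_label_guard(self):
        with pytest.raises(ValueError, match="both"):
            fs.fit_svm(np.ones((3, 1)), np.array([1, 1, 1]))
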