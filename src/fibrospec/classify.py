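"""Mahalanobis discriminant classifiers and the kernel SVM decision rule.

LDA and QDA assign a sample ``x`` to the class ``k`` minimising a
Mahalanobis-distance-based score:

    L_ik = (x - xbar_k)^T C_pooled^-1 (x - xbar_k) - 2 ln(pi_k)        (LDA)
    Q_ik = (x - xbar_k)^T C_k^-1    (x - xbar_k) + ln|C_k| - 2 ln(pi_k) (QDA)

with class means ``xbar_k``, pooled / per-class sample covariances and
training-proportion priors ``pi_k``.  When all per-class covariances equal
the pooled covariance the two scores rank classes identically (the
``ln|C_k|`` term is constant across k).

The SVM predicts via the kernel expansion over support vectors,

    f(z) = sign( sum_i alpha_i y_i K(x_i, z) + b ),

with ``sign(0)`` defined as +1.  The soft-margin dual is solved by
scikit-learn's SVC; the stored model keeps only the support vectors,
their multipliers ``alpha_i`` and labels ``y_i``, and the bias ``b``, and
the decision rule above is evaluated from those directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

#: Ridge is engaged when the covariance condition number exceeds this.
_COND_THRESHOLD = 1e10
#: Ridge magnitude, as a multiple of the mean covariance diagonal.
_RIDGE_FACTOR = 1e-8


@dataclass
class DiscriminantModel:
    """Fitted quantities shared by the LDA and QDA scores."""

    class_labels: list
    class_means: np.ndarray  # (K, p)
    pooled_covariance: np.ndarray  # (p, p)
    class_covariances: np.ndarray  # (K, p, p)
    priors: np.ndarray  # (K,)
    ridge: float = 0.0

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]

    def class_index(self, k) -> int:
        return self.class_labels.index(k)


def fit_discriminant(X: np.ndarray, labels) -> DiscriminantModel:
    """Estimate class means, per-class and pooled covariances, and priors.

    The pooled covariance is the (n_k - 1)-weighted average of the
    per-class sample covariances.  If any covariance is ill-conditioned
    (condition number > 1e10), a ridge of 1e-8 x mean diagonal is recorded
    and added as eps*I before inversion — GA/SPA variable subsets can be
    nearly collinear.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    classes = [c for c in np.unique(labels)]
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape
    means, covs, counts = [], [], []
    for c in classes:
        Xc = X[labels == c]
        if Xc.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        means.append(Xc.mean(axis=0))
        covs.append(np.atleast_2d(np.cov(Xc, rowvar=False, ddof=1)))
        counts.append(Xc.shape[0])
    counts = np.array(counts)
    covs = np.array(covs)
    pooled = np.tensordot(counts - 1, covs, axes=1) / (n - len(classes))

    ridge = 0.0
    for C in [pooled, *covs]:
        if np.linalg.cond(C) > _COND_THRESHOLD:
            ridge = _RIDGE_FACTOR * float(np.mean(np.diag(pooled)))
            break
    return DiscriminantModel(
        class_labels=classes,
        class_means=np.array(means),
        pooled_covariance=pooled,
        class_covariances=covs,
        priors=counts / n,
        ridge=ridge,
    )


def _regularized(C: np.ndarray, ridge: float) -> np.ndarray:
    return C + ridge * np.eye(C.shape[0]) if ridge else C


def _mahalanobis_sq(diff: np.ndarray, C: np.ndarray) -> np.ndarray:
    """(rows of diff)^T C^-1 (rows of diff); raises on a singular C."""
    try:
        sol = np.linalg.solve(C, diff.T)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular covariance matrix: {exc}") from None
    return np.einsum("ij,ji->i", diff, sol)


def lda_score(x: np.ndarray, model: DiscriminantModel, k) -> float:
    """Linear discriminant score L_ik (lower = closer to class k)."""
    i = model.class_index(k)
    diff = np.atleast_2d(np.asarray(x, dtype=float) - model.class_means[i])
    C = _regularized(model.pooled_covariance, model.ridge)
    return float(_mahalanobis_sq(diff, C)[0] - 2.0 * np.log(model.priors[i]))


def qda_score(x: np.ndarray, model: DiscriminantModel, k) -> float:
    """Quadratic discriminant score Q_ik (lower = closer to class k)."""
    i = model.class_index(k)
    diff = np.atleast_2d(np.asarray(x, dtype=float) - model.class_means[i])
    C = _regularized(model.class_covariances[i], model.ridge)
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        raise np.linalg.LinAlgError(f"class {k!r} covariance is not positive definite")
    return float(
        _mahalanobis_sq(diff, C)[0] + logdet - 2.0 * np.log(model.priors[i])
    )


def discriminant_scores(X: np.ndarray, model: DiscriminantModel, rule: str = "lda") -> np.ndarray:
    """Score matrix (n_rows x n_classes) under the LDA or QDA rule."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    cols = []
    for i, _ in enumerate(model.class_labels):
        diff = X - model.class_means[i]
        if rule == "lda":
            C = _regularized(model.pooled_covariance, model.ridge)
            extra = 0.0
        elif rule == "qda":
            C = _regularized(model.class_covariances[i], model.ridge)
            sign, logdet = np.linalg.slogdet(C)
            if sign <= 0:
                raise np.linalg.LinAlgError(
                    f"class {model.class_labels[i]!r} covariance is not positive definite"
                )
            extra = logdet
        else:
            raise ValueError(f"unknown rule {rule!r}")
        cols.append(_mahalanobis_sq(diff, C) + extra - 2.0 * np.log(model.priors[i]))
    return np.column_stack(cols)


def predict_discriminant(X: np.ndarray, model: DiscriminantModel, rule: str = "lda") -> np.ndarray:
    """Assign each row to the class with minimal score (ties: first class)."""
    scores = discriminant_scores(X, model, rule)
    idx = np.argmin(scores, axis=1)  # argmin returns the first class on ties
    return np.array([model.class_labels[i] for i in idx], dtype=object)


@dataclass
class SvmModel:
    """Support vectors, multipliers and bias of the fitted SVM."""

    support_vectors: np.ndarray  # (n_sv, p)
    alphas: np.ndarray  # (n_sv,) all > 0
    sv_labels: np.ndarray  # (n_sv,) in {-1, +1}
    bias: float
    kernel: str = "linear"
    kernel_params: dict = field(default_factory=dict)

    @property
    def n_sv(self) -> int:
        return self.support_vectors.shape[0]


def fit_svm(
    X: np.ndarray,
    y: np.ndarray,
    kernel: str = "linear",
    params: dict | None = None,
    C: float = 1.0,
) -> SvmModel:
    """Solve the soft-margin dual and keep the support-vector expansion.

    ``y`` must be in {-1, +1} with both labels present.  ``params`` may
    carry ``gamma`` for the RBF kernel.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("labels must be in {-1, +1} with both present")
    if kernel not in ("linear", "rbf"):
        raise ValueError(f"unsupported kernel {kernel!r}")
    params = dict(params or {})
    if kernel == "rbf":
        gamma = params.get("gamma")
        if gamma is None:  # sklearn's "scale" default, made explicit
            gamma = 1.0 / (X.shape[1] * X.var()) if X.var() > 0 else 1.0
        kparams = {"gamma": float(gamma)}
    else:
        kparams = {}
    clf = SVC(C=C, kernel=kernel, gamma=kparams.get("gamma", "scale"))
    clf.fit(X, y)
    dual = clf.dual_coef_[0]  # alpha_i * y_i, classes_ ordered (-1, +1)
    keep = np.abs(dual) > 1e-8
    return SvmModel(
        support_vectors=clf.support_vectors_[keep],
        alphas=np.abs(dual[keep]),
        sv_labels=np.sign(dual[keep]).astype(int),
        bias=float(clf.intercept_[0]),
        kernel=kernel,
        kernel_params=kparams,
    )


def _kernel_matrix(model: SvmModel, Z: np.ndarray) -> np.ndarray:
    if model.kernel == "linear":
        return model.support_vectors @ Z.T
    gamma = model.kernel_params["gamma"]
    return np.exp(-gamma * cdist(model.support_vectors, Z, "sqeuclidean"))


def svm_decision_value(Z: np.ndarray, model: SvmModel) -> np.ndarray:
    """The pre-sign sum alpha_i y_i K(x_i, z) + b for each row z."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != model.support_vectors.shape[1]:
        raise ValueError(
            f"query dimension {Z.shape[1]} != model dimension {model.support_vectors.shape[1]}"
        )
    return (model.alphas * model.sv_labels) @ _kernel_matrix(model, Z) + model.bias


def svm_decision(z: np.ndarray, model: SvmModel) -> int:
    """Predicted label in {-1, +1} for a single query (sign(0) := +1)."""
    value = svm_decision_value(np.atleast_2d(z), model)[0]
    return 1 if value >= 0 else -1


def predict_svm(Z: np.ndarray, model: SvmModel) -> np.ndarray:
    """Vectorised decision over the rows of Z."""
    values = svm_decision_value(Z, model)
    return np.where(values >= 0, 1, -1)
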