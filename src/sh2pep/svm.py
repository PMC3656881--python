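"""Regularized polynomial-kernel support-vector classifier.

The predictor for each SH2 domain is a soft-margin SVM with the
inhomogeneous polynomial kernel

    K(x, z) = (x . z + c0)^d,     c0 = 1 by default,

on the 120-dimensional one-hot peptide encoding.  Degree d controls which
order of inter-position amino-acid dependencies the model can express
(d = 1 is an ordinary linear model; d = 2 adds all position-pair
interactions), while the cost parameter C sets the regularization
strength.  A degree-d kernel implicitly works in the space of all
monomials of the input coordinates up to degree d — for d = 3 on 120
inputs, on the order of 3 x 10^5 dimensions — without materializing them.

Training delegates the quadratic program to scikit-learn/libsvm; the
fitted model is stored as its kernel expansion (support vectors, dual
coefficients, bias) so decision values are reproducible from the
serialized form alone:

    f(x) = sum_i alpha_i y_i K(x_i, x) + b.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
import numpy as np
from sklearn.svm import SVC

DEGREE_GRID_DEFAULT = (1, 2, 3)
COST_GRID_DEFAULT = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class SVMConfig:
    """Kernel and regularization hyper-parameters."""

    degree: int = 2
    C: float = 1.0
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError(f"polynomial degree must be >= 1, got {self.degree}")
        if self.C <= 0:
            raise ValueError(f"cost parameter C must be positive, got {self.C}")


def poly_kernel(x: np.ndarray, z: np.ndarray, config: SVMConfig) -> float | np.ndarray:
    """Inhomogeneous polynomial kernel (x . z + c0)^d.

    Accepts vectors or matrices; for matrices returns the Gram block
    ``K[i, j] = (x_i . z_j + c0)^d``.
    """
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape[-1] != z.shape[-1]:
        raise ValueError(f"dimension mismatch: {x.shape[-1]} vs {z.shape[-1]}")
    dots = x @ z.T if x.ndim > 1 or z.ndim > 1 else float(x @ z)
    return (dots + config.coef0) ** config.degree


def monomial_count(n_dims: int, degree: int, cumulative: bool = False) -> int:
    """Number of distinct monomials of (exactly) ``degree`` in ``n_dims`` variables.

    The degree-exact count is the multiset coefficient C(n + d - 1, d);
    with ``cumulative=True`` all degrees 0..d are summed, i.e. the
    dimension of the polynomial feature space the kernel works in.
    """
    if n_dims < 1 or degree < 0:
        raise ValueError("need n_dims >= 1 and degree >= 0")
    if cumulative:
        return sum(comb(n_dims + k - 1, k) for k in range(degree + 1))
    return comb(n_dims + degree - 1, degree)


@dataclass
class SVMModel:
    """A fitted SVM stored as its kernel expansion.

    ``dual_coef`` holds alpha_i * y_i for each support vector; the decision
    function is the kernel expansion plus ``bias``.  ``scheme`` records the
    peptide encoding the model was trained on so mismatched inputs are
    rejected rather than silently mis-scored.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    bias: float
    config: SVMConfig
    scheme: str = "full20"
    n_train_pos: int = 0
    n_train_neg: int = 0

    @property
    def n_features(self) -> int:
        return self.support_vectors.shape[1]

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Signed distance-like score; positive predicts binding."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"encoding mismatch: model expects {self.n_features} features "
                f"(scheme {self.scheme!r}), got {X.shape[1]}"
            )
        K = poly_kernel(X, self.support_vectors, self.config)
        return K @ self.dual_coef + self.bias

    def decision_value(self, x: np.ndarray) -> float:
        return float(self.decision_values(x)[0])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """+1 / -1 class predictions (0 scores resolve to +1)."""
        return np.where(self.decision_values(X) >= 0, 1, -1)

    def primal_weights(self) -> np.ndarray:
        """Explicit weight vector, defined for the linear (d = 1) kernel only."""
        if self.config.degree != 1:
            raise ValueError("primal weights are only explicit for degree 1")
        return self.dual_coef @ self.support_vectors

    def to_dict(self) -> dict:
        return {
            "schema_version": "1.0",
            "config": {"degree": self.config.degree, "C": self.config.C, "coef0": self.config.coef0},
            "scheme": self.scheme,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "bias": self.bias,
            "n_train_pos": self.n_train_pos,
            "n_train_neg": self.n_train_neg,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SVMModel":
        major = str(payload.get("schema_version", "1.0")).split(".")[0]
        if int(major) > 1:
            raise ValueError(f"model schema version {payload['schema_version']} is newer than supported")
        cfg = payload["config"]
        return cls(
            support_vectors=np.asarray(payload["support_vectors"], dtype=float),
            dual_coef=np.asarray(payload["dual_coef"], dtype=float),
            bias=float(payload["bias"]),
            config=SVMConfig(cfg["degree"], cfg["C"], cfg.get("coef0", 1.0)),
            scheme=payload.get("scheme", "full20"),
            n_train_pos=payload.get("n_train_pos", 0),
            n_train_neg=payload.get("n_train_neg", 0),
        )


def train(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    config: SVMConfig = SVMConfig(),
    seed: int = 0,
    scheme: str = "full20",
    tol: float = 1e-3,
) -> SVMModel:
    """Fit a soft-margin polynomial SVM on encoded positive/negative peptides.

    The libsvm solution is deterministic for fixed inputs; ``seed`` fixes
    the (otherwise irrelevant) internal state for reproducibility of any
    tie-dependent paths.
    """
    X_pos = np.atleast_2d(np.asarray(X_pos, dtype=float))
    X_neg = np.atleast_2d(np.asarray(X_neg, dtype=float))
    if len(X_pos) == 0 or len(X_neg) == 0:
        raise ValueError("training requires at least one instance of each class")
    X = np.vstack([X_pos, X_neg])
    y = np.concatenate([np.ones(len(X_pos)), -np.ones(len(X_neg))])
    clf = SVC(
        kernel="poly",
        degree=config.degree,
        C=config.C,
        coef0=config.coef0,
        gamma=1.0,
        tol=tol,
        cache_size=200,
        random_state=seed,
    )
    clf.fit(X, y)
    # libsvm orders classes ascending (-1, +1); dual_coef_ is alpha_i * y_i
    return SVMModel(
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        config=config,
        scheme=scheme,
        n_train_pos=int(len(X_pos)),
        n_train_neg=int(len(X_neg)),
    )
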