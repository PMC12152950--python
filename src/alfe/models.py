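"""Surrogate regressors for affinity prediction on binary fingerprints.

Three algorithm families mirror the screening model zoo: ordinary/ridge
linear regression, random forests, and Gaussian-process regression with the
Tanimoto kernel

    k(x, y) = <x, y> / (|x|^2 + |y|^2 - <x, y>)

on binary bit vectors, which equals the Tanimoto similarity of the on-bit
sets.  The GP and ridge models expose exact closed-form leave-one-out
predictions (O(n^3) once, instead of n refits), used by model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression


def tanimoto_kernel(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Tanimoto (MinMax on binaries) kernel matrix between fingerprint rows."""
    xa = np.asarray(xa, dtype=np.float64)
    xb = np.asarray(xb, dtype=np.float64)
    inner = xa @ xb.T
    na = np.einsum("ij,ij->i", xa, xa)[:, None]
    nb = np.einsum("ij,ij->i", xb, xb)[None, :]
    denom = na + nb - inner
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(denom > 0, inner / np.maximum(denom, 1e-300), 1.0)
    return k


class TanimotoGP:
    """GP regression with a Tanimoto-plus-constant kernel and noise.

    The kernel is k(x, y) = T(x, y) + bias, where the constant component
    absorbs the overall affinity level (equivalent to a random offset with
    prior variance ``bias``), so the prior mean is zero and the exact
    closed-form leave-one-out identity applies.  ``noise`` is the diagonal
    jitter sigma_n^2 added to the Gram matrix.
    """

    def __init__(self, noise: float = 1e-2, bias: float = 10.0) -> None:
        self.noise = float(noise)
        self.bias = float(bias)
        self._x: np.ndarray | None = None
        self._alpha: np.ndarray | None = None

    def _gram(self, x: np.ndarray) -> np.ndarray:
        return tanimoto_kernel(x, x) + self.bias + self.noise * np.eye(len(x))

    def fit(self, x: np.ndarray, y: np.ndarray) -> "TanimotoGP":
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        self._x = x
        cho = cho_factor(self._gram(x), lower=True)
        self._alpha = cho_solve(cho, y)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("model is not fitted")
        k_star = tanimoto_kernel(np.asarray(x, float), self._x) + self.bias
        return k_star @ self._alpha

    def loo_predictions(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Exact leave-one-out predictions via the standard GP identity:
        mu_{-i} = y_i - alpha_i / (K + sigma^2 I)^{-1}_{ii}."""
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        n = len(x)
        cho = cho_factor(self._gram(x), lower=True)
        alpha = cho_solve(cho, y)
        kinv_diag = np.diag(cho_solve(cho, np.eye(n)))
        return y - alpha / kinv_diag


class RidgeOnBits:
    """Linear regression on bit vectors, ridge-regularized in dual form.

    A constant bias feature of value ``bias_scale`` is appended so the
    intercept is learned inside the (lightly penalized) linear model; the
    dual form keeps the linear algebra n x n even for 2048-bit inputs and
    gives the closed-form LOO residual e_i / (1 - h_ii) with the smoother
    H = K (K + lambda I)^{-1}, K = X X^T.  alpha = 0 requests ordinary least
    squares (scikit-learn, with intercept); its LOO then falls back to
    explicit refits in the caller because the hat-matrix identity fails for
    interpolating fits.
    """

    def __init__(self, alpha: float = 1.0, bias_scale: float = 10.0) -> None:
        self.alpha = float(alpha)
        self.bias_scale = float(bias_scale)
        self._x: np.ndarray | None = None
        self._dual: np.ndarray | None = None
        self._ols: LinearRegression | None = None

    @property
    def supports_fast_loo(self) -> bool:
        return self.alpha > 0

    def _augment(self, x: np.ndarray) -> np.ndarray:
        return np.hstack([x, np.full((len(x), 1), self.bias_scale)])

    def fit(self, x: np.ndarray, y: np.ndarray) -> "RidgeOnBits":
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if self.alpha <= 0:
            self._ols = LinearRegression().fit(x, y)
            return self
        self._x = self._augment(x)
        k = self._x @ self._x.T + self.alpha * np.eye(len(x))
        self._dual = np.linalg.solve(k, y)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if self._ols is not None:
            return self._ols.predict(x)
        if self._x is None:
            raise RuntimeError("model is not fitted")
        return (self._augment(x) @ self._x.T) @ self._dual

    def loo_predictions(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if not self.supports_fast_loo:
            raise RuntimeError("closed-form LOO requires alpha > 0")
        xa = self._augment(np.asarray(x, dtype=np.float64))
        y = np.asarray(y, dtype=np.float64)
        n = len(xa)
        k = xa @ xa.T
        ainv = np.linalg.inv(k + self.alpha * np.eye(n))
        h = k @ ainv
        resid = y - h @ y
        denom = 1.0 - np.diag(h)
        denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
        return y - resid / denom


@dataclass
class ModelSpec:
    """One cell of the AutoML grid with its tuned hyperparameters and score."""

    representation: str
    algorithm: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    cv_r2: float = float("-inf")


ALGORITHMS = ("linear_regression", "random_forest", "gp_tanimoto")

# Hyperparameter grids searched by inner 5-fold CV, in declared order.
HYPERPARAMETER_GRIDS: dict[str, list[dict[str, Any]]] = {
    "linear_regression": [{"alpha": 0.0}, {"alpha": 1.0}],
    "random_forest": [
        {"n_estimators": 100, "max_depth": None},
        {"n_estimators": 100, "max_depth": 10},
        {"n_estimators": 500, "max_depth": None},
        {"n_estimators": 500, "max_depth": 10},
    ],
    "gp_tanimoto": [{"noise": 1e-4}, {"noise": 1e-2}, {"noise": 1e-1}],
}


def make_model(algorithm: str, hyperparameters: dict[str, Any], seed: int = 0):
    """Instantiate an unfitted regressor for a grid cell."""
    if algorithm == "linear_regression":
        return RidgeOnBits(alpha=hyperparameters.get("alpha", 0.0))
    if algorithm == "random_forest":
        return RandomForestRegressor(
            n_estimators=hyperparameters.get("n_estimators", 100),
            max_depth=hyperparameters.get("max_depth"),
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "gp_tanimoto":
        return TanimotoGP(noise=hyperparameters.get("noise", 1e-2))
    raise ValueError(f"unknown algorithm {algorithm!r}")
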