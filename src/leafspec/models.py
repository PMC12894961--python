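"""Regression models: single-response PLSR (NIPALS) and linear-kernel SVR.

PLSR handles the p >> n, highly collinear predictor structure of leaf
reflectance by extracting mutually orthogonal latent components — linear
combinations of wavelengths chosen to covary with the response.  The number
of components (NoC) is the model's single complexity hyperparameter; a
fitted model exposes the coefficient vector for *any* NoC up to the fitted
maximum, so calibration over an NoC grid needs one fit per training set.

The implementation is the NIPALS deflation algorithm for a univariate
response: at each step the weight vector w_k ∝ X_k'y_k, score t_k = X_k w_k,
loadings p_k = X_k't_k / t_k't_k and q_k = y_k't_k / t_k't_k, followed by
deflation X_{k+1} = X_k - t_k p_k', y_{k+1} = y_k - q_k t_k.  Coefficients
on the original predictor scale come from the rotation
r_k = w_k - Σ_{j<k} (p_j'w_k) r_j, β_K = Σ_{k≤K} r_k q_k.  Component
extraction stops early once the deflated X is numerically exhausted, so NoC
grids larger than the data rank are safe.

Linear SVR (ε-insensitive loss, regularization C) delegates the convex
optimisation to scikit-learn's libsvm binding; predictors and response are
standardized internally and the fitted function is reported as an affine
map on the original scales.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVR as _SkSVR

_DEFLATION_TOL = 1e-12


@dataclass
class PLSRModel:
    """Fitted PLSR model supporting prediction at any k <= n_components."""

    x_mean: np.ndarray
    x_scale: np.ndarray | None
    y_mean: float
    weights: np.ndarray      # p x K
    x_loadings: np.ndarray   # p x K
    y_loadings: np.ndarray   # K
    rotation: np.ndarray     # p x K
    scores: np.ndarray       # n x K (training scores, kept for diagnostics)
    max_components: int      # requested upper bound
    n_components: int        # effective (may be < requested on rank-deficient X)

    def coefficients(self, k: int) -> tuple[np.ndarray, float]:
        """Coefficient vector and intercept for a k-component model,
        expressed on the original (unscaled) predictor scale."""
        self._check_k(k)
        k_eff = min(k, self.n_components)
        beta = self.rotation[:, :k_eff] @ self.y_loadings[:k_eff]
        if self.x_scale is not None:
            beta = beta / self.x_scale
        intercept = self.y_mean - float(self.x_mean @ beta)
        return beta, intercept

    def predict(self, X_new: np.ndarray, k: int) -> np.ndarray:
        beta, intercept = self.coefficients(k)
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        if X_new.shape[1] != self.x_mean.shape[0]:
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, model expects "
                f"{self.x_mean.shape[0]}"
            )
        return X_new @ beta + intercept

    def predict_components(self, X_new: np.ndarray) -> np.ndarray:
        """m x n_components matrix of predictions for every k at once.

        Column k-1 holds the k-component prediction; used by calibration to
        score a whole NoC grid from a single fit.
        """
        X_new = np.asarray(X_new, dtype=float)
        Xc = X_new - self.x_mean
        if self.x_scale is not None:
            Xc = Xc / self.x_scale
        if self.n_components == 0:
            return np.full((X_new.shape[0], 1), self.y_mean)
        contrib = (Xc @ self.rotation) * self.y_loadings
        return np.cumsum(contrib, axis=1) + self.y_mean

    def _check_k(self, k: int) -> None:
        if not 1 <= k <= self.max_components:
            raise ValueError(
                f"k={k} outside [1, {self.max_components}] "
                f"(effective components: {self.n_components})"
            )

    def to_dict(self) -> dict:
        return {
            "model": "plsr",
            "x_mean": self.x_mean.tolist(),
            "x_scale": None if self.x_scale is None else self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "rotation": self.rotation.tolist(),
            "scores": self.scores.tolist(),
            "max_components": self.max_components,
            "n_components": self.n_components,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSRModel":
        return cls(
            x_mean=np.asarray(d["x_mean"], float),
            x_scale=None if d["x_scale"] is None else np.asarray(d["x_scale"], float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], float),
            x_loadings=np.asarray(d["x_loadings"], float),
            y_loadings=np.asarray(d["y_loadings"], float),
            rotation=np.asarray(d["rotation"], float),
            scores=np.asarray(d["scores"], float),
            max_components=int(d["max_components"]),
            n_components=int(d["n_components"]),
        )


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    max_noc: int,
    scale: bool = False,
) -> PLSRModel:
    """Fit PLSR by NIPALS with mean-centering (optionally unit-variance
    scaling) of X and centering of y.

    A constant response yields a zero-coefficient model whose prediction is
    mean(y) at every k.  Extraction stops early when the deflated predictor
    matrix falls below 1e-12 of its initial Frobenius norm.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if y.shape[0] != n:
        raise ValueError("X and y length mismatch")
    if not 1 <= max_noc <= min(n - 1, p):
        raise ValueError(
            f"max_noc={max_noc} outside [1, {min(n - 1, p)}] for n={n}, p={p}"
        )

    x_mean = X.mean(axis=0)
    Xd = X - x_mean
    x_scale = None
    if scale:
        x_scale = Xd.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0
        Xd = Xd / x_scale
    if not np.any(Xd.std(axis=0) > 0):
        raise ValueError("all predictor columns are constant")
    y_mean = float(y.mean())
    yd = y - y_mean

    W = np.zeros((p, max_noc))
    P = np.zeros((p, max_noc))
    Q = np.zeros(max_noc)
    R = np.zeros((p, max_noc))
    T = np.zeros((n, max_noc))

    x_norm0 = np.linalg.norm(Xd)
    y_scale0 = np.linalg.norm(yd)
    k = 0
    if y_scale0 > 0:
        for k_i in range(max_noc):
            if np.linalg.norm(Xd) < _DEFLATION_TOL * x_norm0:
                break
            w = Xd.T @ yd
            w_norm = np.linalg.norm(w)
            if w_norm < _DEFLATION_TOL * x_norm0 * y_scale0:
                break
            w /= w_norm
            t = Xd @ w
            tt = float(t @ t)
            if tt < (_DEFLATION_TOL * x_norm0) ** 2:
                break
            p_load = (Xd.T @ t) / tt
            q = float(yd @ t) / tt
            Xd = Xd - np.outer(t, p_load)
            yd = yd - q * t
            r = w - R[:, :k_i] @ (P[:, :k_i].T @ w)
            W[:, k_i], P[:, k_i], Q[k_i], R[:, k_i], T[:, k_i] = w, p_load, q, r, t
            k = k_i + 1

    return PLSRModel(
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        weights=W[:, :k],
        x_loadings=P[:, :k],
        y_loadings=Q[:k],
        rotation=R[:, :k],
        scores=T[:, :k],
        max_components=max_noc,
        n_components=k,
    )


def plsr_predict(model: PLSRModel, X_new: np.ndarray, k: int) -> np.ndarray:
    """Predict with a k-component model on the original response scale."""
    return model.predict(X_new, k)


@dataclass
class SVRModel:
    """Fitted linear SVR: an affine function of the input spectrum."""

    coef: np.ndarray
    intercept: float
    C: float
    epsilon: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[None, :]
        return X_new @ self.coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "model": "linear_svr",
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "C": self.C,
            "epsilon": self.epsilon,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SVRModel":
        return cls(
            coef=np.asarray(d["coef"], float),
            intercept=float(d["intercept"]),
            C=float(d["C"]),
            epsilon=float(d["epsilon"]),
            x_mean=np.asarray(d["x_mean"], float),
            x_scale=np.asarray(d["x_scale"], float),
            y_mean=float(d["y_mean"]),
            y_scale=float(d["y_scale"]),
        )


def fit_linear_svr(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    epsilon: float = 0.1,
    tol: float = 1e-8,
) -> SVRModel:
    """Fit ε-insensitive linear SVR; ε is interpreted on the standardized
    response scale (default 0.1), so only C needs tuning.

    Predictors are standardized to unit variance internally; the returned
    coefficients act on the original scales.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    if epsilon < 0:
        raise ValueError(f"epsilon must be nonnegative, got {epsilon}")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1)
    x_scale[x_scale == 0] = 1.0
    y_mean = float(y.mean())
    y_scale = float(y.std(ddof=1))
    if y_scale == 0:
        # constant response: the flat function is optimal
        return SVRModel(
            coef=np.zeros(p), intercept=y_mean, C=C, epsilon=epsilon,
            x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=1.0,
        )
    Xs = (X - x_mean) / x_scale
    ys = (y - y_mean) / y_scale

    svr = _SkSVR(kernel="linear", C=C, epsilon=epsilon, tol=tol, max_iter=200_000)
    with warnings.catch_warnings():
        # the iteration cap bounds solver effort on near-degenerate folds
        # (e.g. very small C); the fit is already at working accuracy there
        warnings.simplefilter("ignore", ConvergenceWarning)
        svr.fit(Xs, ys)
    w_std = np.asarray(svr.coef_).ravel()
    b_std = float(svr.intercept_[0])

    coef = y_scale * w_std / x_scale
    intercept = y_mean + y_scale * b_std - float(coef @ x_mean)
    return SVRModel(
        coef=coef, intercept=intercept, C=C, epsilon=epsilon,
        x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
    )
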