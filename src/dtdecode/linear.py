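"""Ordinary least squares decoding of a continuous target.

The linear decoder estimates beta_hat = (X'X)^{-1} X'y on the training design
matrix and predicts y_hat = X beta_hat out of sample. No intercept column is
added: the acquisition-site indicator block spans the constant vector, so the
model is estimable without one. The Gram inverse, residual variance
sigma2_hat = RSS / (n - p) and residual degrees of freedom are retained for
coefficient inference.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_X_y

__all__ = ["OLSRegressor", "fit_ols", "predict_ols"]

# relative reciprocal-condition threshold below which the Gram matrix is
# treated as singular
_RCOND = 1e-10


class OLSRegressor(RegressorMixin, BaseEstimator):
    """Multiple linear regression via the normal equations.

    Attributes
    ----------
    coef_ : ndarray of shape (p,)
        Estimated regression coefficients beta_hat.
    gram_inverse_ : ndarray of shape (p, p)
        (X'X)^{-1}, used for coefficient standard errors.
    sigma2_ : float
        Residual variance estimate RSS / (n - p); NaN when n <= p.
    df_ : int
        Residual degrees of freedom n - p.
    """

    def fit(self, X, y) -> "OLSRegressor":
        X, y = check_X_y(X, y, y_numeric=True)
        n, p = X.shape
        gram = X.T @ X
        # symmetric eigendecomposition doubles as the singularity check and
        # names the columns involved in any collinearity
        eigvals, eigvecs = scipy.linalg.eigh(gram)
        scale = float(eigvals[-1]) if eigvals[-1] > 0 else 0.0
        if scale == 0.0 or eigvals[0] <= _RCOND * scale:
            null_vec = np.abs(eigvecs[:, 0])
            involved = np.flatnonzero(null_vec > 0.1 * null_vec.max())
            raise np.linalg.LinAlgError(
                "singular Gram matrix: columns "
                f"{involved.tolist()} are collinear (or X has rank < p)"
            )
        gram_inv = eigvecs @ ((1.0 / eigvals)[:, None] * eigvecs.T)
        self.gram_inverse_ = (gram_inv + gram_inv.T) / 2.0
        self.coef_ = scipy.linalg.solve(gram, X.T @ y, assume_a="pos")
        residuals = y - X @ self.coef_
        self.df_ = n - p
        self.sigma2_ = (
            float(residuals @ residuals) / self.df_ if self.df_ >= 1 else float("nan")
        )
        self.n_features_in_ = p
        return self

    # alias matching the beta_hat notation used throughout the docs
    @property
    def beta_(self) -> np.ndarray:
        return self.coef_

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise AttributeError("OLSRegressor is not fitted")
        X = check_array(X)
        if X.shape[1] != self.coef_.shape[0]:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {self.coef_.shape[0]}"
            )
        return X @ self.coef_


def fit_ols(X, y) -> OLSRegressor:
    """Fit beta_hat = (X'X)^{-1} X'y; returns the fitted estimator."""
    return OLSRegressor().fit(X, y)


def predict_ols(fit: OLSRegressor, X) -> np.ndarray:
    """Predict y_hat = X beta_hat."""
    return fit.predict(X)
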