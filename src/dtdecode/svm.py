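"""Support vector regression decoder.

Epsilon-insensitive SVR with a linear kernel and internal feature
standardization. Defaults follow the convention epsilon = C = IQR(y)/13.49
(IQR/1.349 estimates the target's standard deviation robustly; the extra
factor of 10 keeps the tube narrow relative to the target spread). A constant
training target (IQR = 0 with zero variance) degenerates to predicting that
constant.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.utils.validation import check_array, check_X_y

__all__ = ["SVRDecoder", "fit_svr", "predict_svr"]


class SVRDecoder(RegressorMixin, BaseEstimator):
    """Epsilon-insensitive support vector regression with feature scaling.

    Parameters
    ----------
    kernel : str, default "linear"
    C : float or None
        Box constraint; None selects IQR(y)/13.49 at fit time.
    epsilon : float or None
        Insensitivity-tube half width; None selects IQR(y)/13.49.
    standardize : bool, default True
        Standardize features (zero-variance columns are passed through
        unscaled) before the kernel.
    tol : float, default 1e-3
        Solver stopping tolerance.
    """

    def __init__(self, kernel: str = "linear", C: float | None = None,
                 epsilon: float | None = None, standardize: bool = True,
                 tol: float = 1e-3) -> None:
        self.kernel = kernel
        self.C = C
        self.epsilon = epsilon
        self.standardize = standardize
        self.tol = tol

    def fit(self, X, y) -> "SVRDecoder":
        X, y = check_X_y(X, y, y_numeric=True)
        iqr = float(np.subtract(*np.percentile(y, [75, 25])))
        scale = iqr / 13.49
        self.constant_ = None
        if np.ptp(y) == 0.0:
            self.constant_ = float(y[0])
            self.n_features_in_ = X.shape[1]
            return self
        if scale == 0.0:
            # degenerate IQR with non-constant y: fall back to target SD
            scale = float(np.std(y, ddof=1)) / 1.349
        self.C_ = self.C if self.C is not None else scale
        self.epsilon_ = self.epsilon if self.epsilon is not None else scale
        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            X = self.scaler_.transform(X)
        else:
            self.scaler_ = None
        self.svr_ = SVR(kernel=self.kernel, C=self.C_, epsilon=self.epsilon_,
                        tol=self.tol)
        self.svr_.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "constant_"):
            raise AttributeError("SVRDecoder is not fitted")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, model expects {self.n_features_in_}"
            )
        if self.constant_ is not None:
            return np.full(X.shape[0], self.constant_)
        if self.scaler_ is not None:
            X = self.scaler_.transform(X)
        return self.svr_.predict(X)


def fit_svr(X, y, **hyperparams) -> SVRDecoder:
    """Calibrate an SVR decoder on training data."""
    return SVRDecoder(**hyperparams).fit(X, y)


def predict_svr(fit: SVRDecoder, X) -> np.ndarray:
    return fit.predict(X)
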