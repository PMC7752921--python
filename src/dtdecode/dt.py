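"""Distributional transformation (DT) of predictions.

DT is a rank-preserving post-processing step for out-of-sample prediction of a
continuous variable. Each predicted value is replaced by the reference-sample
(training-set) quantile at the predicted value's own empirical-CDF level:

    y_tilde_i = F_ref^{-1}( F_pred(y_hat_i) )

where ``F_pred`` is the empirical CDF of the predictions and ``F_ref^{-1}`` is
the generalized-inverse empirical quantile function of the reference sample
(the training-set target values). DT preserves the complete ordering of the
predictions but replaces their distribution by the reference distribution, so
transformed predictions always lie inside the observed reference range.

When the number of predictions equals the reference sample size and the
predictions are distinct, the output is exactly a permutation of the reference
sample: the i-th smallest prediction maps to the i-th reference order
statistic. Both equalities are exact here because the quantile index is
computed in integer arithmetic.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["EmpiricalCDF", "DistributionalTransformer", "distributional_transform"]


def _as_clean_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains NaN or infinite values")
    return arr


class EmpiricalCDF:
    """Right-continuous empirical CDF with generalized-inverse quantiles.

    F(t) = (1/n) * #{i : x_i <= t}; the quantile function is the generalized
    inverse F^{-1}(q) = min{x in sample : F(x) >= q}, defined on (0, 1], with
    no interpolation between order statistics — F^{-1}(F(x_i)) = x_i whenever
    the sample values are distinct.
    """

    def __init__(self, sample) -> None:
        sample = _as_clean_1d(sample, "sample")
        self.support = np.sort(sample)
        self.n = int(self.support.size)

    def __call__(self, t):
        """Evaluate F at scalar or array ``t``."""
        counts = np.searchsorted(self.support, t, side="right")
        return counts / self.n

    def quantile(self, q):
        """Generalized-inverse quantile at ``q`` in (0, 1]."""
        q = np.asarray(q, dtype=float)
        if np.any(q <= 0.0) or np.any(q > 1.0):
            raise ValueError("quantile level must lie in (0, 1]")
        # small backoff guards against k/n * n rounding up past k
        idx = np.ceil(q * self.n - 1e-9).astype(int) - 1
        result = self.support[np.clip(idx, 0, self.n - 1)]
        return result if result.ndim else float(result)


def _transform(predictions: np.ndarray, reference_sorted: np.ndarray,
               interpolate: bool) -> np.ndarray:
    n_pred = predictions.size
    n_ref = reference_sorted.size
    # integer ECDF level: k_i = #{predictions <= y_hat_i}
    order = np.sort(predictions)
    k = np.searchsorted(order, predictions, side="right")
    if interpolate:
        return np.quantile(reference_sorted, k / n_pred, method="linear")
    # generalized inverse: index ceil(k * n_ref / n_pred) - 1, exactly
    idx = -((-k * n_ref) // n_pred) - 1
    return reference_sorted[idx]


class DistributionalTransformer(TransformerMixin, BaseEstimator):
    """Map predictions onto a reference sample's empirical distribution.

    ``fit`` learns the reference distribution (typically the training-set
    target values); ``transform`` remaps a vector of predictions so that its
    empirical CDF matches the reference while the ranks of the predictions are
    preserved.

    Parameters
    ----------
    interpolate : bool, default False
        If True, interpolate linearly between reference order statistics
        instead of using the generalized inverse. Smoother outputs when the
        two sample sizes differ, at the cost of the exact equal-n permutation
        property.
    jitter : bool, default False
        If True, break ties among predictions with infinitesimal seeded noise
        before ranking. By default tied predictions share one ECDF level and
        therefore map to identical transformed values.
    random_state : int or None
        Seed for the jitter noise.

    Attributes
    ----------
    reference_ecdf_ : EmpiricalCDF
        Empirical CDF of the reference sample.
    n_reference_ : int
    """

    def __init__(self, interpolate: bool = False, jitter: bool = False,
                 random_state: int | None = None) -> None:
        self.interpolate = interpolate
        self.jitter = jitter
        self.random_state = random_state

    def fit(self, X, y=None) -> "DistributionalTransformer":
        reference = _as_clean_1d(X, "reference")
        self.reference_ecdf_ = EmpiricalCDF(reference)
        self.n_reference_ = self.reference_ecdf_.n
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "reference_ecdf_"):
            raise AttributeError("DistributionalTransformer is not fitted")
        predictions = _as_clean_1d(X, "predictions")
        if self.jitter:
            rng = np.random.default_rng(self.random_state)
            span = np.ptp(predictions) or 1.0
            predictions = predictions + rng.uniform(
                -1e-9, 1e-9, size=predictions.shape) * span
        return _transform(predictions, self.reference_ecdf_.support,
                          self.interpolate)


def distributional_transform(predictions, reference, *, interpolate: bool = False,
                             jitter: bool = False,
                             random_state: int | None = None) -> np.ndarray:
    """Functional form: DT of ``predictions`` onto ``reference``'s distribution."""
    transformer = DistributionalTransformer(
        interpolate=interpolate, jitter=jitter, random_state=random_state)
    return transformer.fit(reference).transform(predictions)
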