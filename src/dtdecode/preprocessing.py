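"""Column-wise z-scoring that leaves indicator regressors untouched.

Non-indicator design-matrix columns (region means) are mean-subtracted and
divided by their sample standard deviation (ddof=1); 0/1 site indicators and
the +1/-1 gender regressor pass through bit-identically. By convention the
validation design matrix is scaled by *its own* statistics (fit_transform on
each matrix separately); scaling by training statistics instead is a caller
choice, supported by fitting once and calling transform on both matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array

__all__ = ["ScalingParams", "ColumnZScorer", "zscore_columns"]


@dataclass
class ScalingParams:
    """Per-column mean/SD used for scaling, plus the pass-through mask."""

    mean: np.ndarray
    sd: np.ndarray
    indicator_mask: np.ndarray


class ColumnZScorer(TransformerMixin, BaseEstimator):
    """Z-score selected columns, pass indicator columns through unchanged.

    Parameters
    ----------
    indicator_mask : boolean array of shape (p,) or None
        Columns marked True are left untouched. None scales every column.
    ddof : int, default 1
        Delta degrees of freedom for the standard deviation (sample SD).
    """

    def __init__(self, indicator_mask=None, ddof: int = 1) -> None:
        self.indicator_mask = indicator_mask
        self.ddof = ddof

    def fit(self, X, y=None) -> "ColumnZScorer":
        X = check_array(X)
        p = X.shape[1]
        if self.indicator_mask is None:
            mask = np.zeros(p, dtype=bool)
        else:
            mask = np.asarray(self.indicator_mask, dtype=bool)
            if mask.shape != (p,):
                raise ValueError("indicator_mask length must equal column count")
        scaled = ~mask
        mean = np.zeros(p)
        sd = np.ones(p)
        mean[scaled] = X[:, scaled].mean(axis=0)
        sd[scaled] = X[:, scaled].std(axis=0, ddof=self.ddof)
        zero_sd = np.flatnonzero(scaled & (sd == 0.0))
        if zero_sd.size:
            raise ValueError(
                f"columns {zero_sd.tolist()} selected for scaling have zero "
                "standard deviation"
            )
        self.scaling_ = ScalingParams(mean=mean, sd=sd, indicator_mask=mask)
        self.n_features_in_ = p
        return self

    def transform(self, X) -> np.ndarray:
        X = check_array(X)
        params = self.scaling_
        out = X.copy()
        scaled = ~params.indicator_mask
        out[:, scaled] = (X[:, scaled] - params.mean[scaled]) / params.sd[scaled]
        return out

    def inverse_transform(self, X) -> np.ndarray:
        X = check_array(X)
        params = self.scaling_
        out = X.copy()
        scaled = ~params.indicator_mask
        out[:, scaled] = X[:, scaled] * params.sd[scaled] + params.mean[scaled]
        return out


def zscore_columns(X, indicator_mask=None, ddof: int = 1):
    """Z-score non-indicator columns of ``X``; returns (matrix, ScalingParams)."""
    scorer = ColumnZScorer(indicator_mask=indicator_mask, ddof=ddof)
    transformed = scorer.fit_transform(X)
    return transformed, scorer.scaling_
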