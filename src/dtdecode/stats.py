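"""Performance measures and statistical comparisons for age decoding.

Covers the standard accuracy measures (R^2, adjusted R^2, Pearson r,
Spearman r, MAE, RMSE, and the rank correlation of the prediction error with
the target — "objective 2"), paired Wilcoxon signed-rank comparison of
absolute errors between two prediction methods, empirical Kullback-Leibler
divergence between binned age distributions, the two-sample
Kolmogorov-Smirnov test, and normal-theory inference on OLS regression
coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .linear import OLSRegressor

__all__ = [
    "MetricsReport",
    "ComparisonResult",
    "CoefficientInference",
    "prediction_metrics",
    "wilcoxon_ae_comparison",
    "empirical_kl",
    "ks_two_sample",
    "coefficient_inference",
]


@dataclass
class MetricsReport:
    """The seven accuracy measures; undefined entries are NaN.

    ``objective2`` is Spearman's rank correlation between the prediction
    error (y - y_hat) and y itself: small magnitude means the error is
    independent of the target (no systematic regression-to-the-mean bias).
    """

    r_squared: float
    adj_r_squared: float
    pearson_r: float
    spearman_r: float
    mae: float
    rmse: float
    objective2: float

    @property
    def undefined(self) -> list[str]:
        """Names of measures that are undefined (NaN) for these inputs."""
        return [k for k, v in self.__dict__.items() if isinstance(v, float)
                and math.isnan(v)]

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass
class ComparisonResult:
    """Distribution-level comparison of two prediction methods."""

    wilcoxon_z: float
    wilcoxon_p: float
    kl_divergence: float
    ks_D: float
    ks_p: float

    def to_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass
class CoefficientInference:
    """Normal-theory inference for one regression coefficient."""

    index: int
    estimate: float
    se: float
    ci_lower: float
    ci_upper: float
    p_value: float
    tier: str = field(default="ns")


def _check_pair(y_true, y_pred, min_n: int = 1):
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    return y_true, y_pred


def prediction_metrics(y_true, y_pred, p_model: int = 1) -> MetricsReport:
    """Compute the full accuracy report for one prediction vector.

    Out-of-sample R^2 = 1 - SS_res/SS_tot may be negative. Adjusted R^2 uses
    ``p_model`` design-matrix columns. Correlation measures are NaN when
    their defining variance vanishes (constant targets or constant errors).
    """
    y_true, y_pred = _check_pair(y_true, y_pred, min_n=3)
    if p_model < 1:
        raise ValueError("p_model must be >= 1")
    n = y_true.size
    err = y_true - y_pred
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err ** 2)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = adj_r2 = pearson = spearman = float("nan")
    else:
        r2 = 1.0 - float(np.sum(err ** 2)) / ss_tot
        adj_r2 = (1.0 - (1.0 - r2) * (n - 1) / (n - p_model - 1)
                  if n - p_model - 1 > 0 else float("nan"))
        if np.ptp(y_pred) == 0.0:
            pearson = spearman = float("nan")
        else:
            pearson = float(scipy.stats.pearsonr(y_true, y_pred).statistic)
            spearman = float(scipy.stats.spearmanr(y_true, y_pred).statistic)
    if np.ptp(err) == 0.0 or np.ptp(y_true) == 0.0:
        objective2 = float("nan")
    else:
        objective2 = float(scipy.stats.spearmanr(err, y_true).statistic)
    return MetricsReport(r_squared=r2, adj_r_squared=adj_r2, pearson_r=pearson,
                         spearman_r=spearman, mae=mae, rmse=rmse,
                         objective2=objective2)


def wilcoxon_ae_comparison(y_true, pred_a, pred_b,
                           exact_max_n: int = 25) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test on absolute errors of two methods.

    Tests |y - pred_a| against |y - pred_b|. The z statistic comes from the
    normal approximation with tie and continuity corrections; by construction z < 0 when
    method A has the smaller absolute errors. Zero differences are dropped
    before ranking. For small samples (n <= ``exact_max_n`` after dropping
    zeros, no ties) the p-value is computed by exact enumeration instead of
    the normal approximation.

    Returns
    -------
    (z, p) : two-sided test.
    """
    y_true, pred_a = _check_pair(y_true, pred_a)
    _, pred_b = _check_pair(y_true, pred_b)
    d = np.abs(y_true - pred_a) - np.abs(y_true - pred_b)
    d = d[d != 0.0]
    m = d.size
    if m == 0:
        return 0.0, 1.0
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var -= float(np.sum(tie_counts ** 3 - tie_counts)) / 48.0
    if var <= 0.0:
        return 0.0, 1.0
    # continuity-corrected normal approximation
    shift = w_plus - mu
    z = ((shift - 0.5 * np.sign(shift)) / math.sqrt(var)) if shift else 0.0
    has_ties = bool(np.any(tie_counts > 1))
    if m <= exact_max_n and not has_ties:
        p = float(scipy.stats.wilcoxon(d, method="exact").pvalue)
    else:
        p = float(2.0 * scipy.stats.norm.sf(abs(z)))
    return float(z), p


def empirical_kl(actual, predicted, bin_width: float = 1.0) -> float:
    """Empirical KL divergence KL(actual || predicted) on shared bins.

    Both samples are histogrammed on bins of ``bin_width`` years aligned to
    integer multiples of the bin width, spanning the union of both ranges.
    KL = sum_b p_b * ln(p_b / q_b) over bins with p_b > 0 (natural log).
    When some bin has p_b > 0 but q_b = 0, the predicted histogram is
    epsilon-smoothed (epsilon = 1 / (10 * (n_p + n_q)) added to every bin,
    then renormalised) so the divergence stays finite; otherwise the raw
    histograms are used, making KL(x, x) exactly zero.
    """
    actual = _as_nonempty(actual, "actual")
    predicted = _as_nonempty(predicted, "predicted")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = math.floor(min(actual.min(), predicted.min()) / bin_width) * bin_width
    hi = math.ceil(max(actual.max(), predicted.max()) / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2.0, bin_width)
    p = np.histogram(actual, bins=edges)[0] / actual.size
    q = np.histogram(predicted, bins=edges)[0] / predicted.size
    if np.any((p > 0) & (q == 0)):
        eps = 1.0 / (10.0 * (actual.size + predicted.size))
        q = q + eps
        q = q / q.sum()
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def _as_nonempty(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D = sup_t |F_a(t) - F_b(t)| with the asymptotic Kolmogorov p-value,
    against the null that both samples come from the same continuous
    distribution.
    """
    a = _as_nonempty(a, "a")
    b = _as_nonempty(b, "b")
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = scipy.stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def coefficient_inference(X, y, alpha: float = 0.10,
                          use_t: bool = False) -> list[CoefficientInference]:
    """Standard errors, confidence intervals and significance tiers for OLS.

    SE(beta_j) = sqrt(sigma2_hat * [(X'X)^{-1}]_{jj}) with
    sigma2_hat = RSS / (n - p); the CI is beta_j +/- SE * z_{1-alpha/2}
    using the standard-normal quantile (alpha = 0.10 gives z = 1.645), or the
    Student-t quantile on n - p degrees of freedom when ``use_t``. Each
    coefficient is tagged with the most stringent significance tier it
    reaches among p < 0.05, p < 0.001 and the Bonferroni level p < 0.05/p.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    n, p = X.shape
    if n <= p:
        raise ValueError(
            f"n = {n} <= p = {p}: residual variance is undefined")
    fit = OLSRegressor().fit(X, y)
    se = np.sqrt(fit.sigma2_ * np.diag(fit.gram_inverse_))
    if use_t:
        crit = float(scipy.stats.t.ppf(1.0 - alpha / 2.0, fit.df_))
        pvals = 2.0 * scipy.stats.t.sf(np.abs(fit.coef_ / se), fit.df_)
    else:
        crit = float(scipy.stats.norm.ppf(1.0 - alpha / 2.0))
        pvals = 2.0 * scipy.stats.norm.sf(np.abs(fit.coef_ / se))
    bonferroni = 0.05 / p
    out = []
    for j in range(p):
        pv = float(pvals[j])
        if pv < bonferroni:
            tier = "p<0.05/p_total"
        elif pv < 0.001:
            tier = "p<0.001"
        elif pv < 0.05:
            tier = "p<0.05"
        else:
            tier = "ns"
        out.append(CoefficientInference(
            index=j, estimate=float(fit.coef_[j]), se=float(se[j]),
            ci_lower=float(fit.coef_[j] - crit * se[j]),
            ci_upper=float(fit.coef_[j] + crit * se[j]),
            p_value=pv, tier=tier))
    return out
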