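"""Negative-binomial dispersion estimation from test-group replicates.

The central modelling choice of the method: tagwise NB dispersions are
estimated *exclusively* from the replicates of the test (treatment) group,
because a sampling bottleneck in the treated sample inflates its variance
far beyond the control group's, and a dispersion pooled across both groups
would land between the two and understate the test-group variance.

The estimation pipeline mirrors the classical count-model lineage:

1. per-barcode dispersion MLE under the intercept-only model with
   size-factor offsets and a Cox-Reid adjustment for the fitted mean;
2. a local (tricube-weighted local linear, i.e. lowess) regression of
   log dispersion on log mean, giving a mean->dispersion trend g(mu);
3. the final dispersion is either the trend value ("trended") or an
   empirical-Bayes MAP estimate shrunk toward the trend under a log-normal
   prior, with outliers (far above the trend) kept at their tagwise MLE
   ("shrunk");
4. barcodes whose mean normalized test count falls below the
   goodness-of-fit threshold beta are assigned the *maximum* tagwise
   dispersion, so that a low-count barcode that escapes independent
   filtering cannot produce a spuriously confident test.

Dispersion floor is 1e-8; per-barcode upper bound max(10, 10/mean).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import gammaln, polygamma
from statsmodels.nonparametric.smoothers_lowess import lowess

from .counts_io import BarcodeCountMatrix, CountMatrixError, SizeFactors

DISPERSION_FLOOR = 1e-8
_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


class DispersionError(ValueError):
    pass


@dataclass
class DispersionSet:
    """Gene-wise MLEs, a mean->dispersion trend, and final dispersions."""

    genewise: np.ndarray
    trend: Callable[[np.ndarray], np.ndarray]
    final: np.ndarray
    method: str
    cap_value: float
    capped_mask: np.ndarray
    allzero_mask: np.ndarray
    means_test: np.ndarray
    outlier_mask: np.ndarray | None = None
    prior_var: float | None = None


# ---------------------------------------------------------------------------
# Vectorized profile likelihood machinery
# ---------------------------------------------------------------------------

def _profile_mean(K, s, alpha, n_iter=12):
    """MLE of the intercept q (mu_j = q * s_j) at fixed dispersion, by Newton
    on log q.  Vectorized over barcodes (rows of K)."""
    q = np.maximum(K.sum(axis=1) / s.sum(), 1e-12)
    logq = np.log(q)
    for _ in range(n_iter):
        mu = np.exp(logq)[:, None] * s[None, :]
        denom = 1.0 + alpha[:, None] * mu
        score = ((K - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-300)
        logq = logq + np.clip(step, -5.0, 5.0)
    return np.exp(logq)


def _nb_loglik(K, mu, alpha):
    """NB log-likelihood, summed over replicates; vectorized over barcodes."""
    a = alpha[:, None]
    r = 1.0 / a
    mu = np.maximum(mu, 1e-300)
    ll = (
        gammaln(K + r) - gammaln(r) - gammaln(K + 1.0)
        - r * np.log1p(a * mu)
        + K * (np.log(mu) + np.log(a) - np.log1p(a * mu))
    )
    return ll.sum(axis=1)


def _cr_adjusted_loglik(K, s, alpha, log_trend=None, prior_var=None):
    """Cox-Reid-adjusted profile log-likelihood at dispersion ``alpha``,
    optionally with a log-normal prior penalty centered at ``log_trend``."""
    q = _profile_mean(K, s, alpha)
    mu = q[:, None] * s[None, :]
    w = mu / (1.0 + alpha[:, None] * mu)
    ll = _nb_loglik(K, mu, alpha) - 0.5 * np.log(np.maximum(w.sum(axis=1), 1e-300))
    if log_trend is not None:
        ll = ll - (np.log(alpha) - log_trend) ** 2 / (2.0 * prior_var)
    return ll


def _golden_max(K, s, lo, hi, log_trend=None, prior_var=None, tol=1e-6):
    """Elementwise golden-section maximization of the (penalized) CR
    likelihood on log-dispersion intervals [lo, hi]."""
    a, b = lo.copy(), hi.copy()
    x1 = b - _GOLDEN * (b - a)
    x2 = a + _GOLDEN * (b - a)
    f1 = _cr_adjusted_loglik(K, s, np.exp(x1), log_trend, prior_var)
    f2 = _cr_adjusted_loglik(K, s, np.exp(x2), log_trend, prior_var)
    for _ in range(60):
        mr = f1 < f2  # maximum lies to the right of x1
        a = np.where(mr, x1, a)
        b = np.where(mr, b, x2)
        x1n = np.where(mr, x2, b - _GOLDEN * (b - a))
        x2n = np.where(mr, a + _GOLDEN * (b - a), x1)
        new_x = np.where(mr, x2n, x1n)
        fnew = _cr_adjusted_loglik(K, s, np.exp(new_x), log_trend, prior_var)
        f1, f2 = np.where(mr, f2, fnew), np.where(mr, fnew, f1)
        x1, x2 = x1n, x2n
        if (b - a).max() < tol:
            break
    return np.exp((a + b) / 2.0)


def fit_genewise_dispersions(
    counts_test: BarcodeCountMatrix, sf: SizeFactors | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-barcode Cox-Reid-adjusted NB dispersion MLE (intercept model).

    Returns ``(alpha_hat, allzero_mask)``; barcodes with all-zero test counts
    get the floor dispersion and a flag.
    """
    K = counts_test.counts.astype(float)
    s = np.asarray(sf, dtype=float)
    if K.shape[1] < 2:
        raise DispersionError("dispersion requires >=2 test replicates")
    if len(s) != K.shape[1]:
        raise CountMatrixError("size factors do not match test samples")
    allzero = (K == 0).all(axis=1)
    alpha = np.full(K.shape[0], DISPERSION_FLOOR)
    nz = ~allzero
    if nz.any():
        Knz = K[nz]
        mean_norm = (Knz / s[None, :]).mean(axis=1)
        amax = np.maximum(10.0, 10.0 / mean_norm)
        lo = np.full(Knz.shape[0], np.log(DISPERSION_FLOOR))
        hi = np.log(amax)
        alpha[nz] = _golden_max(Knz, s, lo, hi)
    return np.clip(alpha, DISPERSION_FLOOR, None), allzero


def fit_windowed_common_dispersions(
    counts_test: BarcodeCountMatrix,
    sf: SizeFactors | np.ndarray,
    window: int = 100,
    step: int | None = None,
    min_usable: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Common-dispersion MLEs in sliding windows of mean-ordered barcodes.

    Each window of ``window`` barcodes (sorted by mean normalized count)
    contributes one CR-adjusted maximum-likelihood estimate of a dispersion
    *shared* by its member barcodes (individual means profiled out).  With
    few replicates this pools roughly ``window`` residual degrees of freedom
    per estimate, sidestepping the instability of per-barcode MLEs at
    n = 2-3, and directly traces the local mean-dispersion relation.

    Returns ``(window_means, window_alphas)`` ordered by mean; all-zero
    barcodes are excluded within windows, and windows with fewer than
    ``min_usable`` informative barcodes are skipped.
    """
    K = counts_test.counts.astype(float)
    s = np.asarray(sf, dtype=float)
    if step is None:
        step = max(window // 2, 1)
    means = (K / s[None, :]).mean(axis=1)
    order = np.argsort(means, kind="stable")
    K_sorted = K[order]
    means_sorted = means[order]
    out_m, out_a = [], []
    lo = np.log(DISPERSION_FLOOR)
    for start in range(0, max(len(means) - window + 1, 1), step):
        blk = K_sorted[start:start + window]
        mu_blk = means_sorted[start:start + window]
        usable = (blk > 0).any(axis=1)
        if usable.sum() < min_usable:
            continue
        blk = blk[usable]
        mean_blk = float(mu_blk[usable].mean())
        hi = np.log(max(10.0, 10.0 / max(mean_blk, 1e-12)))

        a, b = lo, hi
        x1 = b - _GOLDEN * (b - a)
        x2 = a + _GOLDEN * (b - a)

        def f(loga: float) -> float:
            al = np.full(blk.shape[0], np.exp(loga))
            return float(_cr_adjusted_loglik(blk, s, al).sum())

        f1, f2 = f(x1), f(x2)
        for _ in range(40):
            if f1 < f2:
                a, x1, f1 = x1, x2, f2
                x2 = a + _GOLDEN * (b - a)
                f2 = f(x2)
            else:
                b, x2, f2 = x2, x1, f1
                x1 = b - _GOLDEN * (b - a)
                f1 = f(x1)
            if b - a < 1e-6:
                break
        out_m.append(mean_blk)
        out_a.append(float(np.exp((a + b) / 2.0)))
    if not out_m:
        raise DispersionError("insufficient barcodes for trend fit")
    order2 = np.argsort(out_m)
    return np.asarray(out_m)[order2], np.asarray(out_a)[order2]


def fit_dispersion_trend(
    means: np.ndarray, genewise: np.ndarray, span: float = 0.7
) -> Callable[[np.ndarray], np.ndarray]:
    """Local regression of log dispersion on log mean.

    Tricube-weighted local linear fit (lowess) in log-log space; the returned
    callable interpolates inside the fitted mean range and extrapolates as a
    constant outside it, never returning below the dispersion floor.
    """
    means = np.asarray(means, float)
    genewise = np.asarray(genewise, float)
    usable = (means > 0) & (genewise > 10.0 * DISPERSION_FLOOR)
    if usable.sum() < 50:
        raise DispersionError("insufficient barcodes for trend fit")
    x = np.log(means[usable])
    y = np.log(genewise[usable])
    fitted = lowess(y, x, frac=span, it=1, return_sorted=True)
    return _interp_trend(fitted[:, 0], fitted[:, 1])


def _interp_trend(log_x: np.ndarray, log_y: np.ndarray) -> Callable:
    """Trend callable: log-log interpolation, constant extrapolation, floored."""
    fx, idx = np.unique(log_x, return_index=True)
    fy = np.asarray(log_y)[idx]

    def trend(mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        logmu = np.log(np.maximum(mu, 1e-300))
        out = np.exp(np.interp(logmu, fx, fy))
        return np.maximum(out, DISPERSION_FLOOR)

    return trend


def fit_trend_from_windows(
    counts_test: BarcodeCountMatrix,
    sf: SizeFactors | np.ndarray,
    window: int = 100,
    span: float = 0.3,
) -> Callable[[np.ndarray], np.ndarray]:
    """Mean->dispersion trend from windowed common-dispersion MLEs.

    The windowed estimates (see :func:`fit_windowed_common_dispersions`) are
    smoothed by lowess in log-log space when there are enough windows,
    otherwise interpolated directly.
    """
    wm, wa = fit_windowed_common_dispersions(counts_test, sf, window=window)
    x = np.log(np.maximum(wm, 1e-300))
    y = np.log(np.maximum(wa, DISPERSION_FLOOR))
    if len(wm) >= 50:
        fitted = lowess(y, x, frac=span, it=1, return_sorted=True)
        return _interp_trend(fitted[:, 0], fitted[:, 1])
    return _interp_trend(x, y)


def compute_final_dispersions(
    counts_test: BarcodeCountMatrix,
    sf: SizeFactors | np.ndarray,
    genewise: np.ndarray,
    allzero_mask: np.ndarray,
    trend: Callable[[np.ndarray], np.ndarray],
    means_test: np.ndarray,
    method: str = "trended",
    beta: float | None = None,
    prior_var_floor: float = 0.25,
    outlier_sd: float = 2.0,
) -> DispersionSet:
    """Assemble final per-barcode dispersions.

    ``method="trended"`` takes the trend value at the barcode's mean.
    ``method="shrunk"`` computes a MAP estimate under a log-normal prior
    centered at the trend: with the log-MLE's sampling variance
    approximated by trigamma((n-1)/2), the posterior mode is the
    precision-weighted average of log tagwise MLE and log trend.  The prior
    variance is the robust variance (1.4826*MAD)^2 of the log residuals
    minus that sampling variance, floored at ``prior_var_floor``.  Barcodes
    whose log residual exceeds ``outlier_sd`` robust SDs *above* the trend
    keep their tagwise MLE; barcodes without a usable tagwise MLE (all-zero
    or floor-slammed) take the trend value.

    If ``beta`` is given, every barcode with mean normalized test count below
    beta is assigned the maximum tagwise dispersion (``cap_value``).
    """
    if method not in ("trended", "shrunk"):
        raise DispersionError(f"unknown dispersion method {method!r}")
    if beta is not None and beta < 0:
        raise DispersionError("beta must be non-negative")
    genewise = np.asarray(genewise, float)
    means_test = np.asarray(means_test, float)
    n = len(genewise)
    trend_vals = trend(means_test)
    outlier_mask = None
    prior_var = None

    if method == "trended":
        final = trend_vals.copy()
    else:
        n_test = counts_test.counts.shape[1]
        usable = (~allzero_mask) & (genewise > 10.0 * DISPERSION_FLOOR)
        resid = np.log(genewise) - np.log(trend_vals)
        if usable.any():
            r_use = resid[usable]
            robust_sd = 1.4826 * np.median(np.abs(r_use - np.median(r_use)))
        else:
            robust_sd = 0.0
        sampling_var = float(polygamma(1, max(n_test - 1, 1) / 2.0))
        prior_var = max(robust_sd**2 - sampling_var, prior_var_floor)
        outlier_mask = usable & (resid > outlier_sd * max(robust_sd, 1e-12))

        final = trend_vals.copy()
        w = prior_var / (prior_var + sampling_var)
        shrink = usable & ~outlier_mask
        final[shrink] = np.exp(
            w * np.log(genewise[shrink]) + (1.0 - w) * np.log(trend_vals[shrink])
        )
        final[outlier_mask] = genewise[outlier_mask]

    final = np.clip(final, DISPERSION_FLOOR, None)
    cap_value = float(genewise.max()) if n else DISPERSION_FLOOR
    capped_mask = np.zeros(n, dtype=bool)
    if beta is not None and beta > 0:
        capped_mask = means_test < beta
        final = np.where(capped_mask, cap_value, final)
    return DispersionSet(
        genewise=genewise,
        trend=trend,
        final=final,
        method=method,
        cap_value=cap_value,
        capped_mask=capped_mask,
        allzero_mask=np.asarray(allzero_mask, bool),
        means_test=means_test,
        outlier_mask=outlier_mask,
        prior_var=prior_var,
    )


def estimate_dispersions(
    counts: BarcodeCountMatrix,
    sf: SizeFactors,
    method: str = "trended",
    beta: float | None = None,
    span: float = 0.3,
    dispersion_columns: str = "test",
) -> DispersionSet:
    """Full dispersion pipeline on the requested columns.

    ``dispersion_columns="test"`` is the method's defining behaviour;
    ``"all"`` reproduces the unmodified pooled estimation (both groups) for
    comparison studies.
    """
    if dispersion_columns == "test":
        sub = counts.restrict("test")
        mask = counts.group_mask("test")
    elif dispersion_columns == "all":
        sub = counts
        mask = np.ones(counts.n_samples, dtype=bool)
    else:
        raise DispersionError("dispersion_columns must be 'test' or 'all'")
    s = np.asarray(sf)[mask]
    genewise, allzero = fit_genewise_dispersions(sub, s)
    means = (sub.counts / s[None, :]).mean(axis=1)
    trend = fit_trend_from_windows(sub, s, span=span)
    return compute_final_dispersions(
        sub, s, genewise, allzero, trend, means, method=method, beta=beta
    )
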