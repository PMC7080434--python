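"""Estimation of the beta count threshold.

Read counts of barcodes that went through a narrow sampling bottleneck stop
behaving negative-binomially at low abundance (excess zeros and dropouts
from the cell-sampling stage).  The beta heuristic locates the mean-count
level above which an NB model is adequate, so that independent filtering can
be bounded away from the non-NB region:

1. barcodes are ordered by mean normalized test count; a sliding window of
   ``window_n`` barcodes (step ``window_n // 4``) pools the window's
   normalized counts, fits NB(m, a) by maximum likelihood, and draws two
   synthetic NB samples of the pooled size.  D_emp is the two-sample
   Kolmogorov-Smirnov statistic between the data and the first synthetic
   sample; D_theo between the two synthetic samples (the statistic's own
   sampling noise);
2. for each block of 30 consecutive windows, Gamma distributions are fitted
   to the D_emp and D_theo populations and the overlap area of the two
   densities is integrated; NB-consistent data gives overlap near 1;
3. a four-parameter log-logistic (sigmoid) curve of overlap versus mean
   count is fitted.  If the curve ascends with the mean and the minimum
   observed overlap is below 0.25, beta is the mean count at which the
   fitted overlap reaches 0.8 of the upper asymptote; otherwise the data is
   treated as NB everywhere and beta = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln

from .counts_io import BarcodeCountMatrix, SizeFactors, normalized_counts


class BetaEstimationError(ValueError):
    pass


@dataclass
class GammaFit:
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shape) and np.isfinite(self.scale)):
            raise BetaEstimationError("non-finite Gamma parameters")
        if self.shape <= 0 or self.scale <= 0:
            raise BetaEstimationError("Gamma parameters must be positive")

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return stats.gamma.pdf(x, a=self.shape, scale=self.scale)

    def ppf(self, q: float) -> float:
        return float(stats.gamma.ppf(q, a=self.shape, scale=self.scale))


@dataclass
class BetaEstimate:
    """The beta threshold plus all intermediates of its estimation."""

    beta: float
    windows: list[tuple[float, float, float]]  # (window mean, D_emp, D_theo)
    overlaps: list[tuple[float, float]]  # (center mean, overlap area)
    sigmoid: tuple[float, float, float, float] | None  # (b, c, d, e)
    ascending: bool
    min_overlap: float
    valid: bool
    seed: int | None = None
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# NB fitting on pooled window counts
# ---------------------------------------------------------------------------

def _nb_loglik_1d(x: np.ndarray, m: float, a: float) -> float:
    r = 1.0 / a
    m = max(m, 1e-12)
    return float(np.sum(
        gammaln(x + r) - gammaln(r) - gammaln(x + 1.0)
        - r * np.log1p(a * m)
        + x * (np.log(m) + np.log(a) - np.log1p(a * m))
    ))


def fit_nb_mle(x: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood NB(m, a) fit to a 1-D sample of integer counts.

    The mean MLE is the sample mean; the dispersion is profiled by bounded
    1-D maximization on log a.  Raises on degenerate samples.
    """
    x = np.asarray(x, dtype=float)
    m = float(x.mean())
    if m <= 0 or x.var() == 0:
        raise BetaEstimationError("degenerate window sample for NB fit")

    def neg(loga: float) -> float:
        return -_nb_loglik_1d(x, m, np.exp(loga))

    res = optimize.minimize_scalar(
        neg, bounds=(np.log(1e-8), np.log(1e4)), method="bounded",
        options={"xatol": 1e-6},
    )
    return m, float(np.exp(res.x))


def _rnb(rng: np.random.Generator, m: float, a: float, size: int) -> np.ndarray:
    r = 1.0 / a
    p = r / (r + m)
    return rng.negative_binomial(r, p, size=size).astype(float)


def window_ks_statistics(
    counts_test: BarcodeCountMatrix,
    sf: SizeFactors | np.ndarray,
    window_n: int = 100,
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float, float]]:
    """Sliding-window empirical vs theoretical KS statistics.

    Returns a list of ``(window_mean, D_emp, D_theo)`` ordered by the window
    mean.  Windows whose NB fit fails are skipped with a warning.
    """
    if rng is None:
        rng = np.random.default_rng()
    if window_n < 30:
        raise BetaEstimationError("window_n must be >= 30")
    norm = normalized_counts(counts_test, np.asarray(sf))
    means = norm.mean(axis=1)
    n = len(means)
    if n < 3 * window_n:
        raise BetaEstimationError(
            f"need at least {3 * window_n} barcodes for beta estimation, got {n}"
        )
    order = np.argsort(means, kind="stable")
    norm_sorted = norm[order]
    means_sorted = means[order]
    step = max(window_n // 4, 1)
    out: list[tuple[float, float, float]] = []
    for start in range(0, n - window_n + 1, step):
        block = norm_sorted[start:start + window_n]
        pooled = np.round(block.ravel())
        try:
            m, a = fit_nb_mle(pooled)
        except BetaEstimationError:
            warnings.warn(f"window at index {start}: NB fit failed, skipped")
            continue
        sim1 = _rnb(rng, m, a, pooled.size)
        sim2 = _rnb(rng, m, a, pooled.size)
        d_emp = stats.ks_2samp(pooled, sim1).statistic
        d_theo = stats.ks_2samp(sim1, sim2).statistic
        out.append((float(means_sorted[start:start + window_n].mean()),
                    float(d_emp), float(d_theo)))
    if not out:
        raise BetaEstimationError("all windows skipped; beta cannot be estimated")
    return out


# ---------------------------------------------------------------------------
# Gamma overlap profile
# ---------------------------------------------------------------------------

def _fit_gamma(x: np.ndarray) -> GammaFit:
    x = np.asarray(x, dtype=float)
    x = x[x > 0]
    if len(x) < 3 or x.var() == 0:
        raise BetaEstimationError("degenerate sample for Gamma fit")
    try:
        shape, _, scale = stats.gamma.fit(x, floc=0)
        return GammaFit(shape=float(shape), scale=float(scale))
    except (BetaEstimationError, Exception):
        # method-of-moments fallback
        m, v = x.mean(), x.var()
        if v <= 0:
            raise BetaEstimationError("Gamma fit failed")
        return GammaFit(shape=float(m * m / v), scale=float(v / m))


def gamma_overlap(fit_a: GammaFit, fit_b: GammaFit, n_grid: int = 2048) -> float:
    """Overlap area of two Gamma densities by trapezoid quadrature on
    [0, max 99.9th percentile]."""
    upper = max(fit_a.ppf(0.999), fit_b.ppf(0.999))
    x = np.linspace(0.0, upper, n_grid)
    o = float(np.trapezoid(np.minimum(fit_a.pdf(x), fit_b.pdf(x)), x))
    return min(max(o, 0.0), 1.0)


def overlap_profile(
    windows: list[tuple[float, float, float]], gamma_window: int = 30
) -> list[tuple[float, float]]:
    """Per-block overlap of the D_emp and D_theo Gamma models.

    ``gamma_window`` consecutive mean-ordered windows form one block; a block
    whose Gamma fits fail on both routes is skipped.
    """
    if len(windows) < gamma_window:
        raise BetaEstimationError(
            f"need at least {gamma_window} windows for the overlap profile"
        )
    arr = np.asarray(windows, dtype=float)
    out: list[tuple[float, float]] = []
    for start in range(0, len(windows) - gamma_window + 1):
        block = arr[start:start + gamma_window]
        try:
            fit_emp = _fit_gamma(block[:, 1])
            fit_theo = _fit_gamma(block[:, 2])
        except BetaEstimationError:
            continue
        center = float(np.median(block[:, 0]))
        out.append((center, gamma_overlap(fit_emp, fit_theo)))
    return out


# ---------------------------------------------------------------------------
# Sigmoid fit and the beta rule
# ---------------------------------------------------------------------------

def _ll4(logm: np.ndarray, b: float, c: float, d: float, loge: float) -> np.ndarray:
    """Four-parameter log-logistic: c + (d - c) / (1 + exp(b*(ln m - ln e)))."""
    return c + (d - c) / (1.0 + np.exp(np.clip(b * (logm - loge), -500, 500)))


def fit_sigmoid(
    center_means: np.ndarray, overlaps: np.ndarray
) -> tuple[float, float, float, float]:
    """Least-squares fit of the log-logistic overlap curve; returns (b, c, d, e)."""
    logm = np.log(np.maximum(center_means, 1e-12))
    o = np.asarray(overlaps, dtype=float)
    lo_o, hi_o = float(o.min()), float(o.max())
    loge0 = float(np.median(logm))

    def resid(p):
        return _ll4(logm, *p) - o

    best = None
    # try both orientations of the slope to avoid a local minimum
    for b0 in (-1.0, 1.0, -4.0, 4.0):
        try:
            res = optimize.least_squares(
                resid, x0=[b0, lo_o, hi_o, loge0],
                bounds=([-50, -0.5, -0.5, logm.min() - 5],
                        [50, 1.5, 1.5, logm.max() + 5]),
                max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.isfinite(best.cost):
        raise BetaEstimationError("sigmoid fit did not converge")
    b, c, d, loge = best.x
    return float(b), float(c), float(d), float(np.exp(loge))


def estimate_beta(
    counts_test: BarcodeCountMatrix,
    sf: SizeFactors | np.ndarray,
    window_n: int = 100,
    rng: np.random.Generator | None = None,
    overlap_target: float = 0.8,
    min_overlap_rule: float = 0.25,
    gamma_window: int = 30,
    seed: int | None = None,
) -> BetaEstimate:
    """Full beta-threshold estimation on the test-group columns.

    Returns a :class:`BetaEstimate`; ``valid=False`` (and ``beta=0``) when
    the data looks NB at all count levels, when the overlap profile is not
    ascending, or when the sigmoid fit fails.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    windows = window_ks_statistics(counts_test, sf, window_n=window_n, rng=rng)
    overlaps = overlap_profile(windows, gamma_window=gamma_window)
    if len(overlaps) < 4:
        return BetaEstimate(
            beta=0.0, windows=windows, overlaps=overlaps, sigmoid=None,
            ascending=False, min_overlap=float("nan"), valid=False, seed=seed,
            notes=["too few overlap blocks for sigmoid fit"],
        )
    centers = np.array([m for m, _ in overlaps])
    ovals = np.array([o for _, o in overlaps])
    min_overlap = float(ovals.min())
    notes: list[str] = []
    try:
        b, c, d, e = fit_sigmoid(centers, ovals)
        sigmoid = (b, c, d, e)
    except BetaEstimationError as exc:
        warnings.warn(str(exc))
        return BetaEstimate(
            beta=0.0, windows=windows, overlaps=overlaps, sigmoid=None,
            ascending=False, min_overlap=min_overlap, valid=False, seed=seed,
            notes=[str(exc)],
        )
    # ascending = fitted overlap increases with mean count
    lo_val = _ll4(np.log(centers.min()), b, c, d, np.log(e))
    hi_val = _ll4(np.log(centers.max()), b, c, d, np.log(e))
    ascending = bool(hi_val > lo_val)
    beta = 0.0
    valid = False
    if ascending and min_overlap < min_overlap_rule:
        target = overlap_target * d  # 0.8 of the upper asymptote
        # invert c + (d-c)/(1+E) = target with E = exp(b*(ln m - ln e))
        denom = target - c
        if 0 < denom < (d - c):
            E = (d - c) / denom - 1.0
            if E > 0 and b != 0:
                beta = float(e * np.exp(np.log(E) / b))
                window_means = np.array([w[0] for w in windows])
                beta = float(np.clip(beta, window_means.min(), window_means.max()))
                valid = True
        if not valid:
            notes.append("sigmoid inverse at 0.8*d outside the curve's range")
    if not valid:
        beta = 0.0
    return BetaEstimate(
        beta=beta, windows=windows, overlaps=overlaps, sigmoid=sigmoid,
        ascending=ascending, min_overlap=min_overlap, valid=valid, seed=seed,
        notes=notes,
    )
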