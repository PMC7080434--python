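"""Beta-bounded independent filtering.

Classical independent filtering discards low-count tags before multiple
testing and picks the count threshold that maximizes the number of BH
rejections at a target FDR.  Unconstrained, that search can settle *below*
the count region where the NB model holds; here the search over quantile
thresholds of the filter statistic (mean normalized test count) is bounded
below by the quantile of the beta threshold, so non-NB barcodes can never
be re-admitted by the rejection-maximization step.

The rejection count as a function of the quantile threshold is smoothed
with a cubic smoothing spline (roughness chosen by generalized
cross-validation) before the maximum is located; ties in the fitted maximum
break toward the smallest threshold, retaining more barcodes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

GRID_STEP = 0.01
GRID_UPPER = 0.95


def _bh_reject_count(p: np.ndarray, alpha: float) -> int:
    p = p[np.isfinite(p)]
    m = len(p)
    if m == 0:
        return 0
    order = np.sort(p)
    thresh = alpha * np.arange(1, m + 1) / m
    passing = np.nonzero(order <= thresh)[0]
    return int(passing[-1] + 1) if len(passing) else 0


def rejections_at_quantile(
    pvalues: np.ndarray,
    filter_stat: np.ndarray,
    quantile: float,
    alpha: float,
) -> int:
    """BH rejection count after discarding barcodes below the given quantile
    of the filter statistic."""
    if not 0.0 <= quantile < 1.0:
        raise ValueError("quantile must be in [0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    fs = np.asarray(filter_stat, dtype=float)
    cutoff = np.quantile(fs, quantile)
    keep = fs >= cutoff
    if not keep.any():
        return 0
    return _bh_reject_count(p[keep], alpha)


def apply_independent_filtering(
    results: pd.DataFrame,
    beta: float = 0.0,
    alpha: float = 0.2,
) -> pd.DataFrame:
    """Choose the rejection-maximizing quantile threshold on [q_beta, 0.95].

    ``results`` must carry ``pvalue`` and ``filter_stat`` columns; the
    returned copy has ``filtered`` set for barcodes below the selected count
    threshold, their ``padj`` missing, and ``padj`` recomputed by BH on the
    retained barcodes.  ``pvalue``, ``stat`` and ``log2FoldChange`` are
    never altered.
    """
    from .nb_testing import bh_adjust

    if beta < 0:
        raise ValueError("beta must be non-negative")
    out = results.copy()
    fs = out["filter_stat"].to_numpy(dtype=float)
    p = out["pvalue"].to_numpy(dtype=float)

    # empirical quantile of beta within the filter statistic
    q_beta = float(np.mean(fs < beta)) if beta > 0 else 0.0
    grid = np.arange(0.0, GRID_UPPER + GRID_STEP / 2, GRID_STEP)
    grid = grid[grid >= q_beta]
    if len(grid) == 0:
        warnings.warn("beta above the 95th percentile; filtering at beta itself")
        theta = q_beta
        cutoff = beta
    else:
        rejections = np.array(
            [rejections_at_quantile(p, fs, q, alpha) for q in grid], dtype=float
        )
        if len(grid) >= 4 and np.ptp(rejections) > 0:
            try:
                spline = make_smoothing_spline(grid, rejections)  # GCV roughness
                fitted = spline(grid)
            except Exception:
                fitted = rejections
        else:
            fitted = rejections
        # ties toward the smallest theta (argmax returns the first maximum)
        theta = float(grid[np.argmax(fitted)])
        cutoff = max(np.quantile(fs, theta), beta)
    filtered = fs < cutoff
    out["filtered"] = filtered
    padj = np.full(len(out), np.nan)
    keep = ~filtered
    padj[keep] = bh_adjust(p[keep])
    out["padj"] = padj
    out["beta_used"] = beta
    return out
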