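"""Benchmark evaluation: classification against ground truth, empirical FDR,
precision-recall / pAUC, the permutation ("random FDR") baseline, and the
local data diagnostics (mean-variance profile, local NB goodness of fit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .beta_threshold import fit_nb_mle, BetaEstimationError, _rnb
from .clonesim import GroundTruth
from .counts_io import BarcodeCountMatrix, SizeFactors, normalized_counts
from .nb_testing import bh_adjust


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray
    recall_bound: float
    pauc: float           # standardized to [0, 1]


@dataclass
class GoFProfile:
    means: np.ndarray
    statistics: np.ndarray
    pvalues: np.ndarray


# ---------------------------------------------------------------------------
# Classification and confusion
# ---------------------------------------------------------------------------

def classify_drbs(results: pd.DataFrame, fdr_threshold: float = 0.25) -> np.ndarray:
    """Call each barcode enriched / depleted / ns.

    A barcode is differentially represented when its BH-adjusted p-value is
    below the FDR threshold; the direction follows the fold change (below 1
    -> depleted, otherwise enriched).  Filtered barcodes are ns.
    """
    padj = results["padj"].to_numpy(dtype=float)
    lfc = results["log2FoldChange"].to_numpy(dtype=float)
    filtered = results["filtered"].to_numpy(dtype=bool)
    calls = np.full(len(results), "ns", dtype=object)
    sig = np.isfinite(padj) & (padj < fdr_threshold) & ~filtered
    calls[sig & (lfc >= 0)] = "enriched"
    calls[sig & (lfc < 0)] = "depleted"
    return calls


def confusion_and_fdr(
    calls: np.ndarray, truth: GroundTruth, direction: str = "enriched"
) -> dict:
    """Confusion counts and empirical false-positive fraction for one call
    direction.  A false positive is a barcode called ``direction`` whose
    ground-truth label differs; with zero calls the empirical FDR is 0 by
    convention."""
    calls = np.asarray(calls, dtype=object)
    labels = np.asarray(truth.labels, dtype=object)
    if len(calls) != len(labels):
        raise ValueError("calls and truth must cover the same barcodes")
    called = calls == direction
    tp = int((called & (labels == direction)).sum())
    fp = int((called & (labels != direction)).sum())
    fn = int((~called & (labels == direction)).sum())
    n_called = int(called.sum())
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "called": n_called,
        "empirical_fdr": fp / max(1, n_called),
    }


# ---------------------------------------------------------------------------
# Precision-recall / pAUC
# ---------------------------------------------------------------------------

def _pr_points(order_scores, positives):
    """Precision/recall after each rank of the score-ordered barcodes."""
    pos = np.asarray(positives, dtype=bool)
    n_pos = pos.sum()
    tp = np.cumsum(pos)
    k = np.arange(1, len(pos) + 1)
    precision = tp / k
    recall = tp / max(n_pos, 1)
    return recall, precision


def pr_pauc(
    pvalues: np.ndarray,
    fold_changes: np.ndarray,
    truth: GroundTruth,
    barcode_ids: np.ndarray,
    recall_bound: float = 1.0,
    positives_only: bool = False,
) -> PRCurve:
    """Precision-recall curve ranked by unadjusted p-value and its partial
    AUC over recall in [0, recall_bound], standardized by the bound.

    The positive class is a barcode *correctly assigned* by the method: its
    fold-change direction (enriched for log2FC >= 0, depleted otherwise)
    matches the ground-truth label.  ``positives_only`` restricts the
    ranking to barcodes with positive log2 fold change — used for scoring
    enrichment detection when truly enriched clones are rare.  Ties in p are
    broken by barcode id so curves are deterministic.
    """
    if not 0.0 < recall_bound <= 1.0:
        raise ValueError("recall bound must be in (0, 1]")
    p = np.asarray(pvalues, dtype=float)
    lfc = np.asarray(fold_changes, dtype=float)
    labels = np.asarray(truth.labels, dtype=object)
    ids = np.asarray(barcode_ids, dtype=str)
    keep = np.isfinite(p)
    if positives_only:
        keep &= lfc > 0
    p, lfc, labels, ids = p[keep], lfc[keep], labels[keep], ids[keep]
    assigned = np.where(lfc >= 0, "enriched", "depleted")
    positive = assigned == labels
    order = np.lexsort((ids, p))
    recall, precision = _pr_points(p[order], positive[order])
    # prepend the (0, first precision) anchor for the integration
    r = np.concatenate([[0.0], recall])
    q = np.concatenate([[precision[0] if len(precision) else 1.0], precision])
    rb = min(recall_bound, 1.0)
    rc = np.clip(r, 0.0, rb)
    area = float(np.trapezoid(q, rc))
    return PRCurve(
        recall=recall, precision=precision,
        recall_bound=recall_bound, pauc=area / rb,
    )


def mean_recall_at_fdr(
    result_tables: list[pd.DataFrame],
    truth: GroundTruth,
    fdr_threshold: float = 0.25,
) -> float:
    """The recall upper bound X: mean recall at the FDR threshold across the
    supplied per-method result tables."""
    recalls = []
    for res in result_tables:
        calls = classify_drbs(res, fdr_threshold)
        labels = np.asarray(truth.labels, dtype=object)
        correct = (calls == labels) & (calls != "ns")
        n_true = int(np.isin(labels, ("enriched", "depleted")).sum())
        recalls.append(correct.sum() / max(n_true, 1))
    return float(np.mean(recalls)) if recalls else 0.0


# ---------------------------------------------------------------------------
# Random-FDR baseline
# ---------------------------------------------------------------------------

def random_fdr_baseline(
    results: pd.DataFrame,
    truth: GroundTruth,
    n_perm: int = 10,
    rng: np.random.Generator | None = None,
    fdr_threshold: float = 0.25,
    lfc_threshold: float = 0.5,
) -> float:
    """Mean false-discovery fraction when adjusted p-values are randomly
    permuted over the barcodes.

    A permuted "enriched" call requires permuted padj below the threshold
    *and* log2 fold change above ``lfc_threshold`` (the directional cutoff
    used for the baseline); the returned value is the mean fraction of such
    calls whose ground truth is not enriched.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    padj = results["padj"].to_numpy(dtype=float)
    lfc = results["log2FoldChange"].to_numpy(dtype=float)
    labels = np.asarray(truth.labels, dtype=object)
    fracs = []
    for _ in range(n_perm):
        perm = rng.permutation(padj)
        called = np.isfinite(perm) & (perm < fdr_threshold) & (lfc > lfc_threshold)
        n_called = called.sum()
        fp = (called & (labels != "enriched")).sum()
        fracs.append(fp / max(1, n_called))
    return float(np.mean(fracs))


# ---------------------------------------------------------------------------
# Local diagnostics
# ---------------------------------------------------------------------------

def local_mean_variance(
    counts: BarcodeCountMatrix,
    sf: SizeFactors | np.ndarray,
    window: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Local mean-variance profile of normalized counts.

    Tagwise variances are averaged within sliding windows of ``window`` read
    counts on the mean-count axis; windows covering no barcodes are omitted.
    Returns (window centers, local variances).
    """
    norm = normalized_counts(counts, np.asarray(sf))
    if norm.shape[1] < 2:
        raise ValueError("need at least 2 samples for a variance profile")
    means = norm.mean(axis=1)
    variances = norm.var(axis=1, ddof=1)
    centers = np.arange(window / 2, means.max() + window / 2, window / 2)
    out_c, out_v = [], []
    for c in centers:
        mask = (means >= c - window / 2) & (means < c + window / 2)
        if mask.any():
            out_c.append(c)
            out_v.append(variances[mask].mean())
    return np.asarray(out_c), np.asarray(out_v)


def local_nb_gof(
    counts: BarcodeCountMatrix,
    sf: SizeFactors | np.ndarray,
    window: int = 100,
    n_mc: int = 99,
    rng: np.random.Generator | None = None,
) -> GoFProfile:
    """Local NB goodness of fit via a two-sample Cramér-von Mises test.

    Barcodes are mean-ordered; each window of ``window`` barcodes pools its
    normalized counts (rounded), fits NB(m, a) by MLE, and compares the data
    against a simulated NB sample of matched size with the two-sample CvM
    statistic.  Significance uses the Monte Carlo add-one estimator over
    ``n_mc`` simulated null pairs, so p is never exactly 0.
    """
    if n_mc < 99:
        raise ValueError("n_mc must be >= 99")
    if rng is None:
        rng = np.random.default_rng()
    norm = normalized_counts(counts, np.asarray(sf))
    means = norm.mean(axis=1)
    order = np.argsort(means, kind="stable")
    norm_sorted = norm[order]
    means_sorted = means[order]
    step = max(window // 2, 1)
    out_m, out_s, out_p = [], [], []
    for start in range(0, len(means) - window + 1, step):
        pooled = np.round(norm_sorted[start:start + window].ravel())
        try:
            m, a = fit_nb_mle(pooled)
        except BetaEstimationError:
            continue
        sim = _rnb(rng, m, a, pooled.size)
        obs_stat = stats.cramervonmises_2samp(pooled, sim).statistic
        null_stats = np.empty(n_mc)
        for j in range(n_mc):
            x1 = _rnb(rng, m, a, pooled.size)
            x2 = _rnb(rng, m, a, pooled.size)
            null_stats[j] = stats.cramervonmises_2samp(x1, x2).statistic
        p = (1.0 + (null_stats >= obs_stat).sum()) / (n_mc + 1.0)
        out_m.append(float(means_sorted[start:start + window].mean()))
        out_s.append(float(obs_stat))
        out_p.append(float(p))
    return GoFProfile(
        means=np.asarray(out_m),
        statistics=np.asarray(out_s),
        pvalues=np.asarray(out_p),
    )


# ---------------------------------------------------------------------------
# Bootstrap utility
# ---------------------------------------------------------------------------

def bootstrap_metric(
    metric_fn,
    barcode_index: np.ndarray,
    rng: np.random.Generator,
    n_resamples: int = 10,
    n_repeats: int = 3,
) -> tuple[float, float]:
    """Barcode-level bootstrap of an arbitrary metric.

    ``metric_fn(indices)`` is evaluated on ``n_resamples`` resamples with
    replacement of the full barcode set, repeated ``n_repeats`` times; the
    mean and SD over all evaluations are returned.  Seed-reproducible via
    the supplied generator.
    """
    n = len(barcode_index)
    values = []
    for _ in range(n_repeats):
        for _ in range(n_resamples):
            idx = rng.integers(0, n, size=n)
            values.append(metric_fn(idx))
    return float(np.mean(values)), float(np.std(values))
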