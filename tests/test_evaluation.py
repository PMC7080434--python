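import numpy as np
import pandas as pd
import pytest

from debra import (
    GroundTruth,
    bootstrap_metric,
    classify_drbs,
    confusion_and_fdr,
    local_mean_variance,
    local_nb_gof,
    mean_recall_at_fdr,
    pr_pauc,
    random_fdr_baseline,
)
from debra.counts_io import BarcodeCountMatrix, SizeFactors

from .conftest import nb_count_matrix


def _results(padj, lfc, p=None, filtered=None):
    n = len(padj)
    return pd.DataFrame(
        {
            "padj": padj,
            "log2FoldChange": lfc,
            "pvalue": padj if p is None else p,
            "filtered": np.zeros(n, bool) if filtered is None else filtered,
        },
        index=pd.Index([f"b{i:03d}" for i in range(n)], name="barcode"),
    )


def _truth(labels):
    labels = np.asarray(labels, dtype=object)
    ids = np.array([f"b{i:03d}" for i in range(len(labels))], dtype=object)
    return GroundTruth(ids, labels, labels)


class TestClassification:
    @pytest.mark.parametrize(
        "padj,lfc,expected",
        [(0.2, 1.0, "enriched"), (0.2, -1.0, "depleted"), (0.5, 3.0, "ns")],
    )
    def test_call_rules(self, padj, lfc, expected):
        res = _results([padj], [lfc])
        assert classify_drbs(res, 0.25)[0] == expected

    def test_filtered_is_ns(self):
        res = _results([0.01], [2.0], filtered=np.array([True]))
        assert classify_drbs(res, 0.25)[0] == "ns"


class TestConfusion:
    def test_all_correct(self):
        calls = np.array(["enriched", "depleted", "ns"], dtype=object)
        truth = _truth(["enriched", "depleted", "unassigned"])
        out = confusion_and_fdr(calls, truth)
        assert out["empirical_fdr"] == 0.0
        assert out["tp"] == 1 and out["fp"] == 0

    def test_fraction_arithmetic(self):
        calls = np.array(["enriched"] * 10 + ["ns"] * 10, dtype=object)
        truth = _truth(["enriched"] * 7 + ["depleted"] * 3 + ["enriched"] * 10)
        out = confusion_and_fdr(calls, truth)
        assert out["empirical_fdr"] == pytest.approx(0.3)
        assert out["tp"] + out["fp"] == out["called"]

    def test_zero_calls_convention(self):
        calls = np.array(["ns", "ns"], dtype=object)
        truth = _truth(["enriched", "depleted"])
        assert confusion_and_fdr(calls, truth)["empirical_fdr"] == 0.0


class TestPAUC:
    def test_perfect_ranking(self):
        n = 30
        truth = _truth(["enriched"] * 15 + ["depleted"] * 15)
        lfc = np.ones(n)  # last 15 wrongly assigned
        p = np.concatenate([np.linspace(1e-8, 1e-4, 15),
                            np.linspace(0.5, 0.99, 15)])
        curve = pr_pauc(p, lfc, truth, truth.barcode_ids)
        assert curve.pauc == pytest.approx(1.0)

    def test_random_ranking_matches_prevalence(self):
        paucs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            truth = _truth(rng.choice(["enriched", "depleted"], n))
            curve = pr_pauc(
                rng.random(n),
                rng.choice([-1.0, 1.0], n),
                truth, truth.barcode_ids,
            )
            paucs.append(curve.pauc)
        assert np.mean(paucs) == pytest.approx(0.5, abs=0.1)

    def test_matches_trapezoid_oracle(self):
        # brute-force loop integration on tiny instances
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(5, 21))
            truth = _truth(rng.choice(["enriched", "depleted"], n))
            p = rng.random(n)
            lfc = rng.normal(size=n)
            X = float(rng.uniform(0.3, 1.0))
            curve = pr_pauc(p, lfc, truth, truth.barcode_ids, recall_bound=X)

            assigned = np.where(lfc >= 0, "enriched", "depleted")
            positive = assigned == truth.labels
            order = np.lexsort((truth.barcode_ids.astype(str), p))
            pos = positive[order]
            n_pos = max(pos.sum(), 1)
            pts = [(0.0, 1.0 if not len(pos) else
                    (1.0 if pos[0] else 0.0))]
            tp = 0
            for k, is_pos in enumerate(pos, start=1):
                tp += is_pos
                pts.append((tp / n_pos, tp / k))
            pts[0] = (0.0, pts[1][1])
            area = 0.0
            for (r1, q1), (r2, q2) in zip(pts, pts[1:]):
                lo, hi = min(r1, X), min(r2, X)
                area += (hi - lo) * (q1 + q2) / 2.0
            assert curve.pauc == pytest.approx(area / X, abs=1e-9)

    def test_positives_only_restricts_to_enrichment(self):
        truth = _truth(["enriched", "depleted", "enriched"])
        p = np.array([0.01, 0.02, 0.03])
        lfc = np.array([1.0, -1.0, -1.0])
        curve = pr_pauc(p, lfc, truth, truth.barcode_ids, positives_only=True)
        assert len(curve.recall) == 1  # only the positive-fold-change barcode

    def test_recall_bound_from_results(self):
        res = _results([0.1, 0.1, 0.9], [1.0, -1.0, 1.0])
        truth = _truth(["enriched", "depleted", "enriched"])
        x = mean_recall_at_fdr([res], truth, fdr_threshold=0.25)
        assert x == pytest.approx(2 / 3)


class TestRandomBaseline:
    def test_all_enriched_universe(self):
        res = _results([0.01] * 20, [1.0] * 20)
        truth = _truth(["enriched"] * 20)
        out = random_fdr_baseline(res, truth, n_perm=5,
                                  rng=np.random.default_rng(0))
        assert out == 0.0

    def test_balanced_truth_baseline(self):
        rng = np.random.default_rng(1)
        n = 2000
        labels = np.array(["enriched"] * (n // 2) + ["depleted"] * (n // 2),
                          dtype=object)
        lfc = np.where(labels == "enriched", 1.0, -1.0)
        # a few flipped signs among high-|lfc| barcodes
        flip = rng.random(n) < 0.2
        lfc = np.where(flip, -lfc, lfc)
        res = _results(rng.random(n) * 0.2, lfc)
        truth = _truth(labels)
        baseline = random_fdr_baseline(res, truth, n_perm=20,
                                       rng=np.random.default_rng(2))
        callable_mask = lfc > 0.5
        expected = (np.asarray(labels)[callable_mask] != "enriched").mean()
        assert baseline == pytest.approx(expected, abs=0.05)

    def test_seed_reproducible(self):
        res = _results(np.linspace(0.01, 0.9, 50),
                       np.linspace(-2, 2, 50))
        truth = _truth(["enriched"] * 25 + ["depleted"] * 25)
        a = random_fdr_baseline(res, truth, 10, np.random.default_rng(3))
        b = random_fdr_baseline(res, truth, 10, np.random.default_rng(3))
        assert a == b


class TestLocalDiagnostics:
    def test_identical_replicates_zero_variance(self):
        K = np.tile(np.array([[10], [100], [400]]), (1, 3))
        m = BarcodeCountMatrix(["a", "b", "c"], K, ["r1", "r2", "r3"],
                               ["test"] * 3)
        _, v = local_mean_variance(m, SizeFactors(np.ones(3)))
        assert np.allclose(v, 0.0)

    def test_poisson_variance_matches_mean(self):
        rng = np.random.default_rng(4)
        mu = rng.uniform(50, 2000, 3000)
        K = rng.poisson(mu[:, None], size=(3000, 6))
        m = BarcodeCountMatrix([f"b{i}" for i in range(3000)], K,
                               [f"r{j}" for j in range(6)], ["test"] * 6)
        centers, var = local_mean_variance(m, SizeFactors(np.ones(6)))
        sel = centers > 50
        ratio = var[sel] / centers[sel]
        assert 0.8 < np.median(ratio) < 1.2

    def test_gof_uniform_under_null(self):
        m = nb_count_matrix(n=3000, reps=4, seed=6, mu_range=(100, 10_000),
                            dispersion_fn=lambda mu: np.full_like(mu, 0.2))
        prof = local_nb_gof(m, SizeFactors(np.ones(4)), window=100, n_mc=99,
                            rng=np.random.default_rng(6))
        assert len(prof.pvalues) >= 50
        assert (prof.pvalues > 0).all()
        assert (prof.pvalues < 0.05).mean() == pytest.approx(0.05, abs=0.05)

    def test_gof_detects_zero_inflation(self):
        m = nb_count_matrix(n=2000, reps=4, seed=7, mu_range=(5, 5000),
                            zero_inflate_below=50)
        prof = local_nb_gof(m, SizeFactors(np.ones(4)), window=100, n_mc=99,
                            rng=np.random.default_rng(7))
        lowest = prof.pvalues[prof.means <= np.quantile(prof.means, 0.1)]
        assert np.median(lowest) < 0.05


def test_bootstrap_metric_reproducible():
    vals = np.arange(100, dtype=float)
    fn = lambda idx: vals[idx].mean()  # noqa: E731
    m1 = bootstrap_metric(fn, vals, np.random.default_rng(8))
    m2 = bootstrap_metric(fn, vals, np.random.default_rng(8))
    assert m1 == m2
    assert m1[0] == pytest.approx(vals.mean(), abs=2.0)
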