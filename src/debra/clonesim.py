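"""Synthetic clone-tracing benchmark generator.

Emulates the mixture design used to benchmark differential-barcode
detection: two independently barcoded cell pools (A and B) with disjoint
barcode sets are mixed 50/50 into an "AB mix"; *null* samples are bottleneck
subsamples of the mix at 20-660 thousand cells with identical expected
barcode representation, and *perturbed* samples additionally spike in cells
from Pool A at a chosen perturbation degree (e.g. a 160e3-cell sample at
degree 0.35 receives 160e3*0.35 = 56e3 extra Pool-A cells).  Each cell
sample is then "sequenced": reads are drawn multinomially (optionally
Dirichlet-multinomial, to model PCR amplification noise) from the cell
proportions at a fixed depth.

Expected fold changes follow the mixing arithmetic: at degree d a Pool-A
barcode is expected at fold change (0.5+d)/(0.5*(1+d)) over the null, and a
Pool-B barcode at 1/(1+d).

Ground truth is assigned the way a wet-lab benchmark would do it: from
sequencing the *pure* pools, a barcode whose Pool-A/Pool-B read ratio
exceeds ``hi`` is truly enriched in A-spiked samples, below ``lo`` truly
depleted; with disjoint pools every barcode resolves to one of the two.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counts_io import BarcodeCountMatrix

NULL_SIZES = (20_000, 40_000, 80_000, 160_000, 330_000, 660_000)
PERTURBED_SIZES = (20_000, 40_000, 80_000, 160_000)
PERTURBATION_DEGREES = (0.18, 0.27, 0.35)


class SimulationError(ValueError):
    pass


@dataclass
class ClonePool:
    label: str
    barcode_ids: np.ndarray
    proportions: np.ndarray

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if abs(self.proportions.sum() - 1.0) > 1e-12:
            raise SimulationError("clone proportions must sum to 1")
        if (self.proportions < 0).any():
            raise SimulationError("clone proportions must be non-negative")

    @property
    def n_clones(self) -> int:
        return len(self.barcode_ids)


@dataclass
class MixtureSample:
    cell_counts: np.ndarray      # per barcode, pools A then B
    n_cells: int                 # base draw from the AB mix
    degree: float
    replica: int = 0

    @property
    def total_cells(self) -> int:
        return int(self.cell_counts.sum())


@dataclass
class GroundTruth:
    barcode_ids: np.ndarray
    labels: np.ndarray           # enriched / depleted / unassigned
    pools: np.ndarray            # A / B membership
    source: str = "read_ratio"


@dataclass
class BenchmarkSet:
    counts: BarcodeCountMatrix | None
    null_table: pd.DataFrame
    perturbed_table: pd.DataFrame
    truth: GroundTruth
    pool_reads: pd.DataFrame     # pure-pool sequencing (poolA, poolB columns)
    enriched_tables: dict[float, pd.DataFrame]
    config: dict


# ---------------------------------------------------------------------------
# Pools and cell sampling
# ---------------------------------------------------------------------------

def simulate_pools(
    n_clones_per_pool: int,
    rng: np.random.Generator,
    sdlog: float = 1.0,
    mean_cells_per_clone: float = 4000.0,
) -> tuple[ClonePool, ClonePool]:
    """Draw two disjoint clone pools with log-normal clone-size spectra.

    Clone sizes emulate independent expansion to ~4,000 cells per clone
    (about 12 divisions) with a log-normal spread ``sdlog`` on the natural
    log scale; sizes are normalized to within-pool proportions.
    """
    if n_clones_per_pool < 10:
        raise SimulationError("need at least 10 clones per pool")
    pools = []
    for label in ("A", "B"):
        sizes = rng.lognormal(
            mean=np.log(mean_cells_per_clone), sigma=sdlog, size=n_clones_per_pool
        )
        ids = np.array(
            [f"{label}_{i:06d}" for i in range(n_clones_per_pool)], dtype=object
        )
        pools.append(ClonePool(label, ids, sizes / sizes.sum()))
    return pools[0], pools[1]


def draw_sample(
    pool_a: ClonePool,
    pool_b: ClonePool,
    n_cells: int,
    degree: float,
    rng: np.random.Generator,
    replica: int = 0,
) -> MixtureSample:
    """Draw a bottleneck sample of the 50/50 AB mix, plus a Pool-A spike-in.

    ``n_cells`` cells are drawn multinomially from the mixture proportions
    (each pool contributing half its clone proportions) and an independent
    ``round(n_cells * degree)`` cells from Pool A alone.  ``degree=0`` gives
    a null sample.  Multinomial sampling stands in for the hypergeometric
    draw from a pool vastly larger than the sample.
    """
    if n_cells < 1:
        raise SimulationError("n_cells must be >= 1")
    if not 0.0 <= degree < 1.0:
        raise SimulationError("perturbation degree must be in [0, 1)")
    mix = np.concatenate([0.5 * pool_a.proportions, 0.5 * pool_b.proportions])
    cells = rng.multinomial(n_cells, mix).astype(np.int64)
    n_spike = int(round(n_cells * degree))
    if n_spike > 0:
        spike = rng.multinomial(n_spike, pool_a.proportions)
        cells[: pool_a.n_clones] += spike
    return MixtureSample(cells, n_cells=n_cells, degree=degree, replica=replica)


def sequence_reads(
    sample_cells: np.ndarray,
    depth: int,
    rng: np.random.Generator,
    pcr_overdispersion: float = 0.0,
) -> np.ndarray:
    """Sequence a cell sample to a fixed read depth.

    ``pcr_overdispersion`` (rho) of 0 gives plain multinomial reads; rho > 0
    draws the read proportions from a Dirichlet with concentration
    ``proportions / rho`` first, modelling PCR amplification jackpots.  The
    column always sums exactly to ``depth``.
    """
    if depth < 1:
        raise SimulationError("depth must be >= 1")
    cells = np.asarray(sample_cells, dtype=float)
    total = cells.sum()
    if total <= 0:
        raise SimulationError("cannot sequence an empty sample")
    props = cells / total
    if pcr_overdispersion > 0:
        pos = props > 0
        conc = props[pos] / pcr_overdispersion
        p = np.zeros_like(props)
        p[pos] = rng.dirichlet(conc)
        props = p
    return rng.multinomial(depth, props).astype(np.int64)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def assign_ground_truth(
    barcode_ids: np.ndarray,
    pool_a_reads: np.ndarray,
    pool_b_reads: np.ndarray,
    hi: float = 10.0,
    lo: float = 0.1,
) -> GroundTruth:
    """Label barcodes by the Pool-A / Pool-B read ratio of pure-pool
    sequencing: ratio > hi -> enriched, ratio < lo -> depleted, otherwise
    unassigned.  A zero Pool-B count with nonzero Pool-A reads counts as an
    infinite ratio."""
    a = np.asarray(pool_a_reads, dtype=float)
    b = np.asarray(pool_b_reads, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(b > 0, a / b, np.where(a > 0, np.inf, np.nan))
    labels = np.full(len(a), "unassigned", dtype=object)
    labels[ratio > hi] = "enriched"
    labels[ratio < lo] = "depleted"
    pools = np.where(
        np.char.startswith(np.asarray(barcode_ids, dtype=str), "A_"), "A", "B"
    ).astype(object)
    return GroundTruth(
        barcode_ids=np.asarray(barcode_ids, dtype=object),
        labels=labels, pools=pools, source="read_ratio",
    )


def resample_enriched_proportion(
    table: pd.DataFrame,
    truth: GroundTruth,
    proportion: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Resample rows so that exactly ``proportion`` of them are Pool-A
    barcodes (enriched in A-spiked samples), emulating experiments with a
    given fraction of responding clones."""
    if not 0.0 < proportion < 1.0:
        raise SimulationError("enriched proportion must be in (0, 1)")
    is_a = truth.pools == "A"
    ids_a = truth.barcode_ids[is_a]
    ids_b = truth.barcode_ids[~is_a]
    n_total = min(int(len(ids_a) / proportion), int(len(ids_b) / (1 - proportion)))
    n_a = int(round(n_total * proportion))
    n_b = n_total - n_a
    take_a = rng.choice(ids_a, size=n_a, replace=False)
    take_b = rng.choice(ids_b, size=n_b, replace=False)
    rows = np.concatenate([take_a, take_b])
    return table.loc[rows]


# ---------------------------------------------------------------------------
# Full benchmark
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkConfig:
    n_clones_per_pool: int = 5000
    sdlog: float = 1.0
    mean_cells_per_clone: float = 4000.0
    null_sizes: tuple[int, ...] = NULL_SIZES
    null_replicas: int = 3          # 6 sizes x 3 replicas = 18 null samples
    perturbed_sizes: tuple[int, ...] = PERTURBED_SIZES
    degrees: tuple[float, ...] = PERTURBATION_DEGREES
    perturbed_replicas: int = 2     # 4 sizes x 3 degrees x 2 = 24 samples
    enriched_proportions: tuple[float, ...] = (0.05, 0.15, 0.5)
    depth: int = 1_000_000
    # squared CV of the per-cell PCR amplification yield; the sample-level
    # Dirichlet overdispersion is amplification_cv2 / total_cells, i.e. the
    # concentration equals cell counts / amplification_cv2
    amplification_cv2: float = 1.0
    pool_depth: int = 1_000_000

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


def build_benchmark(
    config: BenchmarkConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> BenchmarkSet:
    """Generate the full benchmark: null samples, perturbed samples,
    pure-pool sequencing, ground truth, and enriched-proportion resamples.
    Fully determined by the seed."""
    if config is None:
        config = BenchmarkConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    pool_a, pool_b = simulate_pools(
        config.n_clones_per_pool, rng,
        sdlog=config.sdlog, mean_cells_per_clone=config.mean_cells_per_clone,
    )
    barcode_ids = np.concatenate([pool_a.barcode_ids, pool_b.barcode_ids])
    index = pd.Index(barcode_ids, name="barcode")

    null_cols = {}
    for size in config.null_sizes:
        for rep in range(1, config.null_replicas + 1):
            sample = draw_sample(pool_a, pool_b, size, 0.0, rng, replica=rep)
            reads = sequence_reads(
                sample.cell_counts, config.depth, rng,
                pcr_overdispersion=config.amplification_cv2 / sample.total_cells,
            )
            null_cols[f"null_{size // 1000}k.{rep}"] = reads
    null_table = pd.DataFrame(null_cols, index=index)

    pert_cols = {}
    for size in config.perturbed_sizes:
        for degree in config.degrees:
            for rep in range(1, config.perturbed_replicas + 1):
                sample = draw_sample(pool_a, pool_b, size, degree, rng, replica=rep)
                reads = sequence_reads(
                    sample.cell_counts, config.depth, rng,
                    pcr_overdispersion=config.amplification_cv2 / sample.total_cells,
                )
                name = f"pert_{size // 1000}k.p{int(round(degree * 100))}.{rep}"
                pert_cols[name] = reads
    perturbed_table = pd.DataFrame(pert_cols, index=index)

    # sequence the pure pools for ground truth
    a_cells = np.concatenate([pool_a.proportions, np.zeros(pool_b.n_clones)])
    b_cells = np.concatenate([np.zeros(pool_a.n_clones), pool_b.proportions])
    reads_a = sequence_reads(a_cells, config.pool_depth, rng)
    reads_b = sequence_reads(b_cells, config.pool_depth, rng)
    pool_reads = pd.DataFrame({"poolA": reads_a, "poolB": reads_b}, index=index)
    truth = assign_ground_truth(barcode_ids, reads_a, reads_b)

    enriched_tables = {
        p: resample_enriched_proportion(perturbed_table, truth, p, rng)
        for p in config.enriched_proportions
    }
    return BenchmarkSet(
        counts=None,
        null_table=null_table,
        perturbed_table=perturbed_table,
        truth=truth,
        pool_reads=pool_reads,
        enriched_tables=enriched_tables,
        config=config.to_dict(),
    )


def write_benchmark(bench: BenchmarkSet, outdir) -> None:
    """Write count TSVs, a truth TSV (barcode, pool, label) and a JSON
    manifest of all parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bench.null_table.to_csv(outdir / "null_counts.tsv", sep="\t")
    bench.perturbed_table.to_csv(outdir / "perturbed_counts.tsv", sep="\t")
    bench.pool_reads.to_csv(outdir / "pool_reads.tsv", sep="\t")
    truth_df = pd.DataFrame(
        {"pool": bench.truth.pools, "label": bench.truth.labels},
        index=pd.Index(bench.truth.barcode_ids, name="barcode"),
    )
    truth_df.to_csv(outdir / "truth.tsv", sep="\t")
    for p, table in bench.enriched_tables.items():
        table.to_csv(outdir / f"perturbed_enriched_{p:g}.tsv", sep="\t")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bench.config, fh, indent=2)
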