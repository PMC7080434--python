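"""Shared fixtures: simulated benchmark designs and NB count matrices."""

from __future__ import annotations

import numpy as np
import pytest

from debra import (
    BarcodeCountMatrix,
    GroundTruth,
    assign_ground_truth,
    draw_sample,
    sequence_reads,
    simulate_pools,
)

# the benchmark comparison design: 2 test replicas through a narrow
# bottleneck tested against 4 wide-bottleneck controls (2 x 330k + 2 x 660k)
CONTROL_DESIGN = ((330_000, 1), (330_000, 2), (660_000, 1), (660_000, 2))
DEPTH = 1_000_000
N_CLONES = 5000


def bottleneck_design(
    seed: int,
    test_size: int = 20_000,
    degree: float = 0.0,
    n_clones: int = N_CLONES,
    amplification_cv2: float = 1.0,
) -> tuple[BarcodeCountMatrix, GroundTruth]:
    """Simulate the null/perturbed comparison design with ground truth."""
    rng = np.random.default_rng(seed)
    pool_a, pool_b = simulate_pools(n_clones, rng)
    cols, groups, names = [], [], []
    for size, rep in CONTROL_DESIGN:
        s = draw_sample(pool_a, pool_b, size, 0.0, rng)
        cols.append(sequence_reads(
            s.cell_counts, DEPTH, rng,
            pcr_overdispersion=amplification_cv2 / s.total_cells,
        ))
        groups.append("control")
        names.append(f"null_{size // 1000}k.{rep}")
    for rep in (1, 2):
        s = draw_sample(pool_a, pool_b, test_size, degree, rng)
        cols.append(sequence_reads(
            s.cell_counts, DEPTH, rng,
            pcr_overdispersion=amplification_cv2 / s.total_cells,
        ))
        groups.append("test")
        names.append(f"test_{test_size // 1000}k.{rep}")
    ids = np.concatenate([pool_a.barcode_ids, pool_b.barcode_ids])
    counts = BarcodeCountMatrix(ids, np.column_stack(cols), names, groups)
    a_cells = np.concatenate([pool_a.proportions, np.zeros(pool_b.n_clones)])
    b_cells = np.concatenate([np.zeros(pool_a.n_clones), pool_b.proportions])
    reads_a = sequence_reads(a_cells, DEPTH, rng)
    reads_b = sequence_reads(b_cells, DEPTH, rng)
    truth = assign_ground_truth(ids, reads_a, reads_b)
    return counts, truth


def nb_count_matrix(
    n: int = 2000,
    reps: int = 4,
    seed: int = 0,
    mu_range: tuple[float, float] = (1.0, 10_000.0),
    dispersion_fn=lambda mu: 0.05 + 2.0 / mu,
    zero_inflate_below: float | None = None,
    zero_inflate_frac: float = 0.5,
    group: str = "test",
) -> BarcodeCountMatrix:
    """NB counts with a known mean-dispersion relation, optionally
    zero-inflated below a mean cutoff."""
    rng = np.random.default_rng(seed)
    mu = np.exp(rng.uniform(np.log(mu_range[0]), np.log(mu_range[1]), n))
    alpha = dispersion_fn(mu)
    r = 1.0 / alpha
    K = rng.negative_binomial(r[:, None], (r / (r + mu))[:, None], size=(n, reps))
    if zero_inflate_below is not None:
        low = mu < zero_inflate_below
        drop = rng.random((n, reps)) < zero_inflate_frac
        K = np.where(low[:, None] & drop, 0, K)
    return BarcodeCountMatrix(
        [f"b{i:05d}" for i in range(n)], K,
        [f"{group[0]}{j}" for j in range(reps)], [group] * reps,
    )


@pytest.fixture(scope="session")
def null_design():
    return bottleneck_design(seed=1)


@pytest.fixture(scope="session")
def small_matrix():
    """Tiny 2-group matrix for interface tests."""
    counts = np.array([
        [10, 12, 20, 22],
        [100, 110, 95, 105],
        [0, 0, 0, 0],
        [5, 0, 9, 3],
    ])
    return BarcodeCountMatrix(
        ["bc1", "bc2", "bc3", "bc4"], counts,
        ["c1", "c2", "t1", "t2"], ["control", "control", "test", "test"],
    )
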