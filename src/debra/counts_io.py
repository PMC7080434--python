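"""Count-matrix data model, median-of-ratios normalization, and file plumbing.

The universal input of the package is a barcode-by-sample table of sequencing
read counts together with a sample sheet assigning each sample to the
``control`` or ``test`` group.  Counts are stored as 64-bit integers; all
normalized quantities are floating point.  No pseudocounts are added at this
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
TEST = "test"
_VALID_GROUPS = (CONTROL, TEST)


class CountMatrixError(ValueError):
    """Raised when a count matrix or sample sheet violates an invariant."""


@dataclass
class BarcodeCountMatrix:
    """Barcode x sample non-negative integer read counts with group labels.

    Parameters
    ----------
    barcode_ids
        Unique barcode identifiers (one per row of ``counts``).
    counts
        Integer array of shape ``(n_barcodes, n_samples)``; entry ``K[i, j]``
        is the read count of barcode *i* in sample *j*.
    sample_ids
        Sample identifiers (one per column).
    groups
        Group label per sample, each ``"control"`` or ``"test"``.
    """

    barcode_ids: np.ndarray
    counts: np.ndarray
    sample_ids: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.barcode_ids = np.asarray(self.barcode_ids, dtype=object)
        self.counts = np.asarray(self.counts)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.counts.ndim != 2:
            raise CountMatrixError("counts must be a 2-D barcode x sample array")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise CountMatrixError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise CountMatrixError("counts must be non-negative")
        if len(self.barcode_ids) != self.counts.shape[0]:
            raise CountMatrixError("barcode_ids length does not match counts")
        if len(self.sample_ids) != self.counts.shape[1]:
            raise CountMatrixError("sample_ids length does not match counts")
        if len(self.groups) != self.counts.shape[1]:
            raise CountMatrixError("every sample needs a group label")
        if len(set(self.barcode_ids)) != len(self.barcode_ids):
            raise CountMatrixError("barcode_ids must be unique")
        for g in self.groups:
            if g not in _VALID_GROUPS:
                raise CountMatrixError(
                    f"group labels must be 'control' or 'test', got {g!r}"
                )

    @property
    def n_barcodes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        if group not in _VALID_GROUPS:
            raise CountMatrixError(f"unknown group {group!r}")
        return self.groups == group

    def subset_samples(self, mask: np.ndarray) -> "BarcodeCountMatrix":
        mask = np.asarray(mask)
        return BarcodeCountMatrix(
            barcode_ids=self.barcode_ids,
            counts=self.counts[:, mask],
            sample_ids=self.sample_ids[mask],
            groups=self.groups[mask],
        )

    def restrict(self, group: str) -> "BarcodeCountMatrix":
        """Return the matrix restricted to the samples of one group."""
        mask = self.group_mask(group)
        if not mask.any():
            raise CountMatrixError(f"no samples in group {group!r}")
        return self.subset_samples(mask)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.barcode_ids, name="barcode"),
            columns=list(self.sample_ids),
        )


@dataclass
class SizeFactors:
    """Per-sample positive scaling factors from median-of-ratios normalization."""

    factors: np.ndarray = field()

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if (self.factors <= 0).any() or not np.isfinite(self.factors).all():
            raise CountMatrixError("size factors must be positive and finite")

    def __len__(self) -> int:
        return len(self.factors)

    def __array__(self, dtype=None, copy=None) -> np.ndarray:
        return np.asarray(self.factors, dtype=dtype)


def estimate_size_factors(counts: BarcodeCountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    For every barcode with strictly positive counts in all samples, the ratio
    of each sample's count to the barcode's geometric mean is formed; the
    size factor of a sample is the median of these ratios.  Geometric means
    are computed in log space.
    """
    K = counts.counts
    all_positive = (K > 0).all(axis=1)
    if not all_positive.any():
        raise CountMatrixError("no all-positive barcodes for normalization")
    logK = np.log(K[all_positive].astype(float))
    log_geo = logK.mean(axis=1, keepdims=True)
    ratios = np.exp(logK - log_geo)
    return SizeFactors(np.median(ratios, axis=0))


def normalized_counts(counts: BarcodeCountMatrix, sf: SizeFactors) -> np.ndarray:
    if len(sf) != counts.n_samples:
        raise CountMatrixError("size factors do not match samples")
    return counts.counts / np.asarray(sf)[None, :]


def normalized_means(
    counts: BarcodeCountMatrix, sf: SizeFactors, group: str | None = None
) -> np.ndarray:
    """Per-barcode mean of size-factor-normalized counts.

    ``group`` selects ``"control"`` or ``"test"`` samples; ``None`` averages
    over all samples.  This is the "mean count" / baseMean filter statistic.
    """
    norm = normalized_counts(counts, sf)
    if group is None:
        return norm.mean(axis=1)
    mask = counts.group_mask(group)
    if not mask.any():
        raise CountMatrixError(f"empty group selection: {group!r}")
    return norm[:, mask].mean(axis=1)


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------

def read_counts_tsv(counts_path, samples_path) -> BarcodeCountMatrix:
    """Read a count TSV (first column ``barcode``) and a sample sheet.

    The sample sheet is CSV or TSV with columns ``sample`` and ``group``
    (values ``control``/``test``); extra columns are preserved in the file
    but ignored here.  Only samples listed in the sheet are retained, in
    sheet order.
    """
    table = pd.read_csv(counts_path, sep="\t")
    if table.columns[0] != "barcode":
        raise CountMatrixError("count table must have 'barcode' as first column")
    sheet = _read_sample_sheet(samples_path)
    missing = [s for s in sheet["sample"] if s not in table.columns]
    if missing:
        raise CountMatrixError(f"samples missing from count table: {missing}")
    return BarcodeCountMatrix(
        barcode_ids=table["barcode"].to_numpy(dtype=object),
        counts=table[list(sheet["sample"])].to_numpy(),
        sample_ids=sheet["sample"].to_numpy(dtype=object),
        groups=sheet["group"].to_numpy(dtype=object),
    )


def _read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep=None, engine="python")
    for col in ("sample", "group"):
        if col not in sheet.columns:
            raise CountMatrixError(f"sample sheet needs a '{col}' column")
    sheet = sheet.copy()
    sheet["sample"] = sheet["sample"].astype(str)
    sheet["group"] = sheet["group"].astype(str)
    bad = set(sheet["group"]) - set(_VALID_GROUPS)
    if bad:
        raise CountMatrixError(f"sample sheet groups must be control/test, got {bad}")
    return sheet


def write_counts_tsv(counts: BarcodeCountMatrix, path) -> None:
    counts.to_frame().to_csv(path, sep="\t")


def write_results_tsv(results: pd.DataFrame, path) -> None:
    """Write a result table with the canonical column order."""
    cols = [
        "baseMean", "log2FoldChange", "stat", "pvalue", "padj",
        "filtered", "beta_used", "method",
    ]
    out = results[cols].copy()
    out.index.name = "barcode"
    out.to_csv(path, sep="\t")
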