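"""Trimmed max/min fold-change stability statistic and SEG calling.

For a gene with strictly positive expression values across samples, the
trimmed fold change at trim level k is

    FC_k = (k+1)-th largest value / (k+1)-th smallest value,

i.e. the k most extreme values on each side are discarded before forming
the max/min ratio. At k = 1 this is the second-highest over the
second-lowest value, which protects the ratio against a single aberrant
measurement per gene. Genes with FC at or below a cutoff (4.0 in the
headline analysis) are called stably expressed genes (SEGs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .matrix_io import ExpressionMatrix

__all__ = [
    "TrimmedFoldChange",
    "StabilityResult",
    "SegGrid",
    "trimmed_fold_change",
    "stability_table",
    "call_segs",
    "seg_gene_set",
    "seg_grid",
    "fc_distribution_summary",
]

DEFAULT_THRESHOLD = 4.0
DEFAULT_TRIM = 1
DEFAULT_GRID_THRESHOLDS = (3.0, 4.0, 5.0)
DEFAULT_GRID_TRIMS = (0, 1, 2, 3, 4)


class TrimmedFoldChange(NamedTuple):
    fc: float
    upper_value: float
    lower_value: float


@dataclass(frozen=True)
class StabilityResult:
    """Per-gene trimmed extremes and fold change at a given trim level."""

    gene_id: str
    fc: float
    upper_value: float
    lower_value: float
    trim_k: int


def _validate_positive(values: np.ndarray) -> None:
    if (values <= 0).any():
        raise ValueError(
            "expression values must be strictly positive; substitute zeros "
            "before computing fold changes"
        )


def trimmed_fold_change(
    values: Sequence[float],
    trim_k: int = DEFAULT_TRIM,
    *,
    k_high: int | None = None,
    k_low: int | None = None,
) -> TrimmedFoldChange:
    """Trimmed max/min fold change of one gene's expression vector.

    ``trim_k`` discards the k largest and k smallest values symmetrically;
    pass ``k_high`` / ``k_low`` for an asymmetric trim. Duplicated values
    occupy distinct sorted positions.
    """
    k_high = trim_k if k_high is None else k_high
    k_low = trim_k if k_low is None else k_low
    if k_high < 0 or k_low < 0:
        raise ValueError("trim counts must be non-negative")
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a one-dimensional vector of values")
    n = arr.size
    if n < k_high + k_low + 2:
        raise ValueError(
            f"need at least {k_high + k_low + 2} values to trim "
            f"{k_high} high and {k_low} low; got {n}"
        )
    _validate_positive(arr)
    ordered = np.sort(arr)
    upper = float(ordered[n - 1 - k_high])
    lower = float(ordered[k_low])
    return TrimmedFoldChange(fc=upper / lower, upper_value=upper, lower_value=lower)


def _trimmed_extremes_matrix(
    matrix: ExpressionMatrix, trim_k: int
) -> tuple[np.ndarray, np.ndarray]:
    values = matrix.values
    _validate_positive(values)
    n = matrix.n_samples
    if trim_k < 0:
        raise ValueError("trim_k must be non-negative")
    if n < 2 * (trim_k + 1):
        raise ValueError(
            f"need at least {2 * (trim_k + 1)} samples for trim_k={trim_k}; got {n}"
        )
    ordered = np.sort(values, axis=1)
    return ordered[:, n - 1 - trim_k], ordered[:, trim_k]


def stability_table(matrix: ExpressionMatrix, trim_k: int = DEFAULT_TRIM) -> pd.DataFrame:
    """Per-gene fc / upper_value / lower_value at one trim level, as a
    DataFrame indexed by gene_id."""
    upper, lower = _trimmed_extremes_matrix(matrix, trim_k)
    return pd.DataFrame(
        {
            "fc": upper / lower,
            "upper_value": upper,
            "lower_value": lower,
            "trim_k": trim_k,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )


def call_segs(
    matrix: ExpressionMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    trim_k: int = DEFAULT_TRIM,
) -> pd.DataFrame:
    """SEG calls for every gene: ``is_seg`` is True iff fc <= threshold
    (inclusive at the boundary)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    table = stability_table(matrix, trim_k)
    table["threshold"] = threshold
    table["is_seg"] = table["fc"] <= threshold
    return table


def seg_gene_set(
    matrix: ExpressionMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    trim_k: int = DEFAULT_TRIM,
) -> set[str]:
    calls = call_segs(matrix, threshold, trim_k)
    return set(calls.index[calls["is_seg"]])


@dataclass(frozen=True)
class SegGrid:
    """SEG counts over a fold-change-threshold x trim-level grid."""

    thresholds: tuple[float, ...]
    trims: tuple[int, ...]
    counts: np.ndarray  # |thresholds| x |trims|

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.thresholds), len(self.trims)):
            raise ValueError("counts shape does not match thresholds x trims")
        if (np.diff(counts, axis=0) < 0).any():
            raise ValueError("SEG counts must be non-decreasing in threshold")
        if (np.diff(counts, axis=1) < 0).any():
            raise ValueError("SEG counts must be non-decreasing in trim")
        object.__setattr__(self, "counts", counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.thresholds, name="threshold"),
            columns=pd.Index(self.trims, name="trim_k"),
        )


def seg_grid(
    matrix: ExpressionMatrix,
    thresholds: Sequence[float] = DEFAULT_GRID_THRESHOLDS,
    trims: Sequence[int] = DEFAULT_GRID_TRIMS,
) -> SegGrid:
    """Count SEGs at every combination of fold-change cutoff and symmetric
    trim level (the threshold-robustness grid)."""
    thresholds = tuple(sorted(float(t) for t in thresholds))
    trims = tuple(sorted(int(k) for k in trims))
    fcs = []
    for trim_k in trims:
        upper, lower = _trimmed_extremes_matrix(matrix, trim_k)
        fcs.append(upper / lower)
    counts = np.array(
        [[int((fc <= threshold).sum()) for fc in fcs] for threshold in thresholds]
    )
    return SegGrid(thresholds=thresholds, trims=trims, counts=counts)


def fc_distribution_summary(
    matrix: ExpressionMatrix,
    trim_k: int = DEFAULT_TRIM,
    bin_edges: Sequence[float] | None = None,
) -> dict:
    """Min / max / median of the per-gene fold changes plus a histogram over
    log-spaced bins (default: decade bins from 1 to 1e10, with overflow
    collected into the last bin)."""
    upper, lower = _trimmed_extremes_matrix(matrix, trim_k)
    fc = upper / lower
    if bin_edges is None:
        edges = np.logspace(0, 10, 11)
    else:
        edges = np.asarray(bin_edges, dtype=float)
    clipped = np.minimum(fc, edges[-1])
    counts, _ = np.histogram(clipped, bins=edges)
    return {
        "n_genes": int(fc.size),
        "fc_min": float(fc.min()),
        "fc_max": float(fc.max()),
        "fc_median": float(np.median(fc)),
        "bin_edges": edges.tolist(),
        "bin_counts": counts.tolist(),
    }
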