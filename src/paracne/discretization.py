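"""Iterative quantile discretization (IQD) of sparse spectral-count vectors.

Spectral counts are discrete, zero-dominated and heavily tied, so fixed-width
or naive quantile binning either fragments tie groups or leaves most bins
empty.  IQD instead partitions the N samples of one peptide into M bins of
as-equal-as-possible occupancy while keeping every tie group (all samples
sharing a count value) in a single bin: sort by count, fill the current bin
until its quantile quota ``remaining_points / remaining_bins`` is reached,
absorbing whole tie groups, then recompute the quota for the remaining points
and bins.  The canonical special case: with a majority of zeros, all zeros
land in bin 1 and the nonzero values are re-partitioned over the remaining
bins.

The effective number of bins is capped by the number of distinct count
values; a constant vector always yields a single bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phospho_io import SpectralCountMatrix

__all__ = ["BinAssignment", "iqd_discretize", "discretize_matrix"]


@dataclass
class BinAssignment:
    """Per-sample bin labels in ``1..m_effective``, aligned with the input."""

    labels: np.ndarray
    m_requested: int
    m_effective: int

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def zero_based(self) -> np.ndarray:
        return self.labels - 1

    def occupancies(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.m_effective + 1)[1:]


def iqd_discretize(x, m: int) -> BinAssignment:
    """Discretize one count vector into ``m`` near-uniform bins, ties intact.

    Parameters
    ----------
    x
        Vector of non-negative integer counts (length >= 1).
    m
        Requested number of bins (>= 1).  The effective number of bins is
        ``min(m, number of distinct values)``.
    """
    if int(m) != m or m < 1:
        raise ValueError(f"number of bins must be a positive integer, got {m!r}")
    m = int(m)
    x = np.asarray(x)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("input must be a non-empty 1-D vector")
    if not np.issubdtype(x.dtype, np.integer):
        if np.any(x != np.floor(x)):
            raise ValueError("counts must be integers")
        x = x.astype(np.int64)
    if x.min() < 0:
        raise ValueError("counts must be non-negative")

    n = x.size
    # stable order: by (count value, original index) for reproducibility
    order = np.lexsort((np.arange(n), x))
    xs = x[order]
    # tie-group boundaries in the sorted vector
    starts = np.concatenate(([0], np.flatnonzero(np.diff(xs)) + 1, [n]))

    labels_sorted = np.empty(n, dtype=np.int64)
    bin_id = 1
    bins_left = m
    points_left = n
    occupancy = 0
    for g in range(len(starts) - 1):
        lo, hi = starts[g], starts[g + 1]
        labels_sorted[lo:hi] = bin_id
        occupancy += hi - lo
        # close the bin once its quota (points_left / bins_left) is reached;
        # integer comparison avoids float quotas.  A tie group that crosses
        # the quota is absorbed whole into the current bin.
        if bins_left > 1 and occupancy * bins_left >= points_left and hi < n:
            points_left -= occupancy
            bins_left -= 1
            occupancy = 0
            bin_id += 1

    labels = np.empty(n, dtype=np.int64)
    labels[order] = labels_sorted
    return BinAssignment(labels=labels, m_requested=m, m_effective=int(bin_id))


def discretize_matrix(matrix: SpectralCountMatrix, m: int) -> list[BinAssignment]:
    """Row-wise IQD of a count matrix; rows are independent."""
    out = []
    for peptide, row in zip(matrix.peptides, matrix.counts):
        try:
            out.append(iqd_discretize(row, m))
        except ValueError as exc:
            raise ValueError(
                f"row {peptide.format('dollar')!r}: {exc}"
            ) from exc
    return out
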