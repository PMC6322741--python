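"""Plug-in mutual information on binned count data, and bin-number selection.

For two discretized profiles with joint bin counts ``k_ij`` over ``N``
samples, the plug-in (histogram) estimator is

    I(X, Y) = log N + (1/N) * sum_ij k_ij * log(k_ij / (k_i * k_j))

in nats, which equals the Shannon MI of the empirical joint distribution.
Significance can be assessed either by permuting one profile (exact but with
resolution 1/(n_perm+1)) or through the identity G = 2*N*I, which under
independence is asymptotically chi-squared with (Mx-1)(My-1) degrees of
freedom; the analytic tail is what makes Bonferroni-scale thresholds
resolvable when screening thousands of candidate pairs.

The number of bins M is a tuning parameter: too few bins lose signal, too
many overfit N samples.  ``select_bin_number`` sweeps M, scores the inferred
sub-network restricted to a gold standard of known kinase->substrate pairs,
and picks the M with the best precision/sensitivity trade-off (F1 by
default).  Without a gold standard the default is M = 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .discretization import BinAssignment
from .phospho_io import GoldStandard, KinaseList, SpectralCountMatrix

__all__ = [
    "JointCountTable",
    "plugin_mi",
    "plugin_mi_from_labels",
    "mi_pvalue",
    "gtest_pvalue",
    "BinSweepResult",
    "select_bin_number",
]

DEFAULT_BINS = 10


@dataclass
class JointCountTable:
    """Joint bin-count table; marginals and N are derived and validated."""

    k_ij: np.ndarray
    k_i: np.ndarray | None = None
    k_j: np.ndarray | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        k = np.asarray(self.k_ij)
        if k.ndim != 2:
            raise ValueError("joint count table must be 2-D")
        if np.any(k < 0) or np.any(k != np.floor(k)):
            raise ValueError("joint counts must be non-negative integers")
        k = k.astype(np.int64)
        ki, kj, n = k.sum(axis=1), k.sum(axis=0), int(k.sum())
        if self.k_i is not None and not np.array_equal(np.asarray(self.k_i), ki):
            raise ValueError("row marginals inconsistent with joint counts")
        if self.k_j is not None and not np.array_equal(np.asarray(self.k_j), kj):
            raise ValueError("column marginals inconsistent with joint counts")
        if self.n is not None and self.n != n:
            raise ValueError("total N inconsistent with joint counts")
        self.k_ij, self.k_i, self.k_j, self.n = k, ki, kj, n

    @classmethod
    def from_labels(cls, x, y) -> "JointCountTable":
        x, y = _as_labels(x), _as_labels(y)
        if x.shape != y.shape:
            raise ValueError("label vectors differ in length")
        mx, my = int(x.max()) + 1, int(y.max()) + 1
        k = np.bincount(x * my + y, minlength=mx * my).reshape(mx, my)
        return cls(k)

    @property
    def dof(self) -> int:
        """Independence-test degrees of freedom over occupied bins."""
        return max(int(np.count_nonzero(self.k_i)) - 1, 0) * max(
            int(np.count_nonzero(self.k_j)) - 1, 0
        )


def _as_labels(v) -> np.ndarray:
    if isinstance(v, BinAssignment):
        return v.zero_based
    v = np.asarray(v, dtype=np.int64)
    return v - v.min() if v.size and v.min() > 0 else v


def plugin_mi(table: JointCountTable | np.ndarray) -> float:
    """Plug-in MI (nats) of a joint count table; 0*log(0) terms are 0."""
    if not isinstance(table, JointCountTable):
        table = JointCountTable(table)
    k, ki, kj, n = table.k_ij, table.k_i, table.k_j, table.n
    if n < 1:
        raise ValueError("empty table")
    nz = k > 0
    denom = np.outer(ki, kj)[nz]
    terms = k[nz] * (np.log(k[nz]) - np.log(denom))
    mi = np.log(n) + terms.sum() / n
    # analytically >= 0; clamp float round-off on independent tables
    return float(max(mi, 0.0))


def plugin_mi_from_labels(x, y) -> float:
    return plugin_mi(JointCountTable.from_labels(x, y))


def mi_pvalue(x, y, n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation p-value for MI(x, y), permuting the y labels.

    p = (1 + #{permuted MI >= observed}) / (1 + n_perm); the smallest
    attainable value is 1/(1+n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x, y = _as_labels(x), _as_labels(y)
    if x.shape != y.shape:
        raise ValueError("label vectors differ in length")
    rng = np.random.default_rng(seed)
    observed = plugin_mi_from_labels(x, y)
    hits = 0
    for _ in range(n_perm):
        if plugin_mi_from_labels(x, rng.permutation(y)) >= observed - 1e-15:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def gtest_pvalue(table: JointCountTable | np.ndarray) -> float:
    """Analytic independence p-value via G = 2*N*MI ~ chi2(dof)."""
    if not isinstance(table, JointCountTable):
        table = JointCountTable(table)
    dof = table.dof
    if dof == 0:
        return 1.0
    g = 2.0 * table.n * plugin_mi(table)
    return float(stats.chi2.sf(g, dof))


def mi_profile(x: np.ndarray, targets: np.ndarray):
    """Vectorized MI of one label vector against many.

    Parameters
    ----------
    x
        0-based labels, shape (n,).
    targets
        0-based labels, shape (r, n).

    Returns
    -------
    (mi, dof) arrays of shape (r,): plug-in MI in nats and the occupied-bin
    chi-squared degrees of freedom per pair.
    """
    r, n = targets.shape
    mx = int(x.max()) + 1
    my = int(targets.max()) + 1 if targets.size else 1
    flat = (np.arange(r)[:, None] * (mx * my) + x[None, :] * my + targets).ravel()
    k = np.bincount(flat, minlength=r * mx * my).reshape(r, mx, my)
    ki = k.sum(axis=2)  # (r, mx)
    kj = k.sum(axis=1)  # (r, my)
    with np.errstate(divide="ignore", invalid="ignore"):
        logterm = np.log(k) - np.log(ki)[:, :, None] - np.log(kj)[:, None, :]
    logterm[k == 0] = 0.0
    contrib = k * logterm
    mi = np.log(n) + contrib.sum(axis=(1, 2)) / n
    mi = np.maximum(mi, 0.0)
    dof = np.maximum((ki > 0).sum(axis=1) - 1, 0) * np.maximum(
        (kj > 0).sum(axis=1) - 1, 0
    )
    return mi, dof


@dataclass
class SweepRecord:
    m: int
    precision: float
    sensitivity: float
    f_score: float
    n_edges: int


@dataclass
class BinSweepResult:
    records: list[SweepRecord]
    chosen_m: int


def select_bin_number(
    matrix: SpectralCountMatrix,
    gold: GoldStandard | None,
    kinases: KinaseList,
    m_range=range(2, 21),
    alpha: float = 0.05,
    tolerance: float = 0.0,
) -> BinSweepResult:
    """Sweep the bin number M against a gold standard of known gene-level edges.

    For each M the candidate network is inferred on the sub-matrix restricted
    to gold-standard genes, projected to gene level, and scored against the
    gold standard: precision = TP/(TP+FP), sensitivity = TP/(TP+FN) over gold
    edges whose genes are measured.  ``chosen_m`` maximizes the F1 score
    (smallest M on ties).  With no gold standard the default M = 10 is
    returned without a sweep.
    """
    m_range = list(m_range)
    if not m_range:
        raise ValueError("empty bin range")
    if gold is None or len(gold) == 0:
        return BinSweepResult(records=[], chosen_m=DEFAULT_BINS)
    from .core import aggregate_to_protein, apply_dpi, infer_candidate_edges

    gs_genes = gold.genes
    keep = [i for i, p in enumerate(matrix.peptides) if p.gene in gs_genes]
    if not keep:
        raise ValueError("no matrix gene overlaps the gold standard")
    sub = SpectralCountMatrix(
        [matrix.peptides[i] for i in keep],
        list(matrix.samples),
        matrix.counts[keep],
        matrix.sample_classes,
    )
    measured = {p.gene for p in sub.peptides}
    gold_measured = {
        e for e in gold.edges if e[0] in measured and e[1] in measured
    }
    if not gold_measured:
        raise ValueError("no gold-standard edge has both genes in the matrix")

    records = []
    for m in m_range:
        try:
            net = apply_dpi(
                infer_candidate_edges(sub, kinases, m=m, alpha=alpha), tolerance
            )
        except ValueError:
            records.append(SweepRecord(m, 0.0, 0.0, 0.0, 0))
            continue
        if len(net) == 0:
            records.append(SweepRecord(m, 0.0, 0.0, 0.0, 0))
            continue
        predicted = aggregate_to_protein(net).gene_pairs()
        tp = len(predicted & gold_measured)
        precision = tp / len(predicted) if predicted else 0.0
        sensitivity = tp / len(gold_measured)
        f = (
            2 * precision * sensitivity / (precision + sensitivity)
            if precision + sensitivity > 0
            else 0.0
        )
        records.append(SweepRecord(m, precision, sensitivity, f, len(predicted)))
    best = max(records, key=lambda r: (r.f_score, -r.m))
    return BinSweepResult(records=records, chosen_m=best.m)
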