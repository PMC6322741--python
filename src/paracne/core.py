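"""End-to-end kinase->substrate network inference.

Pipeline stages, each exposed as a function:

1. ``infer_candidate_edges`` — every (kinase peptide, other peptide) pair is
   scored by plug-in MI on IQD-discretized rows; pairs passing a
   Bonferroni-corrected independence test become candidate edges.  Distinct
   phosphosites of the same gene are eligible targets, so cis/trans
   autophosphorylation shows up as same-gene or kinase-kinase edges.
2. ``apply_dpi`` — data-processing-inequality pruning: in every triangle of
   network edges the weakest edge is the candidate indirect path and is
   removed when its MI is strictly below ``(1 - tolerance)`` times the
   smaller of the other two.
3. ``bootstrap_consolidate`` — the inference+DPI run is repeated on B
   sample-bootstraps; an edge's support count is tested against a Poisson
   model of the per-edge mean support (Bonferroni over distinct edges), or
   against a simple majority vote.
4. ``annotate_spearman`` / ``aggregate_to_protein`` / ``tk_tk_bias_test`` —
   edge-sign annotation on the raw counts, gene-level max-MI projection, and
   a hypergeometric test for enrichment of kinase-kinase edges.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats

from .discretization import discretize_matrix
from .mutual_information import mi_pvalue, mi_profile
from .networks import Edge, ProteinEdge, ProteinNetwork, SignalingNetwork
from .phospho_io import KinaseList, PeptideID, SpectralCountMatrix

__all__ = [
    "infer_candidate_edges",
    "apply_dpi",
    "bootstrap_consolidate",
    "consolidate_support",
    "annotate_spearman",
    "negative_correlation_summary",
    "aggregate_to_protein",
    "tk_tk_bias_test",
]


def _kinase_rows(matrix: SpectralCountMatrix, kinases: KinaseList) -> list[int]:
    return [i for i, p in enumerate(matrix.peptides) if p.gene in kinases]


def infer_candidate_edges(
    matrix: SpectralCountMatrix,
    kinases: KinaseList,
    m: int = 10,
    alpha: float = 0.05,
    method: str = "gtest",
    n_perm: int = 1000,
    seed: int = 0,
) -> SignalingNetwork:
    """Score all kinase-peptide x peptide pairs and keep the significant ones.

    Every row is IQD-discretized into ``m`` bins; each kinase peptide is
    paired with every other peptide (self-pairs excluded; kinase-kinase pairs
    scored once, regulator = lower row).  ``method='gtest'`` uses the analytic
    chi-squared tail of G = 2*N*MI; ``method='permutation'`` uses the per-pair
    permutation p-value (much slower, resolution-limited).  Significance is
    Bonferroni-corrected over all tested pairs at level ``alpha``.
    """
    if m < 2:
        raise ValueError("need at least 2 bins to detect dependence")
    kin = _kinase_rows(matrix, kinases)
    if not kin:
        raise ValueError("no kinase-list gene matches a matrix peptide")
    kin_set = set(kin)
    assignments = discretize_matrix(matrix, m)
    labels = np.vstack([a.zero_based for a in assignments])

    pairs: list[tuple[int, int]] = []
    blocks: list[tuple[int, list[int]]] = []
    for rank, i in enumerate(kin):
        targets = [
            j
            for j in range(matrix.n_peptides)
            if j != i and not (j in kin_set and kin.index(j) < rank)
        ]
        if targets:
            blocks.append((i, targets))
            pairs.extend((i, j) for j in targets)
    n_pairs = len(pairs)
    if n_pairs == 0:
        return SignalingNetwork([])
    threshold = alpha / n_pairs

    edges: list[Edge] = []
    for i, targets in blocks:
        x = labels[i]
        tmat = labels[targets]
        mi, dof = mi_profile(x, tmat)
        if method == "gtest":
            n = matrix.n_samples
            pvals = np.where(
                dof > 0, stats.chi2.sf(2.0 * n * mi, np.maximum(dof, 1)), 1.0
            )
        elif method == "permutation":
            pvals = np.array(
                [
                    mi_pvalue(x, labels[j], n_perm=n_perm, seed=seed + 7919 * j + i)
                    for j in targets
                ]
            )
        else:
            raise ValueError(f"unknown method {method!r}")
        for j, mi_ij, p in zip(targets, mi, pvals):
            if p <= threshold:
                edges.append(Edge(matrix.peptides[i], matrix.peptides[j], float(mi_ij)))
    return SignalingNetwork(edges)


def _pair_key(a: PeptideID, b: PeptideID) -> tuple[PeptideID, PeptideID]:
    return (a, b) if a <= b else (b, a)


def apply_dpi(net: SignalingNetwork, tolerance: float = 0.0) -> SignalingNetwork:
    """Remove likely-indirect edges by the data processing inequality.

    For a Markov chain TK1 -> TK2 -> S, I(TK1, S) <= min(I(TK1, TK2),
    I(TK2, S)); so in every triangle of network edges the minimum-MI edge is
    removed when strictly below ``(1 - tolerance) * min(other two)``.
    Decisions are taken on the input network and applied at once (an edge
    cannot be saved by another edge's earlier removal).  Only regulator pairs
    can close triangles: substrate-substrate pairs are never scored, so every
    network triangle has two kinase vertices.
    """
    if not 0.0 <= tolerance < 1.0:
        raise ValueError("tolerance must be in [0, 1)")
    mi: dict[tuple[PeptideID, PeptideID], float] = {}
    adjacency: dict[PeptideID, set[PeptideID]] = {}
    for e in net.edges:
        mi[_pair_key(e.regulator, e.substrate)] = e.mi
        adjacency.setdefault(e.regulator, set()).add(e.substrate)
        adjacency.setdefault(e.substrate, set()).add(e.regulator)

    regulators = sorted(net.regulators)
    marked: set[tuple[PeptideID, PeptideID]] = set()
    for k1, k2 in itertools.combinations(regulators, 2):
        kk = _pair_key(k1, k2)
        if kk not in mi:
            continue
        for s in adjacency[k1] & adjacency[k2]:
            if s in (k1, k2):
                continue
            trio = [kk, _pair_key(k1, s), _pair_key(k2, s)]
            mis = [mi[t] for t in trio]
            order = sorted(range(3), key=lambda t: mis[t])
            weakest, runner_up = order[0], order[1]
            if mis[weakest] < (1.0 - tolerance) * mis[runner_up]:
                marked.add(trio[weakest])
    return SignalingNetwork(
        [e for e in net.edges if _pair_key(e.regulator, e.substrate) not in marked]
    )


def bootstrap_consolidate(
    matrix: SpectralCountMatrix,
    kinases: KinaseList,
    m: int = 10,
    alpha: float = 0.05,
    tolerance: float = 0.0,
    b: int = 100,
    seed: int = 0,
    consolidation: str = "poisson",
    method: str = "gtest",
) -> SignalingNetwork:
    """Bootstrap the sample set B times and keep reproducibly supported edges.

    Each bootstrap resamples the columns with replacement and reruns
    inference + DPI.  Under ``consolidation='poisson'`` an edge with support
    s is kept when the Poisson upper tail P(X >= s) at mean = total support /
    distinct edges clears a Bonferroni-corrected 0.05; ``'majority'`` keeps
    edges present in more than half the bootstraps.  The consolidated MI is
    the mean over supporting bootstraps.
    """
    if b < 2:
        raise ValueError("need at least 2 bootstraps")
    rng = np.random.default_rng(seed)
    support: dict[tuple[PeptideID, PeptideID], int] = {}
    mi_sum: dict[tuple[PeptideID, PeptideID], float] = {}
    for _ in range(b):
        idx = rng.integers(0, matrix.n_samples, matrix.n_samples)
        boot = matrix.resample_columns(idx)
        net = apply_dpi(
            infer_candidate_edges(boot, kinases, m=m, alpha=alpha, method=method),
            tolerance,
        )
        for e in net.edges:
            support[e.key] = support.get(e.key, 0) + 1
            mi_sum[e.key] = mi_sum.get(e.key, 0.0) + e.mi
    if not support:
        return SignalingNetwork([])

    counts = np.array(list(support.values()))
    keep = consolidate_support(counts, b, consolidation)
    edges = [
        Edge(reg, sub, mi_sum[(reg, sub)] / s, support=int(s))
        for ((reg, sub), s), ok in zip(support.items(), keep)
        if ok
    ]
    return SignalingNetwork(edges)


def consolidate_support(
    counts: np.ndarray, b: int, consolidation: str = "poisson"
) -> np.ndarray:
    """Boolean keep-mask over per-edge bootstrap support counts.

    ``'poisson'``: edge kept when its support is significantly above the
    per-edge mean support (Poisson upper tail, Bonferroni over distinct
    edges at 0.05).  ``'majority'``: kept when present in more than half the
    bootstraps.
    """
    counts = np.asarray(counts)
    if consolidation == "poisson":
        mu = counts.sum() / counts.size
        pvals = stats.poisson.sf(counts - 1, mu)
        # the Poisson tail is a sporadic-noise filter; when most edges are
        # reproducible the mean support approaches b and the test saturates,
        # but presence in every single bootstrap is never sporadic
        return (pvals * counts.size < 0.05) | (counts == b)
    if consolidation == "majority":
        return counts > b / 2
    raise ValueError(f"unknown consolidation {consolidation!r}")


def annotate_spearman(
    net: SignalingNetwork, matrix: SpectralCountMatrix
) -> SignalingNetwork:
    """Attach a Spearman correlation (on the raw counts) to every edge.

    A constant regulator or substrate row has no defined rank correlation;
    such edges are flagged with rho = NaN and excluded from sign summaries.
    """
    edges = []
    for e in net.edges:
        x = matrix.row(e.regulator)
        y = matrix.row(e.substrate)
        if np.all(x == x[0]) or np.all(y == y[0]):
            edges.append(e.with_(rho=math.nan, rho_p=math.nan))
            continue
        rho, p = stats.spearmanr(x, y)
        edges.append(e.with_(rho=float(rho), rho_p=float(p)))
    return SignalingNetwork(edges)


def negative_correlation_summary(
    net: SignalingNetwork, alpha: float = 0.05
) -> tuple[int, float]:
    """Count and fraction of significantly negative edges (rho < 0, p <= alpha).

    The denominator is the number of edges with a defined correlation;
    degenerate (NaN) edges are excluded.
    """
    defined = [e for e in net.edges if e.rho is not None and not math.isnan(e.rho)]
    if not defined:
        return 0, math.nan
    neg = sum(1 for e in defined if e.rho < 0 and e.rho_p <= alpha)
    return neg, neg / len(defined)


def aggregate_to_protein(net: SignalingNetwork) -> ProteinNetwork:
    """Project to gene level, keeping the max MI over contributing peptide edges."""
    if len(net) == 0:
        raise ValueError("cannot aggregate an empty network")
    agg: dict[tuple[str, str], float] = {}
    for e in net.edges:
        key = (e.regulator.gene, e.substrate.gene)
        if key not in agg or e.mi > agg[key]:
            agg[key] = e.mi
    return ProteinNetwork(
        [ProteinEdge(k, s, mi) for (k, s), mi in sorted(agg.items())]
    )


def tk_tk_bias_test(
    pn: ProteinNetwork, kinases: KinaseList, n_total_targets: int,
    n_tk_targets: int | None = None,
) -> float:
    """Hypergeometric upper tail for enrichment of kinase-kinase edges.

    Under the null the ``n`` network targets are drawn uniformly from
    ``n_total_targets`` candidate genes of which ``n_tk_targets`` are
    kinases; returns P(#TK-TK edges >= observed).
    """
    if len(pn) == 0:
        raise ValueError("empty protein network")
    if n_tk_targets is None:
        n_tk_targets = len(kinases)
    n_edges = len(pn)
    observed = sum(1 for e in pn.edges if e.substrate in kinases)
    return float(
        stats.hypergeom.sf(observed - 1, n_total_targets, n_tk_targets, n_edges)
    )
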