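"""Synthetic ground-truth networks and LUAD-like spectral-count matrices.

The generator emulates the character of immunoaffinity-enriched
phosphotyrosine LC-MS/MS spectral counting: a few dozen tyrosine kinases
among a few thousand peptides, counts that are small non-negative integers
with a majority of zero cells and a right-skewed low-abundance tail, and
predominantly positive kinase<->substrate phospho-state coupling.  Defaults
are a scaled-down version of such a compendium (10 kinases, 100 substrate
proteins, 250 samples split ~154 tumors / 46 cell lines / 50 normals, 60%
zero cells) so that a full inference run is testable in seconds.

Mechanism: each kinase has a latent activity per sample (standard normal in
tumors and cell lines, tightly distributed around baseline in normals,
optionally spiked for designated kinase/sample combinations); kinase-kinase
edges propagate activity; each substrate's latent phospho-state is
``coupling * mean(parent activities) + sqrt(1 - coupling^2) * noise``.
Counts are negative-binomial draws whose log-rate follows the latent state,
with the global intercept calibrated so the expected zero fraction matches
``zero_inflation`` — zeros are therefore abundance-dependent non-detections,
as in real spectral counting, not an independent dropout mask.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field, replace

import numpy as np

from .networks import Edge, SignalingNetwork
from .phospho_io import KinaseList, PeptideID, SpectralCountMatrix

__all__ = [
    "SimulationConfig",
    "simulate_truth",
    "simulate_counts",
    "simulate_dataset",
    "gene_level_performance",
]

_PEPTIDE_LATENT_R = 0.9  # latent correlation of secondary peptides of a protein
_LATENT_SLOPE = 2.5  # log-rate units per latent sd (sets count dynamic range)
_BASE_ABUNDANCE_SD = 0.8  # between-peptide abundance spread (log scale)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset; ``seed`` is mandatory."""

    seed: int
    n_tk: int = 10
    n_substrates: int = 100
    n_tumor: int = 154
    n_cell_line: int = 46
    n_normal: int = 50
    edges_per_tk: int = 10
    shared_substrate_fraction: float = 0.5
    n_synergistic_pairs: int = 1
    n_tk_tk_edges: int = 2
    zero_inflation: float = 0.6
    count_dispersion: float = 4.0
    coupling_strength: float = 0.8
    negative_edge_fraction: float = 0.005
    multi_peptide_fraction: float = 0.2
    normal_activity_sd: float = 0.3
    spike_magnitude: float = 3.0
    spike_tks: tuple[str, ...] = ()
    spike_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in (
            "shared_substrate_fraction",
            "zero_inflation",
            "coupling_strength",
            "negative_edge_fraction",
            "multi_peptide_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.edges_per_tk > self.n_substrates:
            raise ValueError("edges_per_tk exceeds the number of substrates")
        if self.n_synergistic_pairs > 0:
            n_shared = round(self.shared_substrate_fraction * self.edges_per_tk)
            if 2 * self.edges_per_tk - n_shared > self.n_substrates:
                raise ValueError(
                    "a synergistic pair needs 2*edges_per_tk - shared "
                    "substrates; reduce edges_per_tk or add substrates"
                )
        if min(self.n_tk, self.n_substrates, self.n_tumor + self.n_cell_line,
               self.n_normal) < 1:
            raise ValueError("counts must be positive")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be positive")
        if 2 * self.n_synergistic_pairs > self.n_tk:
            raise ValueError("too many synergistic pairs for n_tk")

    @property
    def n_samples(self) -> int:
        return self.n_tumor + self.n_cell_line + self.n_normal

    def tk_genes(self) -> list[str]:
        return [f"TK{i + 1:02d}" for i in range(self.n_tk)]

    def substrate_genes(self) -> list[str]:
        return [f"SUB{j + 1:03d}" for j in range(self.n_substrates)]

    def sample_labels(self) -> tuple[list[str], dict[str, str]]:
        labels, classes = [], {}
        for prefix, cls, n in (
            ("T", "tumor", self.n_tumor),
            ("C", "cell_line", self.n_cell_line),
            ("N", "normal", self.n_normal),
        ):
            for i in range(n):
                lab = f"{prefix}{i + 1:03d}"
                labels.append(lab)
                classes[lab] = cls
        return labels, classes


@dataclass
class GroundTruth:
    """Planted topology plus the latent bookkeeping needed to simulate counts."""

    network: SignalingNetwork
    kinases: KinaseList
    peptides: list[PeptideID]
    gene_parents: dict[str, list[tuple[str, int]]]  # substrate -> [(tk, sign)]
    tk_parents: dict[str, str] = field(default_factory=dict)  # child tk -> parent tk
    synergistic_pairs: list[tuple[str, str]] = field(default_factory=list)


def simulate_truth(cfg: SimulationConfig) -> tuple[GroundTruth, KinaseList]:
    """Draw a bipartite-plus-TK-TK topology with planted synergistic pairs."""
    rng = np.random.default_rng(cfg.seed)
    tks = cfg.tk_genes()
    subs = cfg.substrate_genes()
    kinases = KinaseList.from_symbols(tks)

    # synergistic pairs share a fixed fraction of their substrate sets
    gene_parents: dict[str, list[tuple[str, int]]] = {}
    pairs = [(tks[2 * i], tks[2 * i + 1]) for i in range(cfg.n_synergistic_pairs)]
    paired = {g for p in pairs for g in p}
    n_shared = round(cfg.shared_substrate_fraction * cfg.edges_per_tk)

    def attach(tk: str, targets) -> None:
        for t in targets:
            gene_parents.setdefault(t, []).append(
                (tk, -1 if rng.random() < cfg.negative_edge_fraction else 1)
            )

    for a, b in pairs:
        chosen = rng.choice(subs, size=2 * cfg.edges_per_tk - n_shared, replace=False)
        shared = chosen[:n_shared]
        ua = chosen[n_shared : cfg.edges_per_tk]
        ub = chosen[cfg.edges_per_tk :]
        attach(a, np.concatenate([shared, ua]))
        attach(b, np.concatenate([shared, ub]))
    for tk in tks:
        if tk not in paired:
            attach(tk, rng.choice(subs, size=cfg.edges_per_tk, replace=False))

    # TK->TK edges form a forest directed from lower to higher index
    tk_parents: dict[str, str] = {}
    if cfg.n_tk_tk_edges > 0 and cfg.n_tk > 1:
        children = rng.choice(
            range(1, cfg.n_tk), size=min(cfg.n_tk_tk_edges, cfg.n_tk - 1),
            replace=False,
        )
        for c in children:
            tk_parents[tks[c]] = tks[int(rng.integers(0, c))]

    # peptide layer: every gene emits >= 1 peptide; a configurable fraction
    # of genes emits 2 so protein-level aggregation is exercised
    peptides: dict[str, list[PeptideID]] = {}
    for gene in tks + subs:
        n_pep = 2 if rng.random() < cfg.multi_peptide_fraction else 1
        sites = sorted(rng.choice(range(100, 1400), size=n_pep, replace=False))
        peptides[gene] = [PeptideID(gene, (int(s),)) for s in sites]

    edges = []
    for sub_gene, parents in gene_parents.items():
        for tk, sign in parents:
            for rp in peptides[tk]:
                for sp in peptides[sub_gene]:
                    edges.append(Edge(rp, sp, mi=cfg.coupling_strength,
                                      rho=float(sign)))
    for child, parent in tk_parents.items():
        for rp in peptides[parent]:
            for sp in peptides[child]:
                edges.append(Edge(rp, sp, mi=cfg.coupling_strength, rho=1.0))

    all_peptides = [p for gene in tks + subs for p in peptides[gene]]
    truth = GroundTruth(
        network=SignalingNetwork(edges),
        kinases=kinases,
        peptides=all_peptides,
        gene_parents=gene_parents,
        tk_parents=tk_parents,
        synergistic_pairs=pairs,
    )
    return truth, kinases


def _calibrate_intercept(lam_unit: np.ndarray, r: float, target: float) -> float:
    """Bisect the log intercept so mean NB zero probability hits ``target``."""

    def zero_fraction(c: float) -> float:
        lam = lam_unit * np.exp(c)
        return float(np.mean((r / (r + lam)) ** r))

    lo, hi = -30.0, 10.0
    if zero_fraction(hi) > target:  # even huge rates cannot reach so few zeros
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if zero_fraction(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_counts(truth: GroundTruth, cfg: SimulationConfig) -> SpectralCountMatrix:
    """Draw a spectral-count matrix from the planted topology."""
    rng = np.random.default_rng(cfg.seed + 1)
    labels, classes = cfg.sample_labels()
    n = len(labels)
    tks = cfg.tk_genes()
    is_normal = np.array([classes[s] == "normal" for s in labels])

    # kinase latent activity
    activity: dict[str, np.ndarray] = {}
    for tk in tks:
        a = rng.normal(0.0, 1.0, n)
        a[is_normal] = rng.normal(0.0, cfg.normal_activity_sd, int(is_normal.sum()))
        activity[tk] = a
    c = cfg.coupling_strength
    for tk in tks:  # index order = topological order of the TK forest
        parent = truth.tk_parents.get(tk)
        if parent is not None:
            activity[tk] = c * activity[parent] + np.sqrt(1 - c**2) * activity[tk]
    if cfg.spike_tks:
        # spiked samples model a targeted activation experiment: every kinase
        # is reset to quiescent baseline variation, then the designated ones
        # are pinned exactly spike_magnitude activity-sd above baseline
        spike_cols = [labels.index(s) for s in cfg.spike_samples]
        for tk in tks:
            activity[tk][spike_cols] = rng.normal(
                0.0, cfg.normal_activity_sd, len(spike_cols)
            )
        for tk in cfg.spike_tks:
            activity[tk][spike_cols] = cfg.spike_magnitude

    # gene-level latent phospho-state
    gene_latent: dict[str, np.ndarray] = dict(activity)
    for sub_gene in cfg.substrate_genes():
        parents = truth.gene_parents.get(sub_gene, [])
        if parents:
            # additive integration: a substrate's phospho-state accumulates
            # every parent kinase's contribution, so shared substrates of two
            # co-activated kinases rise above either kinase's private targets
            drive = np.sum([s * activity[tk] for tk, s in parents], axis=0)
            gene_latent[sub_gene] = c * drive + np.sqrt(1 - c**2) * rng.normal(
                0.0, 1.0, n
            )
        else:
            gene_latent[sub_gene] = rng.normal(0.0, 1.0, n)

    # peptide latents: the first peptide of a protein carries the gene latent,
    # further peptides are correlated satellites
    z = np.empty((len(truth.peptides), n))
    base = rng.normal(0.0, _BASE_ABUNDANCE_SD, len(truth.peptides))
    seen: set[str] = set()
    for i, pep in enumerate(truth.peptides):
        g = gene_latent[pep.gene]
        if pep.gene not in seen:
            z[i] = g
            seen.add(pep.gene)
        else:
            z[i] = _PEPTIDE_LATENT_R * g + np.sqrt(
                1 - _PEPTIDE_LATENT_R**2
            ) * rng.normal(0.0, 1.0, n)

    if cfg.zero_inflation >= 1.0:
        counts = np.zeros((len(truth.peptides), n), dtype=np.int64)
        return SpectralCountMatrix(list(truth.peptides), labels, counts, classes)

    lam_unit = np.exp(base[:, None] + _LATENT_SLOPE * z)
    r = cfg.count_dispersion
    c0 = _calibrate_intercept(lam_unit, r, cfg.zero_inflation)
    lam = lam_unit * np.exp(c0)
    counts = rng.negative_binomial(r, r / (r + lam))
    return SpectralCountMatrix(
        list(truth.peptides), labels, counts.astype(np.int64), classes
    )


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[SpectralCountMatrix, GroundTruth, KinaseList]:
    truth, kinases = simulate_truth(cfg)
    return simulate_counts(truth, cfg), truth, kinases


def _canonical_gene_pairs(pairs, kinases: KinaseList) -> set[tuple[str, str]]:
    out = set()
    for a, b in pairs:
        if a in kinases and b in kinases:
            out.add((min(a, b), max(a, b)))
        else:
            out.add((a, b))
    return out


def gene_level_performance(
    inferred: SignalingNetwork, truth: GroundTruth
) -> tuple[float, float]:
    """Gene-level precision/recall of an inferred network vs the planted truth.

    Kinase-kinase pairs are compared without direction (MI is symmetric, so
    the inferred regulator of a TK-TK edge is a convention).
    """
    kin = truth.kinases
    pred = _canonical_gene_pairs(
        {(e.regulator.gene, e.substrate.gene) for e in inferred.edges}, kin
    )
    true = _canonical_gene_pairs(
        {(e.regulator.gene, e.substrate.gene) for e in truth.network.edges}, kin
    )
    if not pred:
        return 0.0, 0.0
    tp = len(pred & true)
    return tp / len(pred), tp / len(true)


def config_with(cfg: SimulationConfig, **kw) -> SimulationConfig:
    """Convenience wrapper around dataclasses.replace for frozen configs."""
    return replace(cfg, **kw)
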