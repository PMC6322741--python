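"""Master-regulator and synergistic-pair inference on phospho signatures.

A sample's *phospho signature* scores every peptide's differential
phosphorylation against the normal reference group.  Each kinase's *signalon*
is its correlation-filtered substrate set (Bonferroni-corrected Spearman p <=
alpha per regulator); because kinases only add phosphate, negative-sign
targets are retained in the type but excluded from enrichment, and the
enrichment itself is single-tail: the signature is ranked by signed score and
a weighted Kolmogorov-Smirnov running sum measures where the signalon
concentrates.  The enrichment score (ES) is standardized into an NES against
a size-matched random-peptide-set null, which also yields the p-value.

Peptide-level results are combined per protein by Stouffer's method, with
the combined p obtained from the same permutation null so it stays uniform
under the null.  Synergy of a kinase pair is the enrichment of the targets
*shared* by both signalons, referenced against equally sized random subsets
of the targets unique to either one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .networks import SignalingNetwork
from .phospho_io import KinaseList, PeptideID, SpectralCountMatrix

__all__ = [
    "PhosphoSignature",
    "Signalon",
    "SignalonTarget",
    "EnrichmentResult",
    "MRResult",
    "compute_signature",
    "build_signalons",
    "enrichment_nes",
    "rank_master_regulators",
    "pair_synergy",
    "phosphosite_rule_classifier",
]


@dataclass
class PhosphoSignature:
    """Per-peptide standardized differential phosphorylation of one sample.

    score = (x_sample - mean(normals)) / sd(normals); peptides whose normal
    counts are constant use the sd floor (median of the nonzero normal sds)
    so the score stays finite.  Higher score = hyper-phosphorylated.
    """

    sample: str
    peptides: list[PeptideID]
    scores: np.ndarray
    _index: dict[PeptideID, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("signature scores must be finite")
        self._index = {p: i for i, p in enumerate(self.peptides)}

    def position_of(self, peptide: PeptideID) -> int | None:
        return self._index.get(peptide)


def compute_signature(
    matrix: SpectralCountMatrix, sample: str, sd_floor: float | None = None
) -> PhosphoSignature:
    """Differential-phosphorylation signature of ``sample`` vs the normals."""
    normals = matrix.samples_of_class("normal")
    if len(normals) < 2:
        raise ValueError("need at least 2 normal-class samples")
    if sample not in matrix.samples:
        raise ValueError(f"unknown sample {sample!r}")
    cols = [matrix.samples.index(s) for s in normals]
    ref = matrix.counts[:, cols].astype(float)
    mean = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    if sd_floor is None:
        positive = sd[sd > 0]
        sd_floor = float(np.median(positive)) if positive.size else 1.0
    denom = np.where(sd > 0, sd, sd_floor)
    x = matrix.column(sample).astype(float)
    return PhosphoSignature(sample, list(matrix.peptides), (x - mean) / denom)


@dataclass(frozen=True)
class SignalonTarget:
    peptide: PeptideID
    sign: int  # +1 / -1, sign of the Spearman correlation with the regulator
    weight: float  # |rho|


@dataclass
class Signalon:
    """A kinase peptide's correlation-filtered substrate set."""

    regulator: PeptideID
    targets: list[SignalonTarget]

    def positive_targets(self) -> list[SignalonTarget]:
        return [t for t in self.targets if t.sign > 0]

    def __len__(self) -> int:
        return len(self.targets)


def build_signalons(
    net: SignalingNetwork,
    matrix: SpectralCountMatrix,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> dict[PeptideID, Signalon]:
    """Filter each regulator's substrates by significant Spearman correlation.

    The Bonferroni correction is applied per regulator over its candidate
    substrate count.  Degenerate (constant-row) substrates are dropped.
    Empty signalons are kept (flagged by their zero length).
    """
    if correction != "bonferroni":
        raise ValueError(f"unknown correction {correction!r}")
    by_reg: dict[PeptideID, list] = {}
    for e in net.edges:
        by_reg.setdefault(e.regulator, []).append(e)
    out: dict[PeptideID, Signalon] = {}
    for reg, edges in by_reg.items():
        x = matrix.row(reg)
        threshold = alpha / len(edges)
        targets = []
        for e in edges:
            y = matrix.row(e.substrate)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            if e.rho is not None and e.rho_p is not None and not math.isnan(e.rho):
                rho, p = e.rho, e.rho_p
            else:
                rho, p = stats.spearmanr(x, y)
                if math.isnan(rho):
                    continue
            if p <= threshold:
                targets.append(
                    SignalonTarget(e.substrate, 1 if rho >= 0 else -1, abs(rho))
                )
        out[reg] = Signalon(reg, targets)
    return out


@dataclass
class EnrichmentResult:
    es: float
    nes: float
    pvalue: float
    n_targets: int
    flagged: bool = False  # True when no usable target set existed
    null_nes: np.ndarray | None = None  # standardized null draws (for Stouffer)


def _rank_quantile_profile(n: int) -> np.ndarray:
    """Normal-quantile magnitude of each position in the ranked signature.

    Raw signature scores are variance-standardized count differences and can
    span orders of magnitude on sparse data; weighting the running sum by
    them directly lets a single outlier peptide dominate the permutation
    null.  Following master-regulator practice the signature is therefore
    rank-transformed to normal quantiles before weighting; ranking order is
    unaffected.
    """
    return stats.norm.ppf(1.0 - (np.arange(n) + 0.5) / n)


def _running_es(order_scores: np.ndarray, hit_pos: np.ndarray, hit_w: np.ndarray) -> float:
    """Weighted KS running-sum ES; positions index the ranked signature."""
    n = order_scores.size
    k = hit_pos.size
    if k == 0 or k >= n:
        return 0.0
    steps = np.full(n, -1.0 / (n - k))
    w = hit_w * np.abs(order_scores[hit_pos])
    total = w.sum()
    steps[hit_pos] = w / total if total > 0 else 1.0 / k
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def _null_es_matrix(
    order_scores: np.ndarray, k: int, weights: np.ndarray, n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """ES of ``n_perm`` random size-k peptide sets carrying the same weights."""
    n = order_scores.size
    positions = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
    steps = np.full((n_perm, n), -1.0 / (n - k))
    rows = np.repeat(np.arange(n_perm), k)
    w = weights[None, :] * np.abs(order_scores[positions])
    totals = w.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    steps[rows, positions.ravel()] = (w / totals).ravel()
    running = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), idx]


def enrichment_nes(
    signature: PhosphoSignature,
    signalon: Signalon,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Single-tail enrichment of a signalon's positive targets in a signature.

    The NES is (ES - mean_null) / sd_null against random size-matched peptide
    sets; the p-value is two-sided on |ES| against the same null.  An empty
    usable target set yields a flagged null result rather than an error.
    """
    usable = [
        t for t in signalon.positive_targets()
        if signature.position_of(t.peptide) is not None
    ]
    if not usable or len(usable) >= len(signature.peptides):
        return EnrichmentResult(0.0, 0.0, 1.0, len(usable), flagged=True)
    order = np.argsort(-signature.scores, kind="stable")
    rank_of = np.empty(order.size, dtype=np.int64)
    rank_of[order] = np.arange(order.size)
    profile = _rank_quantile_profile(order.size)
    hit_pos = np.array(
        [rank_of[signature.position_of(t.peptide)] for t in usable]
    )
    weights = np.array([t.weight for t in usable])
    es = _running_es(profile, hit_pos, weights)
    rng = np.random.default_rng(seed)
    null = _null_es_matrix(profile, len(usable), weights, n_perm, rng)
    mu, sd = null.mean(), null.std(ddof=1)
    if sd == 0:
        return EnrichmentResult(es, 0.0, 1.0, len(usable), flagged=True)
    nes = (es - mu) / sd
    p = (1 + int(np.sum(np.abs(null - mu) >= abs(es - mu) - 1e-15))) / (1 + n_perm)
    return EnrichmentResult(es, float(nes), float(p), len(usable),
                            null_nes=(null - mu) / sd)


@dataclass
class MRResult:
    """Per-sample master-regulator rankings.

    ``peptide_table``: sample, regulator (dollar ID), nes, p.
    ``protein_table``: sample, gene, nes (Stouffer), p (permutation), q (BH).
    ``pair_table`` (when pairs were scored): sample, regulator_a, regulator_b,
    nes, p — peptide-level synergy of the shared targets.
    """

    peptide_table: pd.DataFrame
    protein_table: pd.DataFrame
    pair_table: pd.DataFrame | None = None

    def top_gene(self, sample: str) -> str | None:
        sub = self.protein_table[self.protein_table["sample"] == sample]
        if sub.empty:
            return None
        return sub.loc[sub["nes"].abs().idxmax(), "gene"]


def rank_master_regulators(
    matrix: SpectralCountMatrix,
    net: SignalingNetwork,
    samples: list[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    pairs: list[tuple[PeptideID, PeptideID]] | None = None,
    signalon_matrix: SpectralCountMatrix | None = None,
) -> MRResult:
    """Rank candidate master-regulator kinases in each sample.

    Enrichment runs at the phosphopeptide level; peptide NES values of the
    same gene are combined by Stouffer's method (equal weights), with the
    combined p-value taken from the Stouffer combination of the permutation
    null so it remains calibrated.  q is Benjamini-Hochberg within sample.
    ``signalon_matrix`` lets the correlation filter run on a different
    (e.g. larger, held-out) compendium than the signatures.
    """
    if samples is None:
        samples = [
            s for s in matrix.samples if matrix.sample_class(s) != "normal"
        ]
    signalons = build_signalons(
        net, matrix if signalon_matrix is None else signalon_matrix, alpha=alpha
    )
    regs = sorted(signalons)
    pep_rows, prot_rows, pair_rows = [], [], []
    for si, sample in enumerate(samples):
        sig = compute_signature(matrix, sample)
        results: dict[PeptideID, EnrichmentResult] = {}
        for ri, reg in enumerate(regs):
            res = enrichment_nes(
                sig, signalons[reg], n_perm=n_perm,
                seed=seed + 100003 * si + 101 * ri,
            )
            results[reg] = res
            pep_rows.append(
                {
                    "sample": sample,
                    "regulator": reg.format("dollar"),
                    "nes": res.nes,
                    "p": res.pvalue,
                    "flagged": res.flagged,
                }
            )
        by_gene: dict[str, list[EnrichmentResult]] = {}
        for reg, res in results.items():
            if not res.flagged:
                by_gene.setdefault(reg.gene, []).append(res)
        genes, zvals, pvals = [], [], []
        for gene, rs in sorted(by_gene.items()):
            z = sum(r.nes for r in rs) / math.sqrt(len(rs))
            null_z = sum(r.null_nes for r in rs) / math.sqrt(len(rs))
            p = (1 + int(np.sum(np.abs(null_z) >= abs(z) - 1e-15))) / (
                1 + len(null_z)
            )
            genes.append(gene)
            zvals.append(z)
            pvals.append(p)
        if genes:
            qvals = stats.false_discovery_control(pvals)
        else:
            qvals = []
        for gene, z, p, q in zip(genes, zvals, pvals, qvals):
            prot_rows.append(
                {"sample": sample, "gene": gene, "nes": z, "p": p, "q": float(q)}
            )
        if pairs:
            for pi, (a, b) in enumerate(pairs):
                if a not in signalons or b not in signalons:
                    continue
                syn = pair_synergy(
                    sig, signalons[a], signalons[b], n_perm=n_perm,
                    seed=seed + 100003 * si + 911 * pi + 13,
                )
                pair_rows.append(
                    {
                        "sample": sample,
                        "regulator_a": a.format("dollar"),
                        "regulator_b": b.format("dollar"),
                        "nes": syn.nes,
                        "p": syn.pvalue,
                        "flagged": syn.flagged,
                    }
                )
    return MRResult(
        peptide_table=pd.DataFrame(pep_rows),
        protein_table=pd.DataFrame(prot_rows),
        pair_table=pd.DataFrame(pair_rows) if pairs else None,
    )


def pair_synergy(
    signature: PhosphoSignature,
    signalon_a: Signalon,
    signalon_b: Signalon,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Synergy of two kinases: enrichment of their shared targets.

    The observed ES is computed on the positive targets common to both
    signalons; the null redraws equally sized sets from the targets unique
    to either signalon, so a significant result means the *shared* substrates
    are more enriched than the kinases' private ones.  p is one-sided
    (null ES >= observed).
    """
    pos_a = {t.peptide: t for t in signalon_a.positive_targets()}
    pos_b = {t.peptide: t for t in signalon_b.positive_targets()}
    shared = [
        pos_a[p] for p in pos_a.keys() & pos_b.keys()
        if signature.position_of(p) is not None
    ]
    unique = [
        t for p, t in {**pos_a, **pos_b}.items()
        if (p in pos_a) != (p in pos_b) and signature.position_of(p) is not None
    ]
    if not shared or len(unique) < len(shared):
        return EnrichmentResult(0.0, 0.0, 1.0, len(shared), flagged=True)

    order = np.argsort(-signature.scores, kind="stable")
    rank_of = np.empty(order.size, dtype=np.int64)
    rank_of[order] = np.arange(order.size)
    profile = _rank_quantile_profile(order.size)
    hit_pos = np.array([rank_of[signature.position_of(t.peptide)] for t in shared])
    weights = np.array([t.weight for t in shared])
    es = _running_es(profile, hit_pos, weights)

    rng = np.random.default_rng(seed)
    unique_pos = np.array([rank_of[signature.position_of(t.peptide)] for t in unique])
    k = len(shared)
    null = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(unique_pos.size, size=k, replace=False)
        null[i] = _running_es(profile, unique_pos[pick], weights)
    mu, sd = null.mean(), null.std(ddof=1)
    p = (1 + int(np.sum(null >= es - 1e-15))) / (1 + n_perm)
    nes = (es - mu) / sd if sd > 0 else 0.0
    return EnrichmentResult(es, float(nes), float(p), k)


def phosphosite_rule_classifier(
    mr: MRResult,
    site_a: PeptideID = PeptideID("EGFR", (1197,)),
    site_b: PeptideID = PeptideID("MET", (1003,)),
    alpha: float = 0.05,
) -> dict[str, str]:
    """Classify samples by which phosphosites drive predicted synergy.

    Per sample: ``combo_sensitive`` when the (site_a, site_b) pair itself
    shows significant positive synergy; ``single_agent`` when site_a drives
    significant synergy only with partners other than site_b; ``insensitive``
    otherwise.  If neither named site appears among the scored pairs at all,
    every sample is labelled ``flagged``.
    """
    if mr.pair_table is None or mr.pair_table.empty:
        raise ValueError("MRResult has no pair-synergy table")
    ida, idb = site_a.format("dollar"), site_b.format("dollar")
    tab = mr.pair_table
    mentioned = set(tab["regulator_a"]) | set(tab["regulator_b"])
    samples = sorted(set(tab["sample"]))
    if ida not in mentioned:
        return {s: "flagged" for s in samples}
    labels = {}
    for sample in samples:
        sub = tab[(tab["sample"] == sample) & (tab["p"] <= alpha) & (tab["nes"] > 0)]
        partners = set()
        for _, row in sub.iterrows():
            if row["regulator_a"] == ida:
                partners.add(row["regulator_b"])
            elif row["regulator_b"] == ida:
                partners.add(row["regulator_a"])
        if idb in partners:
            labels[sample] = "combo_sensitive"
        elif partners:
            labels[sample] = "single_agent"
        else:
            labels[sample] = "insensitive"
    return labels
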