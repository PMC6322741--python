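"""Network containers shared by the I/O layer and the inference engine."""

from __future__ import annotations

from dataclasses import dataclass, replace

from .phospho_io import PeptideID


@dataclass(frozen=True)
class Edge:
    """A directed kinase-peptide -> substrate-peptide dependency.

    ``mi`` is the plug-in mutual information of the discretized phospho-state
    profiles; ``support`` the number of bootstrap networks containing the
    edge; ``rho``/``rho_p`` a Spearman correlation annotation (NaN rho marks
    a degenerate, constant-row edge).
    """

    regulator: PeptideID
    substrate: PeptideID
    mi: float
    support: int | None = None
    rho: float | None = None
    rho_p: float | None = None

    @property
    def key(self) -> tuple[PeptideID, PeptideID]:
        return (self.regulator, self.substrate)

    def with_(self, **kw) -> "Edge":
        return replace(self, **kw)


@dataclass
class SignalingNetwork:
    """Peptide-level signaling network: unique (regulator, substrate) edges."""

    edges: list[Edge]

    def __post_init__(self) -> None:
        keys = [e.key for e in self.edges]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (regulator, substrate) edge")

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    @property
    def regulators(self) -> set[PeptideID]:
        return {e.regulator for e in self.edges}

    @property
    def peptides(self) -> set[PeptideID]:
        return {p for e in self.edges for p in e.key}

    def mi_of(self, a: PeptideID, b: PeptideID) -> float | None:
        for e in self.edges:
            if e.key in ((a, b), (b, a)):
                return e.mi
        return None


@dataclass(frozen=True)
class ProteinEdge:
    kinase: str
    substrate: str
    mi_max: float


@dataclass
class ProteinNetwork:
    """Gene-level projection: one edge per (kinase gene, substrate gene)."""

    edges: list[ProteinEdge]

    def __post_init__(self) -> None:
        keys = [(e.kinase, e.substrate) for e in self.edges]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate gene-level edge")

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def gene_pairs(self) -> set[tuple[str, str]]:
        return {(e.kinase, e.substrate) for e in self.edges}
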