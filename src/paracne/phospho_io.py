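"""Data model and TSV I/O for phosphotyrosine spectral-count data.

The molecular input to the whole pipeline is a peptide x sample matrix of
spectral counts: non-negative integers counting MS/MS spectra matched to a
phosphopeptide in a sample.  Rows are identified by a gene symbol plus the
tyrosine positions carried by the peptide, serialized in one of two dialects::

    EGFR$1197        dollar dialect (regulator column of peptide-level tables)
    EGFR_1197        underscore dialect (substrate column)

Multi-site peptides append further positions: ``ABC$10$25`` / ``ABC_10_25``.

This module also reads tyrosine-kinase lists, kinase->substrate gold
standards, and writes the three-column network tables (regulator, substrate,
mutual information) at either peptide or protein level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhosphoIOError",
    "PeptideParseError",
    "PeptideID",
    "SpectralCountMatrix",
    "KinaseList",
    "GoldStandard",
    "normalize_gene",
    "detect_dialect",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_classes",
    "write_network",
    "read_network",
]

SAMPLE_CLASSES = ("tumor", "cell_line", "normal")

#: Legacy/literature symbols mapped onto the HGNC symbol used internally.
GENE_ALIASES = {
    "C-MET": "MET",
    "CMET": "MET",
    "HER2": "ERBB2",
    "HER3": "ERBB3",
    "HER4": "ERBB4",
    "C-SRC": "SRC",
    "C-ABL": "ABL1",
}

_DIALECT_SEP = {"dollar": "$", "underscore": "_"}


class PhosphoIOError(ValueError):
    """Malformed input file or identifier."""


class PeptideParseError(PhosphoIOError):
    pass


def normalize_gene(symbol: str) -> str:
    """Trim, upper-case and alias-resolve a gene symbol (``c-MET`` -> ``MET``)."""
    s = symbol.strip().upper()
    return GENE_ALIASES.get(s, s)


def detect_dialect(text: str) -> str:
    """Guess the serialization dialect of a peptide ID from one data token."""
    return "dollar" if "$" in text else "underscore"


@dataclass(frozen=True, order=True)
class PeptideID:
    """A phosphopeptide: gene symbol plus the tyrosine positions it carries.

    ``sites`` is kept strictly increasing so that two serializations of the
    same peptide compare equal.
    """

    gene: str
    sites: tuple[int, ...]

    def __post_init__(self) -> None:
        gene = normalize_gene(self.gene)
        if not gene:
            raise PeptideParseError("empty gene symbol")
        sites = tuple(int(s) for s in self.sites)
        if not sites:
            raise PeptideParseError(f"peptide {gene!r} has no phosphosites")
        if any(s <= 0 for s in sites):
            raise PeptideParseError(f"peptide {gene!r}: non-positive site in {sites}")
        if any(b <= a for a, b in zip(sites, sites[1:])):
            raise PeptideParseError(
                f"peptide {gene!r}: sites {sites} not strictly increasing"
            )
        object.__setattr__(self, "gene", gene)
        object.__setattr__(self, "sites", sites)

    @classmethod
    def parse(cls, text: str, dialect: str) -> "PeptideID":
        """Parse ``GENE$s1[$s2...]`` (dollar) or ``GENE_s1[_s2...]`` (underscore)."""
        sep = _sep(dialect)
        tokens = text.strip().split(sep)
        if len(tokens) < 2:
            raise PeptideParseError(
                f"{text!r}: no {dialect!r}-separated phosphosite found"
            )
        gene, site_tokens = tokens[0], tokens[1:]
        if not gene:
            raise PeptideParseError(f"{text!r}: empty gene symbol")
        sites = []
        for tok in site_tokens:
            if not tok.isdigit():
                raise PeptideParseError(f"{text!r}: non-numeric site token {tok!r}")
            sites.append(int(tok))
        return cls(gene, tuple(sorted(set(sites))))

    def format(self, dialect: str) -> str:
        sep = _sep(dialect)
        return sep.join([self.gene, *map(str, self.sites)])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format("dollar")


def _sep(dialect: str) -> str:
    try:
        return _DIALECT_SEP[dialect]
    except KeyError:
        raise PhosphoIOError(
            f"unknown dialect {dialect!r}; expected 'dollar' or 'underscore'"
        ) from None


def parse_peptide_id(text: str, dialect: str) -> PeptideID:
    """Module-level alias of :meth:`PeptideID.parse`."""
    return PeptideID.parse(text, dialect)


@dataclass
class SpectralCountMatrix:
    """Peptides x samples matrix of non-negative integer spectral counts.

    ``sample_classes`` optionally tags each sample as tumor / cell_line /
    normal; the normal group is the reference for differential-phosphorylation
    signatures.
    """

    peptides: list[PeptideID]
    samples: list[str]
    counts: np.ndarray
    sample_classes: dict[str, str] | None = None
    _row_index: dict[PeptideID, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.peptides), len(self.samples)):
            raise PhosphoIOError(
                f"count shape {counts.shape} does not match "
                f"{len(self.peptides)} peptides x {len(self.samples)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise PhosphoIOError("spectral counts must be integers")
        counts = counts.astype(np.int64, copy=False)
        if counts.size and counts.min() < 0:
            raise PhosphoIOError("spectral counts must be non-negative")
        self.counts = counts
        if len(set(self.peptides)) != len(self.peptides):
            dup = _first_duplicate(self.peptides)
            raise PhosphoIOError(f"duplicate peptide row {dup.format('dollar')!r}")
        if len(set(self.samples)) != len(self.samples):
            dup = _first_duplicate(self.samples)
            raise PhosphoIOError(f"duplicate sample label {dup!r}")
        if self.sample_classes is not None:
            for label, cls in self.sample_classes.items():
                if cls not in SAMPLE_CLASSES:
                    raise PhosphoIOError(
                        f"sample {label!r}: unknown class {cls!r} "
                        f"(expected one of {SAMPLE_CLASSES})"
                    )
        self._row_index = {p: i for i, p in enumerate(self.peptides)}

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def row(self, peptide: PeptideID) -> np.ndarray:
        try:
            return self.counts[self._row_index[peptide]]
        except KeyError:
            raise PhosphoIOError(
                f"peptide {peptide.format('dollar')!r} not in matrix"
            ) from None

    def row_number(self, peptide: PeptideID) -> int:
        return self._row_index[peptide]

    def sample_class(self, label: str) -> str | None:
        if self.sample_classes is None:
            return None
        return self.sample_classes.get(label)

    def samples_of_class(self, cls: str) -> list[str]:
        if self.sample_classes is None:
            return []
        return [s for s in self.samples if self.sample_classes.get(s) == cls]

    def column(self, label: str) -> np.ndarray:
        try:
            j = self.samples.index(label)
        except ValueError:
            raise PhosphoIOError(f"unknown sample {label!r}") from None
        return self.counts[:, j]

    def resample_columns(self, indices: np.ndarray) -> "SpectralCountMatrix":
        """Column resample (possibly with replacement), relabelling duplicates."""
        labels = []
        seen: dict[str, int] = {}
        for j in indices:
            base = self.samples[j]
            k = seen.get(base, 0)
            seen[base] = k + 1
            labels.append(base if k == 0 else f"{base}#{k}")
        classes = None
        if self.sample_classes is not None:
            classes = {
                lab: self.sample_classes[self.samples[j]]
                for lab, j in zip(labels, indices)
                if self.samples[j] in self.sample_classes
            }
        return SpectralCountMatrix(
            list(self.peptides), labels, self.counts[:, list(indices)], classes
        )

    def to_frame(self, dialect: str = "dollar") -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=[p.format(dialect) for p in self.peptides],
            columns=self.samples,
        )


def _first_duplicate(items):
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


@dataclass(frozen=True)
class KinaseList:
    """Set of gene symbols treated as candidate tyrosine-kinase regulators."""

    symbols: frozenset[str]

    def __contains__(self, gene: str) -> bool:
        return normalize_gene(gene) in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(sorted(self.symbols))

    @classmethod
    def from_symbols(cls, symbols) -> "KinaseList":
        return cls(frozenset(normalize_gene(s) for s in symbols if s.strip()))

    @classmethod
    def from_file(cls, path) -> "KinaseList":
        with open(path) as fh:
            return cls.from_symbols(line.strip() for line in fh if line.strip())


@dataclass(frozen=True)
class GoldStandard:
    """Known (kinase gene, substrate gene) pairs; kinase == substrate allowed
    (autophosphorylation)."""

    edges: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(g for e in self.edges for g in e)

    @classmethod
    def from_pairs(cls, pairs) -> "GoldStandard":
        return cls(
            frozenset((normalize_gene(a), normalize_gene(b)) for a, b in pairs)
        )

    @classmethod
    def from_file(cls, path) -> "GoldStandard":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        if df.shape[1] < 2:
            raise PhosphoIOError(f"{path}: gold standard needs two columns")
        return cls.from_pairs(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_sample_classes(path) -> dict[str, str]:
    """Two-column sidecar TSV (sample label, class), no header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise PhosphoIOError(f"{path}: class sidecar needs two columns")
    classes = {}
    for label, cls in zip(df.iloc[:, 0], df.iloc[:, 1]):
        cls = str(cls).strip()
        if cls not in SAMPLE_CLASSES:
            raise PhosphoIOError(
                f"{path}: sample {label!r} has unknown class {cls!r}"
            )
        classes[str(label).strip()] = cls
    return classes


def read_count_matrix(path, dialect: str | None = None, classes_path=None) -> SpectralCountMatrix:
    """Read a TSV count matrix (header = sample labels, first column = peptide IDs).

    Missing cells are imputed as 0: spectral counting reports absence as
    non-detection, so an empty cell is a zero count, not missing-at-random.
    The ID dialect is auto-detected from the first row when not given; files
    mixing dialects are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise PhosphoIOError(f"{path}: duplicate peptide row {dup!r}")
    ids = [str(i) for i in df.index]
    if not ids:
        raise PhosphoIOError(f"{path}: empty matrix")
    if dialect is None:
        dialect = detect_dialect(ids[0])
    for i in ids:
        if detect_dialect(i) != dialect:
            raise PhosphoIOError(
                f"{path}: mixed ID dialects (row {i!r} is not {dialect!r})"
            )
    peptides = [PeptideID.parse(i, dialect) for i in ids]
    values = df.fillna(0).to_numpy()
    try:
        values = values.astype(np.float64)
    except ValueError as exc:
        raise PhosphoIOError(f"{path}: non-numeric count ({exc})") from None
    if np.any(values < 0):
        raise PhosphoIOError(f"{path}: negative count")
    if np.any(values != np.floor(values)):
        raise PhosphoIOError(f"{path}: non-integer count")
    classes = read_sample_classes(classes_path) if classes_path else None
    return SpectralCountMatrix(
        peptides, [str(c) for c in df.columns], values.astype(np.int64), classes
    )


def write_count_matrix(m: SpectralCountMatrix, path, dialect: str = "dollar") -> None:
    m.to_frame(dialect).to_csv(path, sep="\t")


def _aggregate_max(edges):
    """(kinase gene, substrate gene) -> max MI over contributing peptide edges."""
    agg: dict[tuple[str, str], float] = {}
    for e in edges:
        key = (e.regulator.gene, e.substrate.gene)
        if key not in agg or e.mi > agg[key]:
            agg[key] = e.mi
    return agg


def write_network(net, path, level: str = "peptide") -> None:
    """Write a network as a three-column TSV (regulator, substrate, MI).

    Peptide level serializes the regulator in the dollar dialect and the
    substrate in the underscore dialect; protein level writes bare gene
    symbols with the maximum MI over contributing peptide edges.
    """
    edges = list(net.edges)
    if not edges:
        raise PhosphoIOError("refusing to write an empty network")
    lines = ["regulator\tsubstrate\tmi"]
    if level == "peptide":
        for e in sorted(edges, key=lambda e: (e.regulator, e.substrate)):
            lines.append(
                f"{e.regulator.format('dollar')}\t"
                f"{e.substrate.format('underscore')}\t{e.mi!r}"
            )
    elif level == "protein":
        for (rg, sg), mi in sorted(_aggregate_max(edges).items()):
            lines.append(f"{rg}\t{sg}\t{mi!r}")
    else:
        raise PhosphoIOError(f"unknown level {level!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_network(path):
    """Read a peptide-level three-column network TSV back into a network."""
    from .networks import Edge, SignalingNetwork

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns[:3]) != ["regulator", "substrate", "mi"]:
        raise PhosphoIOError(f"{path}: expected columns regulator/substrate/mi")
    edges = [
        Edge(
            PeptideID.parse(str(r), "dollar"),
            PeptideID.parse(str(s), "underscore"),
            float(mi),
        )
        for r, s, mi in zip(df["regulator"], df["substrate"], df["mi"])
    ]
    return SignalingNetwork(edges)
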