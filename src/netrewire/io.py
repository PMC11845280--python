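"""Readers and writers for the tab-separated artifacts of the workflow.

All formats are plain UTF-8 TSV with transparent gzip support (a ``.gz``
suffix triggers compression on write and decompression on read).  Lines
starting with ``#`` are comments.  Output is sorted deterministically so
files are diffable across runs.

File layouts
------------
``*_ppin.txt(.gz)``
    ``proteinA<TAB>proteinB[<TAB>weight]`` — one interaction per row.
``*_ddin.txt(.gz)``
    same, with domain-instance identifiers ``protein|family|occurrence``.
``*_major_transcripts.txt(.gz)``
    ``protein<TAB>gene<TAB>chosen-feature<TAB>abundance``.
expression (gene level)
    ``gene<TAB>abundance``.
expression (transcript level)
    ``transcript<TAB>gene<TAB>abundance[<TAB>length]``.
domain annotation
    ``protein<TAB>gene<TAB>isoform<TAB>comma-separated-families[<TAB>flag]``
    with one row per isoform; ``flag`` 1 marks the canonical isoform.
DDI library
    ``familyA<TAB>familyB`` — one documented interacting pair per row.
"""

from __future__ import annotations

import gzip
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from .model import (
    DOMAIN_LEVEL,
    DUMMY_FAMILY,
    PROTEIN_LEVEL,
    DomainId,
    Network,
    canonical_edge,
)

GENE_LEVEL = "gene"
TRANSCRIPT_LEVEL = "transcript"


class FormatError(ValueError):
    """A malformed input file; the message names the path and line number."""


# ---------------------------------------------------------------------------
# in-memory containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionTable:
    """Per-sample abundances at gene or transcript level (TPM/FPKM scale)."""

    level: str
    abundance: dict[str, float] = field(default_factory=dict)
    #: transcript -> parent gene (transcript level only)
    tx2gene: dict[str, str] = field(default_factory=dict)
    #: transcript -> length in nucleotides (optional)
    lengths: dict[str, int] = field(default_factory=dict)
    _gene_totals: dict[str, float] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.level not in (GENE_LEVEL, TRANSCRIPT_LEVEL):
            raise ValueError(f"unknown expression level {self.level!r}")

    def get(self, feature: str) -> float:
        """Abundance of a feature; missing records count as 0."""
        return self.abundance.get(feature, 0.0)

    def gene_total(self, gene: str) -> float:
        """Gene abundance: the value itself at gene level, the sum over
        the gene's transcripts at transcript level."""
        if self.level == GENE_LEVEL:
            return self.abundance.get(gene, 0.0)
        if self._gene_totals is None:
            totals: dict[str, float] = {}
            for tx, value in self.abundance.items():
                g = self.tx2gene.get(tx)
                if g is not None:
                    totals[g] = totals.get(g, 0.0) + value
            self._gene_totals = totals
        return self._gene_totals.get(gene, 0.0)


@dataclass
class DomainAnnotation:
    """Protein -> isoform -> ordered domain family list, plus gene mapping.

    ``canonical`` designates one isoform per protein (the architecture
    used in gene-level mode); it defaults to the first isoform read.
    """

    isoforms: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    protein2gene: dict[str, str] = field(default_factory=dict)
    canonical: dict[str, str] = field(default_factory=dict)

    def add_isoform(
        self,
        protein: str,
        gene: str,
        isoform: str,
        families: list[str],
        canonical: bool = False,
    ) -> None:
        if DUMMY_FAMILY in families:
            raise ValueError(
                f"family name {DUMMY_FAMILY!r} is reserved for dummy domains"
            )
        known_gene = self.protein2gene.get(protein)
        if known_gene is not None and known_gene != gene:
            raise ValueError(
                f"protein {protein} mapped to two genes: {known_gene}, {gene}"
            )
        self.protein2gene[protein] = gene
        iso = self.isoforms.setdefault(protein, {})
        iso[isoform] = list(families)
        if canonical or protein not in self.canonical:
            self.canonical[protein] = isoform

    @property
    def proteins(self) -> set[str]:
        return set(self.isoforms)

    def families(self, protein: str) -> set[str]:
        """All families annotated on any isoform of a protein."""
        out: set[str] = set()
        for arch in self.isoforms[protein].values():
            out.update(arch)
        return out

    def occurrence_count(self, protein: str, family: str) -> int:
        """Maximum copy number of a family over the protein's isoforms."""
        return max(arch.count(family) for arch in self.isoforms[protein].values())

    def canonical_architecture(self, protein: str) -> list[str]:
        return self.isoforms[protein][self.canonical[protein]]


@dataclass
class DDILibrary:
    """Documented interacting domain-family pairs, canonically ordered."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str) -> None:
        if not a or not b:
            raise ValueError("family names must be non-empty")
        self.pairs.add(self._key(a, b))

    def interacts(self, a: str, b: str) -> bool:
        return self._key(a, b) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# low-level helpers
# ---------------------------------------------------------------------------


def _open_read(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return _stdio.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _open_write(path: str | Path) -> TextIO:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".gz":
        # mtime=0 keeps gzip output byte-identical across runs
        return _stdio.TextIOWrapper(
            gzip.GzipFile(path, "wb", mtime=0), encoding="utf-8"
        )
    return open(path, "w", encoding="utf-8")


def _rows(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) skipping blanks and comments."""
    with _open_read(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _fmt(x: float) -> str:
    # repr is the shortest string that round-trips the float exactly
    return repr(float(x))


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def _read_network(path: str | Path, level: str) -> Network:
    net = Network(level=level)
    first = True
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected >=2 tab-separated columns")
        a, b = fields[0], fields[1]
        weight: float | None = None
        if len(fields) >= 3 and fields[2] != "":
            if not _is_number(fields[2]):
                if first:
                    first = False
                    continue  # header row
                raise FormatError(f"{path}:{lineno}: non-numeric weight {fields[2]!r}")
            weight = float(fields[2])
        first = False
        try:
            net.add_edge(a, b, weight)
        except ValueError as err:
            raise FormatError(f"{path}:{lineno}: {err}") from err
    return net


def read_ppin(path: str | Path) -> Network:
    """Read a protein-level edge list (``*_ppin.txt(.gz)`` layout)."""
    return _read_network(path, PROTEIN_LEVEL)


def read_ddin(path: str | Path) -> Network:
    """Read a domain-level edge list (``*_ddin.txt(.gz)`` layout)."""
    net = _read_network(path, DOMAIN_LEVEL)
    for node in net.nodes:
        DomainId.parse(node)  # validate identifiers
    return net


def _write_network(net: Network, path: str | Path) -> None:
    with _open_write(path) as fh:
        for edge in sorted(net.edges):
            w = net.weight(edge)
            if w is None:
                fh.write(f"{edge.u}\t{edge.v}\n")
            else:
                fh.write(f"{edge.u}\t{edge.v}\t{_fmt(w)}\n")


def write_ppin(net: Network, path: str | Path) -> None:
    if net.level != PROTEIN_LEVEL:
        raise ValueError("write_ppin expects a protein-level network")
    _write_network(net, path)


def write_ddin(net: Network, path: str | Path) -> None:
    if net.level != DOMAIN_LEVEL:
        raise ValueError("write_ddin expects a domain-level network")
    _write_network(net, path)


# ---------------------------------------------------------------------------
# major transcripts
# ---------------------------------------------------------------------------


def write_major_transcripts(
    major: dict[str, tuple[str, float]],
    protein2gene: dict[str, str],
    path: str | Path,
) -> None:
    """Write the per-protein chosen feature table.

    ``major`` maps protein -> (chosen gene or transcript, abundance).
    """
    with _open_write(path) as fh:
        for protein in sorted(major):
            feature, abundance = major[protein]
            gene = protein2gene.get(protein, ".")
            fh.write(f"{protein}\t{gene}\t{feature}\t{_fmt(abundance)}\n")


def read_major_transcripts(path: str | Path) -> dict[str, tuple[str, str, float]]:
    """Read a major-transcript table: protein -> (gene, feature, abundance)."""
    out: dict[str, tuple[str, str, float]] = {}
    for lineno, fields in _rows(path):
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: expected 4 columns")
        protein, gene, feature, value = fields[:4]
        if not _is_number(value):
            if not out and lineno <= 1:
                continue  # header
            raise FormatError(f"{path}:{lineno}: non-numeric abundance {value!r}")
        out[protein] = (gene, feature, float(value))
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, level: str) -> ExpressionTable:
    """Read a plain TSV expression table at gene or transcript level.

    Repeated feature ids sum (multiple quantification records).  A first
    row whose value column is non-numeric is treated as a header.
    """
    table = ExpressionTable(level=level)
    value_col = 1 if level == GENE_LEVEL else 2
    first = True
    for lineno, fields in _rows(path):
        if len(fields) < value_col + 1:
            if level == TRANSCRIPT_LEVEL and len(fields) == 2:
                raise FormatError(
                    f"{path}:{lineno}: transcript-level table needs a gene column"
                )
            raise FormatError(
                f"{path}:{lineno}: expected >={value_col + 1} tab-separated columns"
            )
        raw = fields[value_col]
        if not _is_number(raw):
            if first:
                first = False
                continue  # header row
            raise FormatError(f"{path}:{lineno}: non-numeric abundance {raw!r}")
        first = False
        value = float(raw)
        if value < 0:
            raise FormatError(f"{path}:{lineno}: negative abundance {value}")
        feature = fields[0]
        table.abundance[feature] = table.abundance.get(feature, 0.0) + value
        if level == TRANSCRIPT_LEVEL:
            gene = fields[1]
            known = table.tx2gene.get(feature)
            if known is not None and known != gene:
                raise FormatError(
                    f"{path}:{lineno}: transcript {feature} mapped to two genes"
                )
            table.tx2gene[feature] = gene
            if len(fields) >= 4 and fields[3] != "":
                length = int(float(fields[3]))
                if length <= 0:
                    raise FormatError(f"{path}:{lineno}: non-positive length")
                table.lengths[feature] = length
    return table


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    with _open_write(path) as fh:
        for feature in sorted(table.abundance):
            value = table.abundance[feature]
            if table.level == GENE_LEVEL:
                fh.write(f"{feature}\t{_fmt(value)}\n")
            else:
                gene = table.tx2gene[feature]
                if feature in table.lengths:
                    fh.write(
                        f"{feature}\t{gene}\t{_fmt(value)}\t{table.lengths[feature]}\n"
                    )
                else:
                    fh.write(f"{feature}\t{gene}\t{_fmt(value)}\n")


# ---------------------------------------------------------------------------
# domain annotation and DDI library
# ---------------------------------------------------------------------------


def read_domain_annotation(path: str | Path) -> DomainAnnotation:
    ann = DomainAnnotation()
    for lineno, fields in _rows(path):
        if len(fields) < 4:
            raise FormatError(
                f"{path}:{lineno}: expected protein, gene, isoform, domains"
            )
        protein, gene, isoform, domains = fields[:4]
        flag = len(fields) >= 5 and fields[4].strip() == "1"
        families = [d for d in domains.split(",") if d] if domains else []
        try:
            ann.add_isoform(protein, gene, isoform, families, canonical=flag)
        except ValueError as err:
            raise FormatError(f"{path}:{lineno}: {err}") from err
    return ann


def write_domain_annotation(ann: DomainAnnotation, path: str | Path) -> None:
    with _open_write(path) as fh:
        for protein in sorted(ann.isoforms):
            gene = ann.protein2gene[protein]
            for isoform in sorted(ann.isoforms[protein]):
                families = ",".join(ann.isoforms[protein][isoform])
                flag = "1" if ann.canonical[protein] == isoform else "0"
                fh.write(f"{protein}\t{gene}\t{isoform}\t{families}\t{flag}\n")


def read_ddi_library(path: str | Path) -> DDILibrary:
    lib = DDILibrary()
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected two family columns")
        try:
            lib.add(fields[0], fields[1])
        except ValueError as err:
            raise FormatError(f"{path}:{lineno}: {err}") from err
    return lib


def write_ddi_library(lib: DDILibrary, path: str | Path) -> None:
    with _open_write(path) as fh:
        for a, b in sorted(lib.pairs):
            fh.write(f"{a}\t{b}\n")
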