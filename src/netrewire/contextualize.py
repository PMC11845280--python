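"""Condition-specific network construction (contextualization).

A reference protein–protein interaction network (PPIN) is first resolved
to a reference domain–domain interaction network (DDIN): every
interaction (u, v) is mapped to all pairs of domain instances on u and v
whose families are documented to interact in the DDI library.  A protein
pair with no documented pair is backed by an artificial edge between
*dummy* domains, so every reference interaction stays representable.

Per sample, each protein is assigned its *major* feature — the most
abundant gene or annotated transcript above the expression threshold.
Domain edges survive only if both owner proteins have a major feature
whose domain architecture contains the edge's families; a protein
interaction survives if at least one of its backing domain edges does.
This is what gives the procedure transcript resolution: an isoform
switch that drops the sole backing domain removes the interaction even
though both proteins stay expressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import (
    GENE_LEVEL,
    TRANSCRIPT_LEVEL,
    DDILibrary,
    DomainAnnotation,
    ExpressionTable,
)
from .model import (
    DOMAIN_LEVEL,
    DomainId,
    Edge,
    Network,
    canonical_edge,
    dummy_domain,
)

GENE_ONLY = "gene-only"
TRANSCRIPT_PREFERRED = "transcript-preferred"


@dataclass(frozen=True)
class ContextOptions:
    """Tunables of the contextualization step.

    threshold
        Minimum abundance (exclusive) for a gene or transcript to count
        as expressed; default 1.0 on the TPM/FPKM scale.
    mode
        ``gene-only``: the protein's gene abundance decides expression
        and the canonical isoform provides the architecture.
        ``transcript-preferred``: the most abundant annotated isoform is
        chosen and its own architecture is used (falls back to gene-only
        behaviour when the expression table is gene-level).
    length_normalize
        Divide transcript abundances by transcript length and rescale to
        one million before thresholding (FPKM-style counts to TPM-style).
    """

    threshold: float = 1.0
    mode: str = TRANSCRIPT_PREFERRED
    length_normalize: bool = False

    def __post_init__(self) -> None:
        if not (self.threshold >= 0 and self.threshold < float("inf")):
            raise ValueError("threshold must be finite and >= 0")
        if self.mode not in (GENE_ONLY, TRANSCRIPT_PREFERRED):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ContextResult:
    """Outputs of contextualizing one sample."""

    ppin: Network
    ddin: Network
    #: protein -> (chosen gene or transcript, abundance)
    major: dict[str, tuple[str, float]]
    options: ContextOptions
    sample: str = ""


def length_normalize(expr: ExpressionTable) -> ExpressionTable:
    """Length-normalize a transcript table and rescale to 1e6 total.

    Each abundance becomes ``a_i / len_i`` rescaled so all transcripts
    sum to 10^6.  Transcripts with zero abundance need no length.  An
    all-zero table stays all-zero.
    """
    if expr.level != TRANSCRIPT_LEVEL:
        raise ValueError("length normalization applies to transcript-level data")
    rates: dict[str, float] = {}
    for tx, value in expr.abundance.items():
        if value == 0:
            rates[tx] = 0.0
            continue
        length = expr.lengths.get(tx)
        if length is None:
            raise ValueError(f"missing length for expressed transcript {tx}")
        rates[tx] = value / length
    total = sum(rates.values())
    scale = 1e6 / total if total > 0 else 0.0
    return ExpressionTable(
        level=TRANSCRIPT_LEVEL,
        abundance={tx: r * scale for tx, r in rates.items()},
        tx2gene=dict(expr.tx2gene),
        lengths=dict(expr.lengths),
    )


def select_major_feature(
    expr: ExpressionTable,
    protein: str,
    annotation: DomainAnnotation,
    opts: ContextOptions,
) -> tuple[str, float] | None:
    """Pick the major gene/transcript of a protein in one sample.

    Returns ``(feature id, abundance)`` or ``None`` when nothing exceeds
    the threshold (the protein counts as unexpressed).  Missing
    expression records count as abundance 0.  Transcript ties break
    lexicographically for reproducibility.
    """
    if protein not in annotation.isoforms:
        raise KeyError(f"protein {protein} absent from the domain annotation")
    if opts.mode == GENE_ONLY or expr.level == GENE_LEVEL:
        gene = annotation.protein2gene[protein]
        abundance = expr.gene_total(gene)
        if abundance > opts.threshold:
            return gene, abundance
        return None
    best: tuple[str, float] | None = None
    for isoform in sorted(annotation.isoforms[protein]):
        abundance = expr.get(isoform)
        if best is None or abundance > best[1]:
            best = (isoform, abundance)
    if best is not None and best[1] > opts.threshold:
        return best
    return None


def build_reference_ddin(
    ppin: Network,
    annotation: DomainAnnotation,
    ddi: DDILibrary,
) -> tuple[Network, dict[Edge, set[Edge]]]:
    """Resolve a reference PPIN into its reference DDIN.

    For every interaction (u, v), all family pairs (f on any isoform of
    u, g on any isoform of v) found in the DDI library are expanded into
    domain edges between every occurrence instance.  Interactions with
    no documented pair get one artificial dummy–dummy edge.  Returns the
    domain-level network and the backing map interaction -> domain edges.
    """
    missing = sorted(n for n in ppin.nodes if n not in annotation.isoforms)
    if missing:
        raise ValueError(
            "network proteins absent from the domain annotation: "
            + ", ".join(missing)
        )
    ddin = Network(level=DOMAIN_LEVEL)
    backing: dict[Edge, set[Edge]] = {}
    for edge in sorted(ppin.edges):
        u, v = edge
        support: set[Edge] = set()
        for f in sorted(annotation.families(u)):
            for g in sorted(annotation.families(v)):
                if not ddi.interacts(f, g):
                    continue
                for i in range(annotation.occurrence_count(u, f)):
                    for j in range(annotation.occurrence_count(v, g)):
                        support.add(
                            ddin.add_edge(
                                str(DomainId(u, f, i)), str(DomainId(v, g, j))
                            )
                        )
        if not support:
            support.add(
                ddin.add_edge(str(dummy_domain(u)), str(dummy_domain(v)))
            )
        backing[edge] = support
    return ddin, backing


def _chosen_architecture(
    protein: str,
    feature: str,
    annotation: DomainAnnotation,
    opts: ContextOptions,
    expr_level: str,
) -> list[str]:
    if opts.mode == GENE_ONLY or expr_level == GENE_LEVEL:
        return annotation.canonical_architecture(protein)
    return annotation.isoforms[protein][feature]


def contextualize_sample(
    ppin: Network,
    ddin: Network,
    backing: dict[Edge, set[Edge]],
    annotation: DomainAnnotation,
    expr: ExpressionTable,
    opts: ContextOptions | None = None,
    sample: str = "",
) -> ContextResult:
    """Prune the reference networks to one sample's expression state.

    A domain instance survives if its owner protein has a major feature
    and the instance occurs in the chosen feature's architecture (dummy
    instances occur in every architecture of their owner).  A domain
    edge survives if both endpoints do; a protein interaction survives
    if at least one backing domain edge does.
    """
    opts = opts or ContextOptions()
    if opts.length_normalize:
        expr = length_normalize(expr)

    major: dict[str, tuple[str, float]] = {}
    for protein in sorted(ppin.nodes):
        chosen = select_major_feature(expr, protein, annotation, opts)
        if chosen is not None:
            major[protein] = chosen

    arch: dict[str, list[str]] = {
        p: _chosen_architecture(p, feat, annotation, opts, expr.level)
        for p, (feat, _) in major.items()
    }

    def survives(node: str) -> bool:
        d = DomainId.parse(node)
        if d.protein not in major:
            return False
        if d.is_dummy:
            return True
        return arch[d.protein].count(d.family) > d.occurrence

    cond_ddin = Network(level=DOMAIN_LEVEL)
    cond_ppin = Network(level=ppin.level)
    for edge in sorted(ppin.edges):
        kept = [
            de
            for de in sorted(backing[edge])
            if survives(de.u) and survives(de.v)
        ]
        if kept:
            for de in kept:
                cond_ddin.add_edge(de.u, de.v)
            cond_ppin.add_edge(edge.u, edge.v, ppin.weight(edge))
    return ContextResult(
        ppin=cond_ppin, ddin=cond_ddin, major=major, options=opts, sample=sample
    )
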