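"""Differential rewiring statistics between two groups of networks.

Given two groups of condition-specific protein networks, every
inter-group sample pair (i, j) yields a pairwise rewiring probability —
the fraction of edges that appear or vanish between the two networks.
Their mean, P_rewired, is the success probability of a binomial null in
which each of the N = |A|·|B| comparisons rewires an edge independently.
An edge alteration observed in k comparisons is scored with the
one-tailed binomial p-value P[X >= k], X ~ Bin(N, P_rewired); p-values
are Benjamini–Hochberg adjusted and alterations with q below the FDR
level form the differential network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import Edge, Network, edge_difference

LOST = "lost"
GAINED = "gained"

PAIR_UNION = "pair"
GLOBAL_UNION = "global"


@dataclass
class SampleNet:
    """One sample: its condition-specific network and major-feature map."""

    name: str
    net: Network
    #: protein -> (chosen gene or transcript, abundance); None when the
    #: major-transcript table was not provided
    major: dict[str, tuple[str, float]] | None = None


@dataclass
class Group:
    """A labelled group of condition-specific sample networks."""

    label: str
    samples: list[SampleNet]

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError(f"group {self.label!r} has no samples")
        for s in self.samples:
            if s.net.level != "protein":
                raise ValueError("rewiring statistics need protein-level networks")


@dataclass
class RewiringNull:
    """The binomial null: N inter-group comparisons at rate P_rewired."""

    n_pairs: int
    per_pair: list[float]
    p_rewired: float


@dataclass
class EdgeAlteration:
    """One rewired interaction, oriented group A -> group B."""

    edge: Edge
    direction: str
    support: int
    lost_pairs: tuple[int, ...]
    gained_pairs: tuple[int, ...]
    p_value: float = float("nan")
    q_value: float = float("nan")
    significant: bool = False

    @property
    def pairs(self) -> tuple[int, ...]:
        """Comparison indices of the majority direction."""
        return self.lost_pairs if self.direction == LOST else self.gained_pairs


@dataclass
class DifferentialNetwork:
    """All tested alterations plus the significant subset."""

    alterations: list[EdgeAlteration]
    null: RewiringNull
    fdr: float

    @property
    def significant(self) -> list[EdgeAlteration]:
        return sorted(
            (a for a in self.alterations if a.significant),
            key=lambda a: (a.q_value, a.p_value, a.edge),
        )

    @property
    def significant_edges(self) -> set[Edge]:
        return {a.edge for a in self.alterations if a.significant}


def pairwise_rewiring_probability(
    net_a: Network,
    net_b: Network,
    denominator: set[Edge] | None = None,
) -> float:
    """Fraction of rewired edges between two sample networks.

    By default the denominator is the pair's own edge union; passing
    ``denominator`` (e.g. the union over every sample) switches to a
    global reading.  An empty denominator yields 0.
    """
    lost, gained = edge_difference(net_a, net_b)
    denom = denominator if denominator is not None else net_a.edges | net_b.edges
    if not denom:
        return 0.0
    return (len(lost) + len(gained)) / len(denom)


def build_null(
    group_a: Group, group_b: Group, union: str = PAIR_UNION
) -> RewiringNull:
    """Average the pairwise rewiring probabilities over all N = |A|·|B|
    inter-group sample pairs."""
    if union not in (PAIR_UNION, GLOBAL_UNION):
        raise ValueError(f"unknown union mode {union!r}")
    denominator = None
    if union == GLOBAL_UNION:
        denominator = set()
        for s in group_a.samples + group_b.samples:
            denominator |= s.net.edges
    per_pair = [
        pairwise_rewiring_probability(a.net, b.net, denominator)
        for a in group_a.samples
        for b in group_b.samples
    ]
    return RewiringNull(
        n_pairs=len(per_pair),
        per_pair=per_pair,
        p_rewired=float(np.mean(per_pair)),
    )


def count_alterations(group_a: Group, group_b: Group) -> list[EdgeAlteration]:
    """Count, per edge, the inter-group comparisons where it rewires.

    Comparison index for (a_i, b_j) is ``i * |B| + j``.  An edge present
    in a_i but absent from b_j counts as lost in that comparison, the
    reverse as gained.  The alteration's direction is the majority one
    (ties resolve to lost, with a warning); edges never rewired are
    omitted.
    """
    sets_a = [s.net.edges for s in group_a.samples]
    sets_b = [s.net.edges for s in group_b.samples]
    universe: set[Edge] = set()
    for es in sets_a + sets_b:
        universe |= es
    nb = len(sets_b)
    out: list[EdgeAlteration] = []
    for edge in sorted(universe):
        lost_pairs: list[int] = []
        gained_pairs: list[int] = []
        for i, ea in enumerate(sets_a):
            in_a = edge in ea
            for j, eb in enumerate(sets_b):
                in_b = edge in eb
                if in_a and not in_b:
                    lost_pairs.append(i * nb + j)
                elif in_b and not in_a:
                    gained_pairs.append(i * nb + j)
        nl, ng = len(lost_pairs), len(gained_pairs)
        if nl == 0 and ng == 0:
            continue
        if nl == ng:
            warnings.warn(
                f"direction tie for edge {edge.u}--{edge.v}; resolved to 'lost'",
                stacklevel=2,
            )
        direction = LOST if nl >= ng else GAINED
        out.append(
            EdgeAlteration(
                edge=edge,
                direction=direction,
                support=max(nl, ng),
                lost_pairs=tuple(lost_pairs),
                gained_pairs=tuple(gained_pairs),
            )
        )
    return out


def edge_pvalue(support: int, null: RewiringNull) -> float:
    """One-tailed binomial p-value of an alteration seen ``support`` times.

    p = P[X >= support], X ~ Bin(N, P_rewired), evaluated with the
    numerically stable survival function (equivalent to
    1 − Σ_{j<support} C(N,j) P^j (1−P)^{N−j}).
    """
    if not 1 <= support <= null.n_pairs:
        raise ValueError(
            f"support {support} outside 1..{null.n_pairs} comparisons"
        )
    return float(stats.binom.sf(support - 1, null.n_pairs, null.p_rewired))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def differential_network(
    group_a: Group,
    group_b: Group,
    fdr: float = 0.05,
    union: str = PAIR_UNION,
) -> DifferentialNetwork:
    """Full rewiring pipeline: null, per-edge tests, BH, significance."""
    if not 0 <= fdr <= 1:
        raise ValueError("fdr must lie in [0, 1]")
    null = build_null(group_a, group_b, union=union)
    alterations = count_alterations(group_a, group_b)
    if alterations and null.p_rewired == 0:
        # cannot happen when the same pairs define both the null and the
        # counts: any alteration makes some pairwise probability positive
        raise RuntimeError("degenerate null: alterations observed at P_rewired = 0")
    if alterations:
        qs = bh_adjust([edge_pvalue(a.support, null) for a in alterations])
        for a, q in zip(alterations, qs):
            a.p_value = edge_pvalue(a.support, null)
            a.q_value = float(q)
            a.significant = a.q_value <= fdr
    return DifferentialNetwork(alterations=alterations, null=null, fdr=fdr)
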