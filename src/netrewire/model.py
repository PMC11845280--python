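"""Core graph and identifier types shared by every pipeline stage.

Networks are undirected, at one of two levels: ``protein`` (nodes are
protein accessions) or ``domain`` (nodes are domain *instances*, i.e. a
specific occurrence of a domain family on a specific protein).  Edges are
stored canonically so that (u, v) and (v, u) are the same interaction.
An optional per-edge weight is carried through verbatim but is never used
by any statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

#: Reserved family name for the artificial domain assigned to proteins
#: without any annotated domain, so their interactions stay representable
#: at the domain level.  Must never clash with a real family name.
DUMMY_FAMILY = "DUMMY"

PROTEIN_LEVEL = "protein"
DOMAIN_LEVEL = "domain"


class Edge(NamedTuple):
    """An undirected interaction, endpoints in canonical (sorted) order."""

    u: str
    v: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.u}--{self.v}"


def canonical_edge(a: str, b: str) -> Edge:
    """Return the canonical :class:`Edge` for an unordered node pair.

    Raises
    ------
    ValueError
        If either identifier is empty, or if ``a == b`` (self-loops are
        rejected; the rewiring model has no use for them).
    """
    if not a or not b:
        raise ValueError("edge endpoints must be non-empty identifiers")
    if a == b:
        raise ValueError(f"self-loop on {a!r} rejected")
    return Edge(a, b) if a < b else Edge(b, a)


@dataclass(frozen=True, order=True)
class DomainId:
    """A domain instance: one occurrence of a family on one protein.

    A protein may carry several copies of the same family; ``occurrence``
    (0-based) distinguishes them.  The string form ``protein|family|occ``
    is the node identifier used in domain-level networks and files.
    """

    protein: str
    family: str
    occurrence: int = 0

    def __post_init__(self) -> None:
        if not self.protein or not self.family:
            raise ValueError("DomainId requires non-empty protein and family")
        if self.occurrence < 0:
            raise ValueError("occurrence index must be >= 0")

    @property
    def is_dummy(self) -> bool:
        return self.family == DUMMY_FAMILY

    def __str__(self) -> str:
        return f"{self.protein}|{self.family}|{self.occurrence}"

    @classmethod
    def parse(cls, s: str) -> "DomainId":
        parts = s.split("|")
        if len(parts) != 3:
            raise ValueError(f"not a domain identifier: {s!r}")
        protein, family, occ = parts
        return cls(protein, family, int(occ))


def dummy_domain(protein: str) -> DomainId:
    """The artificial domain instance of a protein."""
    return DomainId(protein, DUMMY_FAMILY, 0)


@dataclass
class Network:
    """An undirected network at protein or domain level.

    Nodes are plain strings (protein accessions, or stringified
    :class:`DomainId` at domain level).  Duplicate edges collapse,
    keeping the first weight seen.
    """

    level: str = PROTEIN_LEVEL
    nodes: set[str] = field(default_factory=set)
    _edges: dict[Edge, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in (PROTEIN_LEVEL, DOMAIN_LEVEL):
            raise ValueError(f"unknown network level {self.level!r}")

    # -- construction -------------------------------------------------
    def add_node(self, node: str) -> None:
        if not node:
            raise ValueError("node identifier must be non-empty")
        self.nodes.add(node)

    def add_edge(self, a: str, b: str, weight: float | None = None) -> Edge:
        if weight is not None and weight < 0:
            raise ValueError(f"negative edge weight {weight!r}")
        e = canonical_edge(a, b)
        self.nodes.add(e.u)
        self.nodes.add(e.v)
        if e not in self._edges:
            self._edges[e] = weight
        return e

    # -- queries ------------------------------------------------------
    @property
    def edges(self) -> set[Edge]:
        return set(self._edges)

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_edge(a, b) in self._edges

    def weight(self, edge: Edge) -> float | None:
        return self._edges[edge]

    def edge_items(self) -> Iterator[tuple[Edge, float | None]]:
        return iter(self._edges.items())

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def copy(self) -> "Network":
        return Network(self.level, set(self.nodes), dict(self._edges))

    def to_networkx(self):
        """Export as a :class:`networkx.Graph` (weights as edge attributes)."""
        import networkx as nx

        g = nx.Graph(level=self.level)
        g.add_nodes_from(sorted(self.nodes))
        for e, w in sorted(self._edges.items()):
            if w is None:
                g.add_edge(e.u, e.v)
            else:
                g.add_edge(e.u, e.v, weight=w)
        return g


def edge_difference(net_a: Network, net_b: Network) -> tuple[set[Edge], set[Edge]]:
    """Edges lost and gained going from ``net_a`` to ``net_b``.

    Returns ``(lost, gained)`` with ``lost`` the edges present in A but
    not B and ``gained`` the reverse.  Both networks must live at the
    same level (protein vs domain).
    """
    if net_a.level != net_b.level:
        raise ValueError(
            f"cannot diff networks at different levels: "
            f"{net_a.level!r} vs {net_b.level!r}"
        )
    ea, eb = net_a.edges, net_b.edges
    return ea - eb, eb - ea
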