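"""Attribution of significant rewiring to transcriptomic changes.

Each significant alteration is observed in specific inter-group sample
comparisons; the pairs (alteration, comparison) form the universe of a
weighted set cover.  A candidate *reason* is a transcriptomic change of
one endpoint protein — an expression loss/gain or an isoform switch —
that is consistent with the alteration in that specific comparison.

Reason i covering r_w instances across p_w distinct comparisons gets a
score s_i = p_w · r_w and a weight w_i = s_max − s_i, so the reason
explaining the most alterations across the most comparisons is free.
The cover minimizing total weight is approximated with the classical
greedy heuristic: repeatedly pick the reason with the smallest
weight-per-newly-covered-instance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import Edge
from .rewiring import GAINED, LOST, DifferentialNetwork, Group

EXPRESSION_LOSS = "expression-loss"
EXPRESSION_GAIN = "expression-gain"
ISOFORM_SWITCH = "isoform-switch"

#: one element of the cover universe: (edge, direction, comparison index)
Instance = tuple[Edge, str, int]


@dataclass
class Reason:
    """A transcriptomic change of one protein, with its covered instances."""

    protein: str
    kind: str
    instances: frozenset[Instance] = frozenset()
    #: features of the protein involved (genes/transcripts seen to change)
    features: tuple[str, ...] = ()
    r_w: int = 0
    p_w: int = 0
    score: int = 0
    weight: int = 0

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein, self.kind)


@dataclass
class CoverSolution:
    """Greedy cover result: selected reasons in selection order."""

    selected: list[Reason]
    covered: set[Instance]
    uncovered: set[Instance]
    total_weight: int

    @property
    def covered_fraction(self) -> float:
        total = len(self.covered) + len(self.uncovered)
        return len(self.covered) / total if total else 1.0


def alteration_universe(diff: DifferentialNetwork) -> set[Instance]:
    """All (edge, direction, comparison) instances of significant alterations."""
    return {
        (a.edge, a.direction, pair)
        for a in diff.alterations
        if a.significant
        for pair in a.pairs
    }


def enumerate_reasons(
    diff: DifferentialNetwork, group_a: Group, group_b: Group
) -> list[Reason]:
    """Candidate transcriptomic explanations for the significant alterations.

    For an instance (edge (u,v), direction, comparison (a,b)) each
    endpoint w contributes a candidate when its major feature differs
    between a and b consistently with the direction: expressed on the
    side where the edge is present and absent on the other side
    (expression loss/gain), or a different major feature on each side
    (isoform switch).  Instances with no candidate are left uncoverable.
    """
    for s in group_a.samples + group_b.samples:
        if s.major is None:
            raise ValueError(f"sample {s.name!r} has no major-feature map")
    nb = len(group_b.samples)
    collected: dict[tuple[str, str], set[Instance]] = {}
    feats: dict[tuple[str, str], set[str]] = {}

    def add(protein: str, kind: str, inst: Instance, *features: str) -> None:
        key = (protein, kind)
        collected.setdefault(key, set()).add(inst)
        feats.setdefault(key, set()).update(features)

    for inst in sorted(alteration_universe(diff)):
        edge, direction, pair = inst
        a = group_a.samples[pair // nb]
        b = group_b.samples[pair % nb]
        for w in edge:
            fa = a.major.get(w)  # type: ignore[union-attr]
            fb = b.major.get(w)  # type: ignore[union-attr]
            if direction == LOST:
                if fa is not None and fb is None:
                    add(w, EXPRESSION_LOSS, inst, fa[0])
                elif fa is not None and fb is not None and fa[0] != fb[0]:
                    add(w, ISOFORM_SWITCH, inst, fa[0], fb[0])
            else:
                if fa is None and fb is not None:
                    add(w, EXPRESSION_GAIN, inst, fb[0])
                elif fa is not None and fb is not None and fa[0] != fb[0]:
                    add(w, ISOFORM_SWITCH, inst, fa[0], fb[0])
    return [
        Reason(
            protein=protein,
            kind=kind,
            instances=frozenset(instances),
            features=tuple(sorted(feats[(protein, kind)])),
        )
        for (protein, kind), instances in sorted(collected.items())
    ]


def score_reasons(candidates: list[Reason]) -> list[Reason]:
    """Assign r_w, p_w, s_i = p_w·r_w and w_i = s_max − s_i to candidates."""
    if not candidates:
        return []
    scored: list[Reason] = []
    for r in candidates:
        r_w = len(r.instances)
        p_w = len({pair for (_, _, pair) in r.instances})
        scored.append(
            Reason(
                protein=r.protein,
                kind=r.kind,
                instances=r.instances,
                features=r.features,
                r_w=r_w,
                p_w=p_w,
                score=p_w * r_w,
            )
        )
    s_max = max(r.score for r in scored)
    for r in scored:
        r.weight = s_max - r.score
    return scored


def greedy_cover(
    reasons: list[Reason], universe: set[Instance]
) -> CoverSolution:
    """Chvátal's greedy weighted set cover over the instance universe.

    Repeatedly selects the reason minimizing weight / newly-covered
    (zero-weight reasons with new coverage come first at ratio 0); ties
    break by lower weight, then larger new coverage, then lexicographic
    reason key.  Stops when no candidate adds coverage; instances no
    reason covers are reported as uncovered.
    """
    universe = set(universe)
    covered: set[Instance] = set()
    selected: list[Reason] = []
    total_weight = 0
    pool = sorted(reasons, key=lambda r: r.key)
    while True:
        best = None
        best_key = None
        for r in pool:
            new = len((r.instances & universe) - covered)
            if new == 0:
                continue
            key = (r.weight / new, r.weight, -new, r.key)
            if best_key is None or key < best_key:
                best, best_key = r, key
        if best is None:
            break
        selected.append(best)
        covered |= best.instances & universe
        total_weight += best.weight
        pool.remove(best)
    return CoverSolution(
        selected=selected,
        covered=covered,
        uncovered=universe - covered,
        total_weight=total_weight,
    )


def attribute(
    diff: DifferentialNetwork, group_a: Group, group_b: Group
) -> tuple[CoverSolution, list[Reason]]:
    """Convenience wrapper: enumerate, score and cover in one call."""
    universe = alteration_universe(diff)
    scored = score_reasons(enumerate_reasons(diff, group_a, group_b))
    return greedy_cover(scored, universe), scored
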