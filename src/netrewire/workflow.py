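"""In-memory orchestration of the full pipeline on a synthetic scenario."""

from __future__ import annotations

from dataclasses import dataclass

from .contextualize import ContextOptions, build_reference_ddin, contextualize_sample
from .reasons import CoverSolution, Reason, attribute
from .rewiring import (
    PAIR_UNION,
    DifferentialNetwork,
    Group,
    SampleNet,
    differential_network,
)
from .simulate import Scenario


@dataclass
class PipelineResult:
    group_a: Group
    group_b: Group
    diff: DifferentialNetwork
    cover: CoverSolution
    reasons: list[Reason]


def contextualize_group(
    scenario: Scenario, label: str, opts: ContextOptions, ddin, backing
) -> Group:
    samples = []
    for name, table in scenario.groups[label]:
        result = contextualize_sample(
            scenario.ppin, ddin, backing, scenario.annotation, table, opts, name
        )
        samples.append(SampleNet(name=name, net=result.ppin, major=result.major))
    return Group(label=label, samples=samples)


def run_scenario(
    scenario: Scenario,
    opts: ContextOptions | None = None,
    fdr: float = 0.05,
    union: str = PAIR_UNION,
) -> PipelineResult:
    """Contextualize every sample, test rewiring, attribute reasons."""
    opts = opts or ContextOptions()
    ddin, backing = build_reference_ddin(
        scenario.ppin, scenario.annotation, scenario.ddi
    )
    group_a = contextualize_group(scenario, "group1", opts, ddin, backing)
    group_b = contextualize_group(scenario, "group2", opts, ddin, backing)
    diff = differential_network(group_a, group_b, fdr=fdr, union=union)
    cover, reasons = attribute(diff, group_a, group_b)
    return PipelineResult(
        group_a=group_a, group_b=group_b, diff=diff, cover=cover, reasons=reasons
    )
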