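"""Seeded generators for every input the pipeline consumes.

The generator emulates a two-condition interactome study: an
Erdős–Rényi reference network over a protein universe, domain
architectures with partial annotation coverage, a DDI library backing a
controllable fraction of interactions, and per-sample transcript-level
expression tables for two groups.  Ground-truth rewiring is planted
through one of three mechanisms — an expression loss or gain of one
endpoint, or an isoform switch that drops the sole backing domain — on
dedicated protein pairs kept out of the random background, so that at
zero noise the true differential network is exactly the planted set.
Background noise toggles whole-protein expression independently per
sample, so the null rewiring process propagates through
contextualization exactly like real expression variability would.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .io import (
    TRANSCRIPT_LEVEL,
    DDILibrary,
    DomainAnnotation,
    ExpressionTable,
    write_ddi_library,
    write_domain_annotation,
    write_expression,
    write_ppin,
)
from .model import Edge, Network, canonical_edge
from .reasons import EXPRESSION_GAIN, EXPRESSION_LOSS, ISOFORM_SWITCH
from .rewiring import GAINED, LOST

MECHANISMS = (EXPRESSION_LOSS, EXPRESSION_GAIN, ISOFORM_SWITCH)

#: abundance ratio of a minor isoform relative to the canonical one; small
#: enough that background isoform switches are vanishingly rare, so the
#: background noise level is governed by the flip rate alone
_MINOR_FACTOR = 0.1
_SIGMA = 0.4


@dataclass(frozen=True)
class ScenarioSpec:
    """Study conditions for one synthetic two-group experiment.

    Defaults describe the reference stochastic setting used throughout:
    a 200-protein network at Erdős–Rényi density 0.025 (mean degree ~5),
    half of the interactions backed by documented domain pairs, two
    isoforms per protein, three samples per group, and a background
    flip rate of 0.02 per protein per sample.
    """

    n_proteins: int = 200
    edge_density: float = 0.025
    ddi_backed_fraction: float = 0.5
    unannotated_fraction: float = 0.1
    isoforms_per_protein: int = 2
    n_samples_per_group: int = 3
    #: mechanisms of the planted alterations, one dedicated edge each
    planted: tuple[str, ...] = ()
    background_flip_rate: float = 0.02
    expression_scale: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 2:
            raise ValueError("need at least 2 proteins")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge density must lie in (0, 1]")
        if not 0 <= self.background_flip_rate < 1:
            raise ValueError("flip rate must lie in [0, 1)")
        if not 0 <= self.ddi_backed_fraction <= 1:
            raise ValueError("ddi_backed_fraction must lie in [0, 1]")
        if not 0 <= self.unannotated_fraction <= 1:
            raise ValueError("unannotated_fraction must lie in [0, 1]")
        if self.isoforms_per_protein < 1:
            raise ValueError("need at least one isoform per protein")
        if self.n_samples_per_group < 1:
            raise ValueError("need at least one sample per group")
        if self.expression_scale <= 0:
            raise ValueError("expression scale must be positive")
        for mech in self.planted:
            if mech not in MECHANISMS:
                raise ValueError(f"unknown planted mechanism {mech!r}")
        if 2 * len(self.planted) > self.n_proteins:
            raise ValueError(
                "infeasible: planted edges need more proteins than the network has"
            )
        if ISOFORM_SWITCH in self.planted and self.isoforms_per_protein < 2:
            raise ValueError("isoform switches need >= 2 isoforms per protein")

    @classmethod
    def from_json(cls, path: str | Path, seed: int | None = None) -> "ScenarioSpec":
        data = json.loads(Path(path).read_text())
        if "planted" in data:
            data["planted"] = tuple(data["planted"])
        if seed is not None:
            data["seed"] = seed
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class PlantedEdge:
    edge: Edge
    direction: str  # orientation group1 -> group2
    mechanism: str
    reason_protein: str


@dataclass
class GroundTruth:
    planted: list[PlantedEdge]

    @property
    def edges(self) -> set[Edge]:
        return {p.edge for p in self.planted}


@dataclass
class Scenario:
    spec: ScenarioSpec
    ppin: Network
    annotation: DomainAnnotation
    ddi: DDILibrary
    #: group label -> list of (sample name, transcript-level table)
    groups: dict[str, list[tuple[str, ExpressionTable]]]
    truth: GroundTruth


def _tx(protein: str, k: int) -> str:
    return f"{protein}.T{k}"


def generate_scenario(spec: ScenarioSpec) -> Scenario:
    """Generate all pipeline inputs plus ground truth, deterministically."""
    rng = np.random.default_rng(spec.seed)
    width = max(4, len(str(spec.n_proteins)))
    proteins = [f"P{i + 1:0{width}d}" for i in range(spec.n_proteins)]
    n_planted = len(spec.planted)
    background = proteins[: spec.n_proteins - 2 * n_planted]
    planted_pool = proteins[spec.n_proteins - 2 * n_planted :]

    # --- domain architectures --------------------------------------------
    annotation = DomainAnnotation()
    pool = [f"PF{i + 1:04d}" for i in range(max(2, len(background)))]
    unannotated = rng.random(len(background)) < spec.unannotated_fraction
    arch_of: dict[str, list[str]] = {}
    for idx, protein in enumerate(background):
        if unannotated[idx]:
            canonical: list[str] = []
        else:
            canonical = [pool[k] for k in rng.choice(len(pool), size=2, replace=False)]
        arch_of[protein] = canonical
        gene = f"G{idx + 1:0{width}d}"
        annotation.add_isoform(protein, gene, _tx(protein, 1), canonical, True)
        for k in range(2, spec.isoforms_per_protein + 1):
            annotation.add_isoform(protein, gene, _tx(protein, k), canonical[:1])

    # --- reference network ------------------------------------------------
    ppin = Network()
    g = nx.fast_gnp_random_graph(
        len(background), spec.edge_density, seed=int(rng.integers(2**31))
    )
    for i, j in sorted(g.edges()):
        ppin.add_edge(background[i], background[j])
    for p in background:
        ppin.add_node(p)

    # --- DDI library backing a fraction of the background edges -----------
    ddi = DDILibrary()
    backable = [
        e for e in sorted(ppin.edges) if arch_of[e.u] and arch_of[e.v]
    ]
    n_backed = int(round(spec.ddi_backed_fraction * len(backable)))
    if backable and n_backed:
        chosen = rng.choice(len(backable), size=n_backed, replace=False)
        for k in sorted(chosen):
            e = backable[k]
            fu = arch_of[e.u][int(rng.integers(len(arch_of[e.u])))]
            fv = arch_of[e.v][int(rng.integers(len(arch_of[e.v])))]
            ddi.add(fu, fv)

    # --- planted alterations on dedicated protein pairs -------------------
    truth = GroundTruth(planted=[])
    for idx, mech in enumerate(spec.planted):
        u, v = planted_pool[2 * idx], planted_pool[2 * idx + 1]
        fam_u, fam_v = f"PX{idx + 1:03d}A", f"PX{idx + 1:03d}B"
        gu = f"G{len(background) + 2 * idx + 1:0{width}d}"
        gv = f"G{len(background) + 2 * idx + 2:0{width}d}"
        minor_u = [] if mech == ISOFORM_SWITCH else [fam_u]
        annotation.add_isoform(u, gu, _tx(u, 1), [fam_u], True)
        annotation.add_isoform(v, gv, _tx(v, 1), [fam_v], True)
        for k in range(2, max(2, spec.isoforms_per_protein) + 1):
            annotation.add_isoform(u, gu, _tx(u, k), minor_u)
            annotation.add_isoform(v, gv, _tx(v, k), [fam_v])
        ddi.add(fam_u, fam_v)
        edge = ppin.add_edge(u, v)
        direction = GAINED if mech == EXPRESSION_GAIN else LOST
        truth.planted.append(PlantedEdge(edge, direction, mech, u))

    # --- transcript lengths ------------------------------------------------
    lengths: dict[str, int] = {}
    for protein in proteins:
        for k in range(1, spec.isoforms_per_protein + 1):
            lengths[_tx(protein, k)] = int(rng.integers(500, 5001))
    if spec.isoforms_per_protein < 2:
        for idx in range(n_planted):
            for p in planted_pool[2 * idx : 2 * idx + 2]:
                lengths[_tx(p, 2)] = int(rng.integers(500, 5001))

    # --- expression tables --------------------------------------------------
    scale = spec.expression_scale

    def draw() -> float:
        return float(scale * rng.lognormal(0.0, _SIGMA))

    groups: dict[str, list[tuple[str, ExpressionTable]]] = {}
    for group in ("group1", "group2"):
        samples: list[tuple[str, ExpressionTable]] = []
        for s in range(1, spec.n_samples_per_group + 1):
            flips = rng.random(len(background)) < spec.background_flip_rate
            abundance: dict[str, float] = {}
            tx2gene: dict[str, str] = {}

            def put(protein: str, k: int, value: float) -> None:
                tx = _tx(protein, k)
                if value > 0:
                    abundance[tx] = value
                    tx2gene[tx] = annotation.protein2gene[protein]

            for idx, protein in enumerate(background):
                values = [draw()] + [
                    _MINOR_FACTOR * draw()
                    for _ in range(spec.isoforms_per_protein - 1)
                ]
                if flips[idx]:
                    continue  # protein toggled off in this sample
                for k, value in enumerate(values, start=1):
                    put(protein, k, value)
            for idx, mech in enumerate(spec.planted):
                u, v = planted_pool[2 * idx], planted_pool[2 * idx + 1]
                n_iso = max(2, spec.isoforms_per_protein)
                u_vals = [draw()] + [_MINOR_FACTOR * draw() for _ in range(n_iso - 1)]
                v_vals = [draw()] + [_MINOR_FACTOR * draw() for _ in range(n_iso - 1)]
                expressed_u = (
                    group == "group1"
                    if mech in (EXPRESSION_LOSS, ISOFORM_SWITCH)
                    else group == "group2"
                )
                if mech == ISOFORM_SWITCH:
                    if group == "group2":
                        # the domain-less minor isoform takes over
                        u_vals = [u_vals[1], u_vals[0]] + u_vals[2:]
                    expressed_u = True
                if expressed_u:
                    for k, value in enumerate(u_vals, start=1):
                        put(u, k, value)
                for k, value in enumerate(v_vals, start=1):
                    put(v, k, value)
            table = ExpressionTable(
                level=TRANSCRIPT_LEVEL,
                abundance=abundance,
                tx2gene=tx2gene,
                lengths={tx: lengths[tx] for tx in abundance},
            )
            samples.append((f"{group}_s{s}", table))
        groups[group] = samples
    return Scenario(
        spec=spec, ppin=ppin, annotation=annotation, ddi=ddi,
        groups=groups, truth=truth,
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Write all generated inputs plus ground_truth.txt; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {
        "ppin": outdir / "reference_ppin.txt",
        "annotation": outdir / "annotation.txt",
        "ddi": outdir / "ddi_library.txt",
        "ground_truth": outdir / "ground_truth.txt",
        "spec": outdir / "scenario_spec.json",
    }
    write_ppin(scenario.ppin, paths["ppin"])
    write_domain_annotation(scenario.annotation, paths["annotation"])
    write_ddi_library(scenario.ddi, paths["ddi"])
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        for p in scenario.truth.planted:
            fh.write(
                f"{p.edge.u}\t{p.edge.v}\t{p.direction}\t{p.mechanism}"
                f"\t{p.reason_protein}\n"
            )
    spec_dict = asdict(scenario.spec)
    spec_dict["planted"] = list(spec_dict["planted"])
    paths["spec"].write_text(json.dumps(spec_dict, indent=2) + "\n")
    for group, samples in scenario.groups.items():
        for name, table in samples:
            path = outdir / f"{name}.txt"
            write_expression(table, path)
            paths[name] = path
    return paths
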