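"""Synthetic fixtures: a random true DAG plus oracle-consistent study files.

The generator samples a DAG (edges drawn only forward along a random
topological order, so acyclicity holds by construction), draws study designs
without replacement from the research-map pool, answers each with the
d-separation oracle, and emits both a research-map annotation and the
equivalent constraints file.  Everything is a pure function of the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Mapping

from .constraints import (
    IndependenceConstraint,
    Polarity,
    StudyDesign,
    constraints_to_json_dict,
    enumerate_study_designs,
    study_result_to_constraint,
)
from .dag import DirectedAcyclicGraph, default_variables
from .simulation import Oracle


@dataclass(frozen=True)
class FixtureSpec:
    n_vars: int = 4
    edge_probability: float = 0.5
    n_studies: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_vars <= 6:
            raise ValueError("n_vars must be between 2 and 6")
        if not 0.0 <= self.edge_probability <= 1.0:
            raise ValueError("edge_probability must lie in [0, 1]")
        pool = 4 * self.n_vars * (self.n_vars - 1)
        if not 1 <= self.n_studies <= pool:
            raise ValueError(
                f"n_studies must be between 1 and the pool size {pool}"
            )


@dataclass(frozen=True)
class Fixture:
    true_graph: DirectedAcyclicGraph
    studies: tuple[tuple[StudyDesign, Polarity], ...]
    constraints: tuple[IndependenceConstraint, ...]
    research_map: Mapping
    constraints_json: Mapping


def generate_fixture(spec: FixtureSpec) -> Fixture:
    rng = random.Random(spec.seed)
    variables = list(default_variables(spec.n_vars))
    order = variables[:]
    rng.shuffle(order)
    edges = [
        (order[i], order[j])
        for i in range(spec.n_vars)
        for j in range(i + 1, spec.n_vars)
        if rng.random() < spec.edge_probability
    ]
    true_graph = DirectedAcyclicGraph(sorted(variables), edges)
    oracle = Oracle(true_graph)

    pool = enumerate_study_designs(variables)
    designs = rng.sample(pool, spec.n_studies)
    studies = tuple((d, oracle.verdict(d)) for d in designs)
    constraints = tuple(
        study_result_to_constraint(d, verdict) for d, verdict in studies
    )
    return Fixture(
        true_graph=true_graph,
        studies=studies,
        constraints=constraints,
        research_map=_research_map(variables, studies),
        constraints_json=constraints_to_json_dict(variables, constraints),
    )


def _research_map(variables, studies) -> dict:
    """Group studies into research-map edges keyed by (ordered pair, verdict);
    dependence is rendered as excitation (the correlation sign is metadata
    the causal analysis discards)."""
    grouped: dict[tuple[str, str, Polarity], list[StudyDesign]] = {}
    for design, verdict in studies:
        grouped.setdefault((design.source, design.target, verdict), []).append(design)
    edges = []
    for (source, target, verdict), designs in sorted(
        grouped.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)
    ):
        edges.append(
            {
                "source": source,
                "target": target,
                "relation": (
                    "excitation" if verdict is Polarity.DEPENDENT else "independence"
                ),
                "studies": [
                    {"method": d.method.value}
                    for d in sorted(designs, key=StudyDesign.sort_key)
                ],
            }
        )
    return {"nodes": [{"name": v} for v in sorted(variables)], "edges": edges}
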