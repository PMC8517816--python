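"""Model dimension: how many independent parameters a network needs.

The dimension of a discrete network is ``Σ_i (r_i − 1) · q_i`` where ``r_i``
is the cardinality of node *i* and ``q_i`` the number of configurations of
its parents (``q_i = 1`` for a root). This is what makes full-table
elicitation explode — a binary node with *n* binary parents already needs
``2^n`` rows — and what the noisy-OR parameterization of the advice nodes
avoids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .errors import StructureError
from .model import ModelSpec
from .levels import N_LEVELS

__all__ = ["NodeSpec", "model_dimension", "parent_configuration_counts", "nodes_of_model"]


@dataclass(frozen=True)
class NodeSpec:
    """Abstract node: a name, its cardinality r, and its parent names."""

    name: str
    cardinality: int
    parents: tuple[str, ...] = ()

    def __post_init__(self):
        if self.cardinality < 2:
            raise ValueError(f"node {self.name!r}: cardinality must be >= 2")
        object.__setattr__(self, "parents", tuple(self.parents))


def _as_nodes(model: "ModelSpec | Iterable[NodeSpec]") -> tuple[NodeSpec, ...]:
    if isinstance(model, ModelSpec):
        return nodes_of_model(model)
    return tuple(model)


def nodes_of_model(model: ModelSpec) -> tuple[NodeSpec, ...]:
    """Expand a knowledge base into its explicit node list.

    Context roots (gender, age), then per dimension an IF node with the two
    context parents, a CF root, a CS node with (IF, CF) parents, the question
    nodes, and one binary node per advice with its parent dimensions' CS
    nodes as parents.
    """
    nodes = [NodeSpec("gender", 2), NodeSpec("age", 2)]
    for d in model.dimensions:
        nodes.append(NodeSpec(f"IF[{d.id}]", N_LEVELS, ("gender", "age")))
        nodes.append(NodeSpec(f"CF[{d.id}]", N_LEVELS))
        nodes.append(NodeSpec(f"CS[{d.id}]", N_LEVELS, (f"IF[{d.id}]", f"CF[{d.id}]")))
    for q in model.questions:
        nodes.append(NodeSpec(f"Q[{q.id}]", N_LEVELS, (f"IF[{q.dimension_id}]",)))
    for a in model.advice:
        nodes.append(
            NodeSpec(
                f"advice[{a.id}]",
                2,
                tuple(f"CS[{pd}]" for pd in a.parent_dimension_ids),
            )
        )
    return tuple(nodes)


def parent_configuration_counts(
    model: "ModelSpec | Iterable[NodeSpec]",
) -> Mapping[str, int]:
    """Per-node q_i: the product of parent cardinalities (1 for a root)."""
    nodes = _as_nodes(model)
    card = {n.name: n.cardinality for n in nodes}

    graph = nx.DiGraph()
    graph.add_nodes_from(card)
    for n in nodes:
        for p in n.parents:
            if p not in card:
                raise StructureError(f"node {n.name!r} references unknown parent {p!r}")
            graph.add_edge(p, n.name)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise StructureError(f"parent structure contains a cycle: {cycle}")

    q: dict[str, int] = {}
    for n in nodes:
        qi = 1
        for p in n.parents:
            qi *= card[p]
        q[n.name] = qi
    return q


def model_dimension(model: "ModelSpec | Iterable[NodeSpec]") -> int:
    """Number of independent parameters of the full-table network.

    ``Σ_i (r_i − 1) · q_i``; raises :class:`StructureError` on a cyclic
    parent structure.
    """
    nodes = _as_nodes(model)
    q = parent_configuration_counts(nodes)
    return sum((n.cardinality - 1) * q[n.name] for n in nodes)
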