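"""Brute-force exact inference by enumeration of the factorized joint.

The network defines a unique joint distribution as the product of each
node's conditional table given its parents; on small networks every
marginal and posterior can be computed exactly by summing that product over
all configurations. This module is the independent reference the engine is
tested against — it shares no code path with the engine's closed forms —
and is deliberately capped at 10^6 joint configurations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import OracleScopeError, StructureError
from .levels import LevelDistribution, N_LEVELS, SeverityLevel
from .model import AdviceSpec, ContextProfile, ModelSpec

__all__ = ["OracleNode", "EnumerationOracle", "dimension_oracle", "advice_oracle_score"]

_MAX_CONFIGS = 10**6


@dataclass(frozen=True)
class OracleNode:
    """A discrete node: cardinality and P(node | parent values) as a callable."""

    name: str
    cardinality: int
    parents: tuple[str, ...]
    cpd: Callable[[tuple[int, ...]], Sequence[float]]


class EnumerationOracle:
    """Exact posteriors on a small discrete network by exhaustive summation."""

    def __init__(self, nodes: Sequence[OracleNode]):
        self.nodes = tuple(nodes)
        self._order = [n.name for n in self.nodes]
        known = set(self._order)
        for n in self.nodes:
            missing = set(n.parents) - known
            if missing:
                raise StructureError(f"node {n.name!r}: unknown parents {sorted(missing)}")
        size = math.prod(n.cardinality for n in self.nodes)
        if size > _MAX_CONFIGS:
            raise OracleScopeError(f"joint state space {size} exceeds {_MAX_CONFIGS}")

    def _joint(self, config: Mapping[str, int]) -> float:
        p = 1.0
        for n in self.nodes:
            parent_vals = tuple(config[par] for par in n.parents)
            p *= float(n.cpd(parent_vals)[config[n.name]])
            if p == 0.0:
                return 0.0
        return p

    def posterior(self, query: str, evidence: Mapping[str, int] | None = None) -> np.ndarray:
        """P(query | evidence) by summing the joint over all configurations."""
        evidence = dict(evidence or {})
        free = [n for n in self.nodes if n.name not in evidence and n.name != query]
        qcard = next(n.cardinality for n in self.nodes if n.name == query)
        out = np.zeros(qcard)
        for qval in range(qcard):
            for combo in itertools.product(*(range(n.cardinality) for n in free)):
                config = dict(evidence)
                config[query] = qval
                config.update({n.name: v for n, v in zip(free, combo)})
                out[qval] += self._joint(config)
        total = out.sum()
        if total == 0.0:
            raise ZeroDivisionError("evidence has zero probability under the joint")
        return out / total


def dimension_oracle(
    model: ModelSpec,
    dimension_id: str,
    prior: LevelDistribution,
) -> EnumerationOracle:
    """The one-dimension sub-network: an IF root plus its question nodes."""
    dim = model.dimension(dimension_id)
    nodes = [OracleNode("IF", N_LEVELS, (), lambda _p, pr=prior: pr.probs)]
    for qid in dim.question_ids:
        q = model.question(qid)
        nodes.append(
            OracleNode(qid, N_LEVELS, ("IF",), lambda pv, lik=q.likelihood: lik[pv[0]])
        )
    return EnumerationOracle(nodes)


def advice_oracle_score(
    advice: AdviceSpec, cs_dists: Mapping[str, LevelDistribution]
) -> float:
    """P(advice relevant) by enumerating all 4^p parent configurations.

    Builds the full noisy-OR conditional table row by row — the expansion
    the noisy-OR parameterization avoids storing — and sums it against the
    independent parent severity distributions.
    """
    parents = advice.parent_dimension_ids
    nodes = [
        OracleNode(pd, N_LEVELS, (), lambda _p, d=cs_dists[pd]: d.probs) for pd in parents
    ]

    def noisy_or_row(parent_vals: tuple[int, ...]) -> np.ndarray:
        survive = 1.0 - advice.leak
        for pd, val in zip(parents, parent_vals):
            survive *= 1.0 - advice.activation_for(pd, SeverityLevel(val))
        return np.array([survive, 1.0 - survive])

    nodes.append(OracleNode("advice", 2, tuple(parents), noisy_or_row))
    return float(EnumerationOracle(nodes).posterior("advice")[1])
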