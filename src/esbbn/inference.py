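"""Exact inference on the discrete network.

Two independent routes are provided:

* :func:`posterior` — variable elimination with a min-fill elimination
  order (deterministic lexicographic tie-break), the production path;
* :func:`enumerate_joint` — brute-force summation of the full joint,
  guarded to small networks, used as the independent oracle in tests.

Evidence is hard evidence (clamping): the catchment and management
choices enter the model as observed states of root nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .network import NetworkDefinition

#: node-count guard for the enumeration oracle
ENUMERATION_MAX_NODES = 12

_ZERO = 1e-300


class InconsistentEvidenceError(ValueError):
    """The observed evidence has probability zero under the model."""


@dataclass(frozen=True)
class EvidenceSet:
    """Hard evidence: node name -> observed state label."""

    assignments: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))

    def validate(self, net: NetworkDefinition) -> None:
        for node, state in self.assignments.items():
            spec = net.node(node)  # raises KeyError for unknown node
            if state not in spec.states:
                raise ValueError(
                    f"evidence {node}={state!r}: state not in {spec.states}"
                )

    def items(self):
        return self.assignments.items()

    def __contains__(self, node: str) -> bool:
        return node in self.assignments

    def __len__(self) -> int:
        return len(self.assignments)


@dataclass(frozen=True)
class PosteriorResult:
    """Posterior distribution of one node given an evidence set."""

    node: str
    states: tuple[str, ...]
    distribution: np.ndarray
    evidence: EvidenceSet

    def __post_init__(self) -> None:
        dist = np.asarray(self.distribution, dtype=float)
        object.__setattr__(self, "distribution", dist)
        object.__setattr__(self, "states", tuple(self.states))

    def prob(self, state: str) -> float:
        return float(self.distribution[self.states.index(state)])

    def as_dict(self) -> dict[str, float]:
        return {s: float(p) for s, p in zip(self.states, self.distribution)}


# ---------------------------------------------------------------------------
# factors


class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, variables: tuple[str, ...], table: np.ndarray):
        self.vars = variables
        self.table = table


def _multiply(a: _Factor, b: _Factor) -> _Factor:
    out_vars = a.vars + tuple(v for v in b.vars if v not in a.vars)
    a_shape = a.table.shape + (1,) * (len(out_vars) - len(a.vars))
    perm = [b.vars.index(v) if v in b.vars else None for v in out_vars]
    b_axes = [p for p in perm if p is not None]
    b_table = np.transpose(b.table, b_axes) if b.vars else b.table
    b_shape = tuple(
        b_table.shape[b_axes.index(b.vars.index(v))] if v in b.vars else 1
        for v in out_vars
    )
    return _Factor(out_vars, a.table.reshape(a_shape) * b_table.reshape(b_shape))


def _sum_out(f: _Factor, var: str) -> _Factor:
    axis = f.vars.index(var)
    return _Factor(
        f.vars[:axis] + f.vars[axis + 1 :], f.table.sum(axis=axis)
    )


def _network_factors(net: NetworkDefinition) -> list[_Factor]:
    factors = []
    for name, prior in net.priors.items():
        factors.append(_Factor((name,), np.asarray(prior, dtype=float)))
    for name, cpt in net.cpts.items():
        factors.append(_Factor(cpt.parents + (name,), cpt.table))
    return factors


def _reduce_evidence(
    factors: list[_Factor], net: NetworkDefinition, evidence: EvidenceSet
) -> list[_Factor]:
    reduced = []
    for f in factors:
        table = f.table
        variables = list(f.vars)
        for node, state in evidence.items():
            if node in variables:
                axis = variables.index(node)
                idx = net.node(node).states.index(state)
                table = np.take(table, idx, axis=axis)
                variables.pop(axis)
        reduced.append(_Factor(tuple(variables), table))
    return reduced


def _min_fill_order(factors: Sequence[_Factor], keep: set[str]) -> list[str]:
    """Min-fill elimination order over all factor variables not in ``keep``.

    Ties are broken lexicographically so runs are reproducible.
    """
    adj: dict[str, set[str]] = {}
    for f in factors:
        for v in f.vars:
            adj.setdefault(v, set()).update(u for u in f.vars if u != v)
    to_eliminate = sorted(v for v in adj if v not in keep)
    order = []
    while to_eliminate:
        best = None
        best_fill = None
        for v in to_eliminate:
            nbrs = [u for u in adj[v] if u in adj]
            fill = sum(
                1
                for i, u in enumerate(nbrs)
                for w in nbrs[i + 1 :]
                if w not in adj[u]
            )
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        assert best is not None
        order.append(best)
        nbrs = [u for u in adj[best] if u in adj]
        for i, u in enumerate(nbrs):
            for w in nbrs[i + 1 :]:
                adj[u].add(w)
                adj[w].add(u)
        for u in nbrs:
            adj[u].discard(best)
        del adj[best]
        to_eliminate.remove(best)
    return order


def _eliminate(factors: list[_Factor], order: Sequence[str]) -> list[_Factor]:
    factors = list(factors)
    for var in order:
        involved = [f for f in factors if var in f.vars]
        factors = [f for f in factors if var not in f.vars]
        if not involved:
            continue
        prod = involved[0]
        for f in involved[1:]:
            prod = _multiply(prod, f)
        factors.append(_sum_out(prod, var))
    return factors


# ---------------------------------------------------------------------------
# public API


def posterior(
    net: NetworkDefinition,
    evidence: EvidenceSet | Mapping[str, str],
    query: str,
) -> PosteriorResult:
    """Exact posterior P(query | evidence) by variable elimination.

    Raises :class:`InconsistentEvidenceError` if the evidence has zero
    probability, and ``KeyError`` for an unknown query node.
    """
    if not isinstance(evidence, EvidenceSet):
        evidence = EvidenceSet(evidence)
    evidence.validate(net)
    spec = net.node(query)

    if query in evidence:
        # posterior of an observed node is a point mass, provided the
        # evidence as a whole is possible
        z = _evidence_probability(net, evidence)
        if z <= _ZERO:
            raise InconsistentEvidenceError("evidence has probability 0")
        dist = np.zeros(len(spec.states))
        dist[spec.states.index(evidence.assignments[query])] = 1.0
        return PosteriorResult(query, spec.states, dist, evidence)

    factors = _reduce_evidence(_network_factors(net), net, evidence)
    order = _min_fill_order(factors, keep={query})
    remaining = _eliminate(factors, order)
    result = _Factor((), np.array(1.0))
    for f in remaining:
        result = _multiply(result, f)
    if result.vars != (query,):
        # query variable appeared in no factor slice (fully disconnected)
        result = _multiply(result, _Factor((query,), np.ones(len(spec.states))))
        result.table = result.table.reshape(len(spec.states))
    z = float(result.table.sum())
    if z <= _ZERO:
        raise InconsistentEvidenceError("evidence has probability 0")
    return PosteriorResult(query, spec.states, result.table / z, evidence)


def _evidence_probability(net: NetworkDefinition, evidence: EvidenceSet) -> float:
    factors = _reduce_evidence(_network_factors(net), net, evidence)
    order = _min_fill_order(factors, keep=set())
    remaining = _eliminate(factors, order)
    z = 1.0
    for f in remaining:
        z *= float(np.asarray(f.table).sum())
    return z


def posterior_all(
    net: NetworkDefinition,
    evidence: EvidenceSet | Mapping[str, str],
    queries: Sequence[str],
) -> list[PosteriorResult]:
    """Posteriors for several query nodes under the same evidence."""
    return [posterior(net, evidence, q) for q in queries]


def enumerate_joint(
    net: NetworkDefinition,
    evidence: EvidenceSet | Mapping[str, str],
    query: str,
) -> PosteriorResult:
    """Oracle: posterior by summing the explicitly materialised joint.

    Same contract as :func:`posterior`; guarded to networks of at most
    ``ENUMERATION_MAX_NODES`` nodes to avoid exponential blow-up.
    """
    if len(net.nodes) > ENUMERATION_MAX_NODES:
        raise ValueError(
            f"enumeration oracle limited to {ENUMERATION_MAX_NODES} nodes, "
            f"got {len(net.nodes)}"
        )
    if not isinstance(evidence, EvidenceSet):
        evidence = EvidenceSet(evidence)
    evidence.validate(net)
    spec = net.node(query)

    order = [n.name for n in net.nodes]
    axis = {name: i for i, name in enumerate(order)}
    cards = [len(net.node(n).states) for n in order]
    joint = np.ones([1] * len(order))
    for f in _network_factors(net):
        shape = [1] * len(order)
        perm = sorted(range(len(f.vars)), key=lambda i: axis[f.vars[i]])
        table = np.transpose(f.table, perm)
        for v in f.vars:
            shape[axis[v]] = cards[axis[v]]
        joint = joint * table.reshape(shape)

    for node, state in evidence.items():
        a = axis[node]
        idx = net.node(node).states.index(state)
        mask_shape = [1] * len(order)
        mask_shape[a] = cards[a]
        mask = np.zeros(cards[a])
        mask[idx] = 1.0
        joint = joint * mask.reshape(mask_shape)

    other_axes = tuple(a for n, a in axis.items() if n != query)
    marginal = joint.sum(axis=other_axes)
    z = float(marginal.sum())
    if z <= _ZERO:
        raise InconsistentEvidenceError("evidence has probability 0")
    return PosteriorResult(query, spec.states, marginal / z, evidence)
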