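"""Elicitation-realistic synthetic CPTs, group estimate sets and networks.

The elicited tables behind the demonstration study are unpublished, so the
package ships a generator that emulates the *structure* of the workshop
protocol instead of its values:

* best-case parent combination anchored at a high probability (default
  90%) on the most favourable child state, worst case mirrored;
* probabilities restricted to a coarse grid (default 5%), the resolution
  experts actually used;
* intermediate rows interpolated monotonically in parent favourability,
  so that improving any single parent never worsens the child
  (first-order stochastic dominance);
* between-group disagreement that is largest, in relative terms, for the
  low-probability entries — the pattern the uncertainty analysis of the
  original workshops reported.

All generation is bit-reproducible from (parameters, seed).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .elicitation import GroupEstimateSet
from .network import CPT, NetworkDefinition, NodeSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ElicitationModel:
    """Parameters of the synthetic workshop-protocol CPT generator.

    anchor_prob
        probability placed on the modal outcome of the best- and
        worst-case rows (the ">90%" anchoring step of the protocol).
    grid
        probability resolution; every generated entry is a multiple.
    monotone
        interpolate rows monotonically in parent favourability. When
        off, rows are grid-snapped Dirichlet draws (useful for generic
        random networks).
    """

    anchor_prob: float = 0.9
    grid: float = 0.05
    monotone: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 <= self.anchor_prob <= 1.0:
            raise ValueError("anchor_prob must be in [0.5, 1]")
        steps = 1.0 / self.grid
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("grid must divide 1 evenly")

    @property
    def n_steps(self) -> int:
        return int(round(1.0 / self.grid))


@dataclass(frozen=True)
class GroupNoiseModel:
    """Between-group jitter applied to a base CPT.

    Each expert group's copy of an entry p is drawn uniformly from
    ``p ± h`` with half-width ``h = min(magnitude * b, p, 1 - p)`` where
    ``b`` is ``low_prob_bias`` for entries below ``low_prob_threshold``
    and 1 otherwise. Capping the half-width at min(p, 1-p) keeps the
    interval symmetric inside [0, 1], so each element is unbiased across
    groups while the *relative* range concentrates at low-probability
    entries, as observed between real expert groups.
    """

    n_groups: int = 4
    magnitude: float = 0.05
    low_prob_bias: float = 3.0
    low_prob_threshold: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if self.low_prob_bias < 1:
            raise ValueError("low_prob_bias must be >= 1")


# ---------------------------------------------------------------------------
# grid helpers


def _snap_simplex(row: np.ndarray, n_steps: int) -> np.ndarray:
    """Largest-remainder rounding of a probability vector onto the grid."""
    scaled = row * n_steps
    floor = np.floor(scaled)
    short = int(round(n_steps - floor.sum()))
    remainder = scaled - floor
    order = np.argsort(-remainder, kind="stable")
    floor[order[:short]] += 1
    return floor / n_steps


def _round_grid(x: float, n_steps: int) -> float:
    """Round a scalar to the nearest grid multiple, half away from zero."""
    return np.floor(np.abs(x) * n_steps + 0.5) * np.sign(x) / n_steps


# ---------------------------------------------------------------------------
# monotone CPT generation


def _anchor_row(n: int, modal: int, anchor: float, n_steps: int, rng) -> np.ndarray:
    """A grid row with ``anchor`` on state ``modal`` and the remaining mass
    scattered (at random, in grid quanta) over the adjacent states."""
    row = np.zeros(n)
    row[modal] = anchor
    quanta = int(round((1.0 - anchor) * n_steps))
    others = [i for i in range(n) if i != modal]
    # weight spare mass towards states near the modal one
    weights = np.array([1.0 / (1 + abs(i - modal)) for i in others])
    for _ in range(quanta):
        i = rng.choice(len(others), p=weights / weights.sum())
        row[others[i]] += 1.0 / n_steps
    return row


def _favourability(
    combo_idx: Sequence[int], cards: Sequence[int]
) -> float:
    """Mean normalized parent rank: 0 = all parents at their best state,
    1 = all at their worst."""
    ranks = [
        (i / (c - 1)) if c > 1 else 0.0 for i, c in zip(combo_idx, cards)
    ]
    return float(np.mean(ranks)) if ranks else 0.0


def generate_cpt(
    child: NodeSpec,
    parents: Sequence[NodeSpec],
    em: ElicitationModel,
    parent_orders: Mapping[str, Sequence[str]] | None = None,
) -> CPT:
    """Generate a workshop-protocol-shaped CPT for ``child`` given ``parents``.

    ``parent_orders`` optionally overrides the favourability order of a
    parent *for this CPT only* (favourable state first); by default a
    parent's stored state order is its favourability order. Monotone
    interpolation is done on cumulative distributions and rounded to the
    grid there, which preserves first-order stochastic dominance exactly
    even after rounding.
    """
    rng = np.random.default_rng(em.seed)
    n = child.cardinality
    n_steps = em.n_steps
    orders = []
    for p in parents:
        if parent_orders and p.name in parent_orders:
            order = tuple(parent_orders[p.name])
            if sorted(order) != sorted(p.states):
                raise ValueError(f"favourability order for {p.name!r} must permute its states")
        else:
            order = p.states
        orders.append(order)
    cards = [p.cardinality for p in parents]

    if not em.monotone:
        rows = {}
        for combo in itertools.product(*(p.states for p in parents)):
            rows[combo] = _snap_simplex(rng.dirichlet(np.ones(n)), n_steps)
        return CPT.from_rows(
            child.name, [p.name for p in parents], child.states,
            [p.states for p in parents], rows,
        )

    best = _anchor_row(n, 0, em.anchor_prob, n_steps, rng)
    worst = _anchor_row(n, n - 1, em.anchor_prob, n_steps, rng)
    f_best = np.cumsum(best)
    f_worst = np.cumsum(worst)
    gamma = rng.uniform(0.7, 1.4)  # per-CPT curvature of the response

    rows = {}
    for combo in itertools.product(*(p.states for p in parents)):
        idx = [order.index(s) for order, s in zip(orders, combo)]
        s = _favourability(idx, cards) ** gamma
        cum = (1.0 - s) * f_best + s * f_worst
        cum_grid = np.array([_round_grid(c, n_steps) for c in cum])
        cum_grid[-1] = 1.0
        row = np.diff(np.concatenate([[0.0], cum_grid]))
        rows[combo] = row
    return CPT.from_rows(
        child.name, [p.name for p in parents], child.states,
        [p.states for p in parents], rows,
    )


def generate_prior(spec: NodeSpec, em: ElicitationModel, rng=None) -> np.ndarray:
    rng = np.random.default_rng(em.seed) if rng is None else rng
    return _snap_simplex(rng.dirichlet(np.ones(spec.cardinality)), em.n_steps)


# ---------------------------------------------------------------------------
# group perturbation


def perturb_groups(cpt: CPT, gnm: GroupNoiseModel) -> GroupEstimateSet:
    """Emulate ``n_groups`` expert groups filling the same table.

    Element means across groups equal the base element (the jitter
    interval is symmetric and fully inside [0, 1]); rows are renormalized
    afterwards, which perturbs that identity only at second order.
    """
    rng = np.random.default_rng(gnm.seed)
    groups = []
    for g in range(gnm.n_groups):
        table = cpt.table.copy()
        flat = table.reshape(-1, table.shape[-1])
        for row in flat:
            for j, p in enumerate(row):
                scale = gnm.magnitude * (
                    gnm.low_prob_bias if p < gnm.low_prob_threshold else 1.0
                )
                half = min(scale, p, 1.0 - p)
                if half > 0:
                    row[j] = p + rng.uniform(-half, half)
            total = row.sum()
            if total <= 0:  # pragma: no cover - impossible by construction
                logger.warning("degenerate perturbed row; restoring base")
                row[:] = 1.0 / len(row)
            else:
                row /= total
        groups.append(
            (
                f"G{g + 1}",
                CPT(cpt.child, cpt.parents, cpt.child_states, cpt.parent_states, table),
            )
        )
    return GroupEstimateSet(node=cpt.child, groups=groups)


# ---------------------------------------------------------------------------
# random networks


def generate_network(
    n_nodes: int,
    max_parents: int = 3,
    states_per_node: int | Sequence[int] = (2, 3),
    em: ElicitationModel | None = None,
    seed: int = 0,
) -> NetworkDefinition:
    """Random DAG with monotone CPTs, reproducible from ``seed``.

    Node ``Ni`` may only draw parents among ``N0 .. Ni-1``, which makes
    the index order a topological order. Guarded to the enumeration
    oracle's size limit so every generated network can be cross-checked.
    """
    from .inference import ENUMERATION_MAX_NODES

    if not 1 <= n_nodes <= ENUMERATION_MAX_NODES:
        raise ValueError(f"n_nodes must be in [1, {ENUMERATION_MAX_NODES}]")
    em = em or ElicitationModel()
    rng = np.random.default_rng(seed)
    if isinstance(states_per_node, int):
        choices = [states_per_node]
    else:
        choices = list(states_per_node)

    nodes = []
    for i in range(n_nodes):
        k = int(rng.choice(choices))
        states = tuple(f"s{j}" for j in range(k))
        nodes.append(NodeSpec(name=f"N{i:02d}", states=states))

    edges: list[tuple[str, str]] = []
    cpts = {}
    priors = {}
    for i, spec in enumerate(nodes):
        n_par = int(rng.integers(0, min(i, max_parents) + 1))
        if n_par == 0:
            priors[spec.name] = generate_prior(spec, em, rng)
            continue
        parent_idx = sorted(rng.choice(i, size=n_par, replace=False).tolist())
        parents = [nodes[j] for j in parent_idx]
        edges.extend((p.name, spec.name) for p in parents)
        sub_em = ElicitationModel(
            anchor_prob=em.anchor_prob,
            grid=em.grid,
            monotone=em.monotone,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cpts[spec.name] = generate_cpt(spec, parents, sub_em)
    return NetworkDefinition(nodes=nodes, edges=edges, cpts=cpts, priors=priors)
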