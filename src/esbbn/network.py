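"""Discrete Bayesian belief network: nodes, ordered states, CPTs, and file I/O.

A network is a DAG of discrete variables. Every node carries an explicit,
ordered list of state labels; by package convention the *most favourable*
state comes first (e.g. ``Low`` for a nutrient concentration, ``Good`` for
instream habitat). Non-root nodes own one conditional probability table
(CPT); root nodes own a prior. Probabilities are stored internally as
fractions, but the on-disk YAML dialect uses percentages, matching the way
expert workshops elicit them.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: tolerance on CPT / prior row sums after percent -> fraction conversion
ROW_SUM_TOL = 1e-9

#: separator used for parent-state combination keys in network files
COMBO_SEP = "|"


class NetworkFormatError(ValueError):
    """The file does not parse as the network-definition dialect."""


class NetworkValidationError(ValueError):
    """A structurally invalid network; carries the full diagnostic list."""

    def __init__(self, diagnostics: Sequence["Diagnostic"]):
        self.diagnostics = list(diagnostics)
        super().__init__(
            "invalid network definition:\n"
            + "\n".join(f"  - {d}" for d in self.diagnostics)
        )


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding: which node, which rule, and what happened."""

    node: str
    rule: str
    message: str
    severity: str = "error"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.node}: {self.rule}: {self.message}"


@dataclass(frozen=True)
class Interval:
    """A numeric interval with explicit boundary inclusivity and units.

    Used for the threshold column of abiotic nodes, e.g. phosphorus
    ``High`` is the open interval (0.035, inf) mg/L while nitrate ``Low``
    is the closed ray (-inf, 0.8] mg/L as N.
    """

    lower: float | None = None
    upper: float | None = None
    lower_closed: bool = False
    upper_closed: bool = False
    units: str = ""

    def contains(self, x: float) -> bool:
        if self.lower is not None:
            if x < self.lower or (x == self.lower and not self.lower_closed):
                return False
        if self.upper is not None:
            if x > self.upper or (x == self.upper and not self.upper_closed):
                return False
        return True


@dataclass(frozen=True)
class NodeSpec:
    """A discrete node: name, ordered states (most favourable first),
    free-text description and optional numeric thresholds per state."""

    name: str
    states: tuple[str, ...]
    description: str = ""
    thresholds: Mapping[str, Interval] | None = None
    reconstructed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))

    @property
    def best_state(self) -> str:
        return self.states[0]

    @property
    def worst_state(self) -> str:
        return self.states[-1]

    @property
    def cardinality(self) -> int:
        return len(self.states)


class CPT:
    """Conditional probability table P(child | parents).

    The table is a dense ndarray of shape ``(*parent_cards, n_child_states)``
    whose axes follow the declared parent order, so ``table[i, j, :]`` is the
    distribution of the child given the i-th state of the first parent and
    the j-th state of the second. Rows must sum to 1 within ``ROW_SUM_TOL``.
    """

    __slots__ = ("child", "parents", "child_states", "parent_states", "table")

    def __init__(
        self,
        child: str,
        parents: Sequence[str],
        child_states: Sequence[str],
        parent_states: Sequence[Sequence[str]],
        table: np.ndarray,
    ):
        self.child = child
        self.parents = tuple(parents)
        self.child_states = tuple(child_states)
        self.parent_states = tuple(tuple(s) for s in parent_states)
        expected = tuple(len(s) for s in self.parent_states) + (len(self.child_states),)
        table = np.asarray(table, dtype=float)
        if table.shape != expected:
            raise ValueError(
                f"CPT table for {child!r} has shape {table.shape}, expected {expected}"
            )
        self.table = table

    # -- construction -----------------------------------------------------

    @classmethod
    def from_rows(
        cls,
        child: str,
        parents: Sequence[str],
        child_states: Sequence[str],
        parent_states: Sequence[Sequence[str]],
        rows: Mapping[tuple[str, ...], Sequence[float]],
    ) -> "CPT":
        """Build from a mapping parent-state-combination -> probability row.

        Every combination must appear exactly once; raises ``ValueError``
        naming the child and the offending combination otherwise.
        """
        parent_states = [tuple(s) for s in parent_states]
        cards = tuple(len(s) for s in parent_states)
        table = np.full(cards + (len(child_states),), np.nan)
        combos = set(itertools.product(*parent_states))
        seen = set()
        for combo, row in rows.items():
            combo = tuple(combo)
            if combo not in combos:
                raise ValueError(f"CPT for {child!r}: unknown parent combination {combo}")
            if combo in seen:
                raise ValueError(f"CPT for {child!r}: duplicate parent combination {combo}")
            seen.add(combo)
            idx = tuple(ps.index(s) for ps, s in zip(parent_states, combo))
            table[idx] = np.asarray(row, dtype=float)
        missing = combos - seen
        if missing:
            raise ValueError(
                f"CPT for {child!r}: missing parent combination {sorted(missing)[0]}"
            )
        return cls(child, parents, child_states, parent_states, table)

    # -- access -----------------------------------------------------------

    def combos(self) -> Iterator[tuple[str, ...]]:
        """All parent-state combinations, in axis order."""
        return itertools.product(*self.parent_states)

    def _index(self, combo: Sequence[str]) -> tuple[int, ...]:
        return tuple(ps.index(s) for ps, s in zip(self.parent_states, combo))

    def row(self, combo: Sequence[str]) -> np.ndarray:
        """Probability vector over child states for one parent combination."""
        return self.table[self._index(combo)]

    def prob(self, combo: Sequence[str], child_state: str) -> float:
        return float(self.row(combo)[self.child_states.index(child_state)])

    def with_row(self, combo: Sequence[str], row: Sequence[float]) -> "CPT":
        table = self.table.copy()
        table[self._index(combo)] = np.asarray(row, dtype=float)
        return CPT(self.child, self.parents, self.child_states, self.parent_states, table)

    def substitute(self, combo: Sequence[str], child_state: str, value: float) -> "CPT":
        """Replace one entry and rescale the rest of the row to restore sum 1.

        The remaining entries of the row keep their relative proportions;
        raises ``ValueError`` if the rest of the row carries no mass to
        rescale (the row would not be a distribution).
        """
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"substituted probability {value} outside [0, 1]")
        row = self.row(combo).copy()
        j = self.child_states.index(child_state)
        others = np.delete(row, j)
        rest = others.sum()
        if rest <= 0.0:
            if value == 1.0:
                row[:] = 0.0
                row[j] = 1.0
                return self.with_row(combo, row)
            raise ValueError(
                f"CPT for {self.child!r}, row {tuple(combo)}: cannot rescale a row "
                "with no remaining probability mass"
            )
        scale = (1.0 - value) / rest
        row *= scale
        row[j] = value
        return self.with_row(combo, row)

    def allclose(self, other: "CPT", atol: float = 1e-9) -> bool:
        return (
            self.child == other.child
            and self.parents == other.parents
            and self.child_states == other.child_states
            and self.parent_states == other.parent_states
            and np.allclose(self.table, other.table, atol=atol, rtol=0.0)
        )

    def same_signature(self, other: "CPT") -> bool:
        return (
            self.child == other.child
            and self.parents == other.parents
            and self.child_states == other.child_states
            and self.parent_states == other.parent_states
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CPT({self.child!r} | {', '.join(self.parents) or 'root'})"


@dataclass
class NetworkDefinition:
    """A validated-on-demand network: nodes, edges, CPTs and root priors."""

    nodes: list[NodeSpec]
    edges: list[tuple[str, str]]
    cpts: dict[str, CPT]
    priors: dict[str, np.ndarray]
    #: free-form provenance per edge, e.g. "stated" vs "reconstructed"
    edge_provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    # -- structure --------------------------------------------------------

    @property
    def node_map(self) -> dict[str, NodeSpec]:
        return {n.name: n for n in self.nodes}

    def node(self, name: str) -> NodeSpec:
        try:
            return self.node_map[name]
        except KeyError:
            raise KeyError(f"unknown node {name!r}") from None

    def parents(self, name: str) -> tuple[str, ...]:
        if name in self.cpts:
            return self.cpts[name].parents
        return tuple(p for p, c in self.edges if c == name)

    def children(self, name: str) -> list[str]:
        return [c for p, c in self.edges if p == name]

    def roots(self) -> list[str]:
        children = {c for _, c in self.edges}
        return [n.name for n in self.nodes if n.name not in children]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(n.name for n in self.nodes)
        g.add_edges_from(self.edges)
        return g

    def copy(self) -> "NetworkDefinition":
        return NetworkDefinition(
            nodes=list(self.nodes),
            edges=list(self.edges),
            cpts=dict(self.cpts),
            priors={k: v.copy() for k, v in self.priors.items()},
            edge_provenance=dict(self.edge_provenance),
        )

    def with_cpt(self, cpt: CPT) -> "NetworkDefinition":
        net = self.copy()
        net.cpts[cpt.child] = cpt
        return net

    # -- validation -------------------------------------------------------

    def validate(self) -> list[Diagnostic]:
        """Check every structural invariant; empty list iff the network is valid."""
        diags: list[Diagnostic] = []
        names = [n.name for n in self.nodes]
        for name in {n for n in names if names.count(n) > 1}:
            diags.append(Diagnostic(name, "unique-node-names", "duplicate node name"))
        nm = {n.name: n for n in self.nodes}

        for spec in self.nodes:
            if len(spec.states) < 2:
                diags.append(
                    Diagnostic(spec.name, "state-count", f"{len(spec.states)} state(s), need >=2")
                )
            if len(set(spec.states)) != len(spec.states):
                diags.append(Diagnostic(spec.name, "unique-states", "duplicate state labels"))
            diags.extend(_check_thresholds(spec))

        for p, c in self.edges:
            for end in (p, c):
                if end not in nm:
                    diags.append(
                        Diagnostic(end, "dangling-edge", f"edge ({p} -> {c}) references unknown node")
                    )
        if not diags:
            if not nx.is_directed_acyclic_graph(self.graph()):
                cycle = nx.find_cycle(self.graph())
                diags.append(
                    Diagnostic(cycle[0][0], "acyclicity", f"cycle detected: {cycle}")
                )

        edge_parents = {c: sorted(p for p, cc in self.edges if cc == c) for c in nm}
        for name, spec in nm.items():
            has_parents = bool(edge_parents.get(name))
            if has_parents:
                if name in self.priors:
                    diags.append(Diagnostic(name, "prior-vs-cpt", "non-root node has a prior"))
                if name not in self.cpts:
                    diags.append(Diagnostic(name, "missing-cpt", "non-root node has no CPT"))
            else:
                if name in self.cpts:
                    diags.append(Diagnostic(name, "prior-vs-cpt", "root node has a CPT"))
                if name not in self.priors:
                    diags.append(Diagnostic(name, "missing-prior", "root node has no prior"))

        for name, cpt in self.cpts.items():
            spec = nm.get(name)
            if spec is None:
                diags.append(Diagnostic(name, "unknown-node", "CPT for undeclared node"))
                continue
            if cpt.child_states != spec.states:
                diags.append(
                    Diagnostic(name, "state-mismatch", "CPT child states differ from node states")
                )
            if sorted(cpt.parents) != edge_parents.get(name, []):
                diags.append(
                    Diagnostic(
                        name,
                        "parent-mismatch",
                        f"CPT parents {cpt.parents} do not match edges {tuple(edge_parents.get(name, []))}",
                    )
                )
            for parent, pstates in zip(cpt.parents, cpt.parent_states):
                if parent in nm and nm[parent].states != pstates:
                    diags.append(
                        Diagnostic(
                            name, "parent-state-mismatch", f"states of parent {parent!r} differ"
                        )
                    )
            diags.extend(_check_rows(name, cpt))

        for name, prior in self.priors.items():
            spec = nm.get(name)
            if spec is None:
                diags.append(Diagnostic(name, "unknown-node", "prior for undeclared node"))
                continue
            if len(prior) != len(spec.states):
                diags.append(Diagnostic(name, "prior-length", "prior length differs from state count"))
                continue
            if np.any(prior < 0) or np.any(prior > 1):
                diags.append(Diagnostic(name, "probability-range", "prior entry outside [0, 1]"))
            if abs(float(prior.sum()) - 1.0) > ROW_SUM_TOL:
                diags.append(
                    Diagnostic(name, "row-sum", f"prior sums to {float(prior.sum()):.12f}, not 1")
                )
        for d in diags:
            logger.error("validation: %s", d)
        return diags

    def require_valid(self) -> "NetworkDefinition":
        diags = self.validate()
        if diags:
            raise NetworkValidationError(diags)
        return self


def _check_thresholds(spec: NodeSpec) -> list[Diagnostic]:
    if not spec.thresholds:
        return []
    diags: list[Diagnostic] = []
    for state in spec.thresholds:
        if state not in spec.states:
            diags.append(
                Diagnostic(spec.name, "threshold-state", f"threshold for unknown state {state!r}")
            )
    # intervals must be pairwise disjoint
    items = [(s, iv) for s, iv in spec.thresholds.items() if s in spec.states]
    for (s1, a), (s2, b) in itertools.combinations(items, 2):
        lo = max(
            a.lower if a.lower is not None else -np.inf,
            b.lower if b.lower is not None else -np.inf,
        )
        hi = min(
            a.upper if a.upper is not None else np.inf,
            b.upper if b.upper is not None else np.inf,
        )
        if lo < hi or (lo == hi and a.contains(lo) and b.contains(lo)):
            diags.append(
                Diagnostic(
                    spec.name, "threshold-overlap", f"intervals for {s1!r} and {s2!r} overlap"
                )
            )
    return diags


def _check_rows(name: str, cpt: CPT) -> list[Diagnostic]:
    diags = []
    if np.any(cpt.table < -ROW_SUM_TOL) or np.any(cpt.table > 1 + ROW_SUM_TOL):
        diags.append(Diagnostic(name, "probability-range", "CPT entry outside [0, 1]"))
    sums = cpt.table.sum(axis=-1)
    bad = np.argwhere(np.abs(sums - 1.0) > ROW_SUM_TOL)
    for idx in bad:
        combo = tuple(ps[i] for ps, i in zip(cpt.parent_states, idx))
        diags.append(
            Diagnostic(
                name,
                "row-sum",
                f"row {combo} sums to {float(sums[tuple(idx)]):.12f}, not 1",
            )
        )
    return diags


def validate_network(net: NetworkDefinition) -> list[Diagnostic]:
    """Functional alias for :meth:`NetworkDefinition.validate`."""
    return net.validate()


# ---------------------------------------------------------------------------
# deterministic rule CPTs


def rule_cpt(
    child: str,
    child_states: Sequence[str],
    parents: Sequence[NodeSpec],
    rule: Mapping[tuple[str, ...], str],
) -> CPT:
    """Deterministic CPT: each parent combination maps to a single child state.

    Used for nodes the experts defined by a verbal rule rather than elicited
    probabilities (e.g. overall angling quality is High if either trout or
    salmon angling is Good, Low if both are Poor, Medium otherwise).
    """
    parent_states = [p.states for p in parents]
    rows: dict[tuple[str, ...], list[float]] = {}
    for combo in itertools.product(*parent_states):
        if combo not in rule:
            raise ValueError(f"rule for {child!r} does not cover parent combination {combo}")
        target = rule[combo]
        if target not in child_states:
            raise ValueError(f"rule for {child!r} maps {combo} to unknown state {target!r}")
        row = [0.0] * len(child_states)
        row[list(child_states).index(target)] = 1.0
        rows[combo] = row
    return CPT.from_rows(child, [p.name for p in parents], child_states, parent_states, rows)


# ---------------------------------------------------------------------------
# file I/O (YAML dialect; probabilities as percentages)


def _interval_to_dict(iv: Interval) -> dict:
    d: dict = {}
    if iv.lower is not None:
        d["lower"] = iv.lower
        d["lower_closed"] = iv.lower_closed
    if iv.upper is not None:
        d["upper"] = iv.upper
        d["upper_closed"] = iv.upper_closed
    if iv.units:
        d["units"] = iv.units
    return d


def _interval_from_dict(d: Mapping) -> Interval:
    return Interval(
        lower=d.get("lower"),
        upper=d.get("upper"),
        lower_closed=bool(d.get("lower_closed", False)),
        upper_closed=bool(d.get("upper_closed", False)),
        units=d.get("units", ""),
    )


def _pct(fraction: float) -> float:
    """Fraction -> percentage for file storage, stable under round-trip."""
    return round(float(fraction) * 100.0, 9)


def network_to_dict(net: NetworkDefinition) -> dict:
    doc: dict = {"nodes": [], "edges": [], "priors": {}, "cpts": {}}
    for spec in net.nodes:
        nd: dict = {"name": spec.name, "states": list(spec.states)}
        if spec.description:
            nd["description"] = spec.description
        if spec.thresholds:
            nd["thresholds"] = {s: _interval_to_dict(iv) for s, iv in spec.thresholds.items()}
        if spec.reconstructed:
            nd["reconstructed"] = True
        doc["nodes"].append(nd)
    for p, c in net.edges:
        prov = net.edge_provenance.get((p, c))
        doc["edges"].append([p, c] if prov is None else [p, c, prov])
    for name in net.priors:
        doc["priors"][name] = [_pct(x) for x in net.priors[name]]
    for name, cpt in net.cpts.items():
        rows = {}
        for combo in cpt.combos():
            rows[COMBO_SEP.join(combo)] = [_pct(x) for x in cpt.row(combo)]
        doc["cpts"][name] = {"parents": list(cpt.parents), "rows": rows}
    return doc


def network_from_dict(doc: Mapping) -> NetworkDefinition:
    try:
        nodes = []
        for nd in doc.get("nodes", []):
            thresholds = None
            if nd.get("thresholds"):
                thresholds = {
                    s: _interval_from_dict(d) for s, d in nd["thresholds"].items()
                }
            nodes.append(
                NodeSpec(
                    name=nd["name"],
                    states=tuple(nd["states"]),
                    description=nd.get("description", ""),
                    thresholds=thresholds,
                    reconstructed=bool(nd.get("reconstructed", False)),
                )
            )
        nm = {n.name: n for n in nodes}
        edges: list[tuple[str, str]] = []
        provenance: dict[tuple[str, str], str] = {}
        for entry in doc.get("edges", []):
            p, c = entry[0], entry[1]
            edges.append((p, c))
            if len(entry) > 2:
                provenance[(p, c)] = str(entry[2])
        priors = {
            name: np.asarray(vals, dtype=float) / 100.0
            for name, vals in (doc.get("priors") or {}).items()
        }
        cpts = {}
        for name, block in (doc.get("cpts") or {}).items():
            parents = list(block["parents"])
            for p in parents:
                if p not in nm:
                    raise NetworkFormatError(
                        f"CPT for {name!r} references unknown parent {p!r}"
                    )
            if name not in nm:
                raise NetworkFormatError(f"CPT for undeclared node {name!r}")
            parent_states = [nm[p].states for p in parents]
            rows = {
                tuple(key.split(COMBO_SEP)): [float(x) / 100.0 for x in row]
                for key, row in block["rows"].items()
            }
            cpts[name] = CPT.from_rows(name, parents, nm[name].states, parent_states, rows)
    except NetworkFormatError:
        raise
    except (KeyError, TypeError, AttributeError) as exc:
        raise NetworkFormatError(f"malformed network definition: {exc}") from exc
    return NetworkDefinition(
        nodes=nodes, edges=edges, cpts=cpts, priors=priors, edge_provenance=provenance
    )


def loads_network(text: str) -> NetworkDefinition:
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise NetworkFormatError(f"not parseable as YAML: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise NetworkFormatError("network file must be a YAML mapping")
    return network_from_dict(doc).require_valid()


def load_network(path: str | Path) -> NetworkDefinition:
    """Load and validate a network definition file.

    Raises :class:`NetworkFormatError` on parse problems and
    :class:`NetworkValidationError` (listing node, row and rule) on
    structural violations such as cycles or row sums != 1.
    """
    return loads_network(Path(path).read_text())


def dumps_network(net: NetworkDefinition) -> str:
    return yaml.safe_dump(network_to_dict(net), sort_keys=False, width=100)


def save_network(net: NetworkDefinition, path: str | Path) -> None:
    Path(path).write_text(dumps_network(net))
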