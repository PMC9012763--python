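"""Multi-group expert CPT estimates: aggregation, disagreement, protocol checks.

In the elicitation workshops each table was filled independently by more
than one small expert group, and the definitive CPT is the element-wise
average of the group tables. Between-group disagreement for one CPT
element is summarised by the *relative range*,

    (max - min) / mean

of the group estimates: 0 means exact agreement, 2.00 (for example) means
the spread between groups is twice the mean estimate. Empirically the
largest relative ranges sit at the low-probability entries, which is
reassuring: the entries that drive posteriors are the ones the groups
agree on.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .network import COMBO_SEP, CPT, Diagnostic, NetworkFormatError, NodeSpec

logger = logging.getLogger(__name__)

DEFAULT_HIGH_CUTOFF = 1.0
DEFAULT_LOW_CUTOFF = 0.25


@dataclass
class GroupEstimateSet:
    """Per-group CPT estimates for one node, sharing a single signature."""

    node: str
    groups: list[tuple[str, CPT]]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("need at least one group")
        ref = self.groups[0][1]
        for gid, cpt in self.groups:
            if cpt.child != self.node:
                raise ValueError(f"group {gid!r}: CPT child {cpt.child!r} != node {self.node!r}")
            if not cpt.same_signature(ref):
                raise ValueError(
                    f"group {gid!r}: CPT signature differs from group {self.groups[0][0]!r}"
                )

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def signature(self) -> CPT:
        return self.groups[0][1]

    def estimates(self, combo: Sequence[str], child_state: str) -> np.ndarray:
        """The per-group probability estimates for one CPT element."""
        return np.array([cpt.prob(combo, child_state) for _, cpt in self.groups])


@dataclass
class DisagreementMap:
    """Relative range and qualitative band per CPT element of one node."""

    node: str
    values: dict[tuple[tuple[str, ...], str], float]
    bands: dict[tuple[tuple[str, ...], str], str]
    high_cutoff: float = DEFAULT_HIGH_CUTOFF
    low_cutoff: float = DEFAULT_LOW_CUTOFF

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (combo, state), rr in self.values.items():
            rows.append(
                {
                    "parent_combination": COMBO_SEP.join(combo),
                    "child_state": state,
                    "relative_range": rr,
                    "band": self.bands[(combo, state)],
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def aggregate_groups(ges: GroupEstimateSet) -> CPT:
    """Element-wise mean of the group tables, rows renormalized to sum 1.

    Renormalization is a no-op for exact inputs but guards against tables
    typed as rounded percentages.
    """
    ref = ges.signature
    mean = np.mean([cpt.table for _, cpt in ges.groups], axis=0)
    sums = mean.sum(axis=-1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError(f"aggregated CPT for {ges.node!r} has an all-zero row")
    mean = mean / sums
    return CPT(ref.child, ref.parents, ref.child_states, ref.parent_states, mean)


def relative_range(estimates: Sequence[float]) -> float:
    """Between-group disagreement for one CPT element: (max - min) / mean.

    All-zero estimates are perfect agreement *at* zero; the statistic is
    formally 0/0 there, so 0 is returned with a logged warning.
    """
    est = np.asarray(list(estimates), dtype=float)
    if est.size == 0:
        raise ValueError("need at least one estimate")
    if np.any(est < 0):
        raise ValueError("probability estimates must be >= 0")
    mean = float(est.mean())
    if mean == 0.0:
        logger.warning("relative range of all-zero estimates is undefined; returning 0")
        return 0.0
    return float((est.max() - est.min()) / mean)


def disagreement_map(
    ges: GroupEstimateSet,
    high_cutoff: float = DEFAULT_HIGH_CUTOFF,
    low_cutoff: float = DEFAULT_LOW_CUTOFF,
) -> DisagreementMap:
    """Relative range per CPT element, banded high / intermediate / low.

    An element is banded ``high`` (poor agreement) when its relative range
    is >= ``high_cutoff`` and ``low`` (good agreement) when <= ``low_cutoff``.
    """
    if not high_cutoff >= low_cutoff >= 0:
        raise ValueError("cutoffs must satisfy high_cutoff >= low_cutoff >= 0")
    if ges.n_groups == 1:
        logger.warning(
            "disagreement map for %r from a single group: all ranges are 0", ges.node
        )
    ref = ges.signature
    values: dict[tuple[tuple[str, ...], str], float] = {}
    bands: dict[tuple[tuple[str, ...], str], str] = {}
    for combo in ref.combos():
        for state in ref.child_states:
            rr = relative_range(ges.estimates(combo, state))
            key = (tuple(combo), state)
            values[key] = rr
            if rr >= high_cutoff:
                bands[key] = "high"
            elif rr <= low_cutoff:
                bands[key] = "low"
            else:
                bands[key] = "intermediate"
    return DisagreementMap(ges.node, values, bands, high_cutoff, low_cutoff)


# ---------------------------------------------------------------------------
# workshop fill-protocol checks


def check_protocol(
    cpt: CPT,
    parent_orders: Mapping[str, Sequence[str]] | None = None,
    anchor_prob: float = 0.9,
    grid: float = 0.05,
    tol: float = 1e-9,
) -> list[Diagnostic]:
    """Advisory diagnostics against the workshop fill protocol.

    Checks, per the elicitation procedure: the best-case row anchors at
    least ``anchor_prob`` on the most favourable child state (and the
    worst-case row symmetrically); every probability sits on the ``grid``;
    and P(best child state) is monotone non-increasing along any single
    parent's favourability sweep. ``parent_orders`` gives the favourable-
    first state order per parent where it differs from the stored order.
    """
    diags: list[Diagnostic] = []
    orders = []
    for pname, pstates in zip(cpt.parents, cpt.parent_states):
        if parent_orders and pname in parent_orders:
            orders.append(tuple(parent_orders[pname]))
        else:
            orders.append(pstates)

    best_combo = tuple(o[0] for o in orders)
    worst_combo = tuple(o[-1] for o in orders)
    if cpt.prob(best_combo, cpt.child_states[0]) < anchor_prob - tol:
        diags.append(
            Diagnostic(
                cpt.child,
                "anchor-best",
                f"best-case row {best_combo} puts "
                f"{cpt.prob(best_combo, cpt.child_states[0]):.2f} < {anchor_prob} "
                "on the most favourable state",
                severity="warning",
            )
        )
    if cpt.prob(worst_combo, cpt.child_states[-1]) < anchor_prob - tol:
        diags.append(
            Diagnostic(
                cpt.child,
                "anchor-worst",
                f"worst-case row {worst_combo} puts "
                f"{cpt.prob(worst_combo, cpt.child_states[-1]):.2f} < {anchor_prob} "
                "on the least favourable state",
                severity="warning",
            )
        )

    n_steps = round(1.0 / grid)
    for combo in cpt.combos():
        for state, p in zip(cpt.child_states, cpt.row(combo)):
            if abs(p * n_steps - round(p * n_steps)) > tol * n_steps:
                diags.append(
                    Diagnostic(
                        cpt.child,
                        "grid",
                        f"P({state} | {combo}) = {p:.4f} is off the {grid:.0%} grid",
                        severity="warning",
                    )
                )

    # monotone sweep: fix all other parents, worsen one parent at a time
    best_state_idx = 0
    for k, (pname, order) in enumerate(zip(cpt.parents, orders)):
        other_states = [o for i, o in enumerate(orders) if i != k]
        for context in itertools.product(*other_states):
            probs = []
            for s in order:
                combo = list(context)
                combo.insert(k, s)
                probs.append(cpt.row(combo)[best_state_idx])
            for a, b in zip(probs, probs[1:]):
                if b > a + tol:
                    diags.append(
                        Diagnostic(
                            cpt.child,
                            "monotone",
                            f"P(best state) increases as parent {pname!r} worsens "
                            f"(context {context})",
                            severity="warning",
                        )
                    )
                    break
    return diags


# ---------------------------------------------------------------------------
# group-estimate file I/O (same YAML dialect as the network file)


def load_groups(path: str | Path, node_spec: NodeSpec, parent_specs: Sequence[NodeSpec]) -> GroupEstimateSet:
    """Read a multi-group estimate file: ``node``, then one CPT block per
    group under ``groups``, probabilities as percentages."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
        node = doc["node"]
        blocks = doc["groups"]
    except (yaml.YAMLError, KeyError, TypeError) as exc:
        raise NetworkFormatError(f"malformed group-estimate file: {exc}") from exc
    if node != node_spec.name:
        raise ValueError(f"file is for node {node!r}, expected {node_spec.name!r}")
    pmap = {p.name: p for p in parent_specs}
    groups = []
    for gid, block in blocks.items():
        parents = list(block["parents"])
        parent_states = [pmap[p].states for p in parents]
        rows = {
            tuple(key.split(COMBO_SEP)): [float(x) / 100.0 for x in row]
            for key, row in block["rows"].items()
        }
        groups.append(
            (str(gid), CPT.from_rows(node, parents, node_spec.states, parent_states, rows))
        )
    return GroupEstimateSet(node=node, groups=groups)


def save_groups(ges: GroupEstimateSet, path: str | Path) -> None:
    doc: dict = {"node": ges.node, "groups": {}}
    for gid, cpt in ges.groups:
        rows = {
            COMBO_SEP.join(combo): [round(float(x) * 100.0, 9) for x in cpt.row(combo)]
            for combo in cpt.combos()
        }
        doc["groups"][gid] = {"parents": list(cpt.parents), "rows": rows}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, width=100))
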