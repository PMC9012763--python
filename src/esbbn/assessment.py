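"""Ecosystem-service outcomes: expected indicator values, change metrics,
and the min/max CPT sensitivity scan.

Each ES node's posterior class distribution is collapsed to an expected
indicator value via a class-value map (e.g. the angling classes High /
Medium / Low stand for typically 5 / 2 / 1 catchable fish per 20 m reach;
the mayfly classes for 8 / 6 / 3 / 1 / 0 species). Scenario outcomes are
reported as the expected value, the absolute change from the baseline
scenario and the change relative to the baseline, rounded the way the
demonstration-study tables print them (change to 2 d.p.; relative change
to a whole percent for angling, one decimal for mayfly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import EvidenceSet, posterior_all
from .network import NetworkDefinition
from .scenario import CatchmentRecord, Scenario, run_scenario


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (the convention of the printed tables;
    Python's builtin banker's rounding differs on exact halves)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(f"{x:.9f}").quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassValueMap:
    """Representative indicator quantity per state of one ES node."""

    node: str
    values: Mapping[str, float]
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))


#: default class-value maps for the four ES indicator nodes. Angling and
#: mayfly quantities are the published per-class values; dipper and algal
#: scum have no published quantities, so ordinal scores (2/1/0) are used.
DEFAULT_CLASS_VALUES: dict[str, ClassValueMap] = {
    "Angling": ClassValueMap(
        "Angling", {"High": 5.0, "Medium": 2.0, "Low": 1.0}, units="fish per 20 m reach"
    ),
    "MayflyRichness": ClassValueMap(
        "MayflyRichness",
        {"8 species": 8.0, "6 species": 6.0, "3 species": 3.0, "1 species": 1.0, "none": 0.0},
        units="species",
    ),
    "Dipper": ClassValueMap(
        "Dipper", {"High": 2.0, "Medium": 1.0, "Low": 0.0}, units="ordinal score"
    ),
    "AlgalScum": ClassValueMap(
        "AlgalScum", {"Absent": 2.0, "Occasional": 1.0, "Extensive": 0.0}, units="ordinal score"
    ),
}

#: decimals used when printing relative change, per indicator convention
RELATIVE_CHANGE_DECIMALS = {"Angling": 0, "MayflyRichness": 1, "Dipper": 1, "AlgalScum": 1}


@dataclass(frozen=True)
class ESOutcome:
    """One (ES node, scenario) result row."""

    node: str
    scenario: str
    states: tuple[str, ...]
    distribution_pct: tuple[float, ...]
    expected: float
    change: float | None = None
    relative_change: float | None = None

    def as_row(self) -> dict:
        row = {
            "node": self.node,
            "scenario": self.scenario,
            "expected": self.expected,
            "change": self.change,
            "relative_change_pct": self.relative_change,
        }
        for s, p in zip(self.states, self.distribution_pct):
            row[f"P({s}) %"] = p
        return row


@dataclass(frozen=True)
class SensitivityRecord:
    """One uncertain CPT element and, after scanning, its per-ES impact.

    ``low``/``high`` are the lowest and highest group estimates of the
    element; ``es_deltas`` holds 100*(E_high - E_low)/E_baseline per ES
    node, rounded to two decimals.
    """

    node: str
    parent_combo: tuple[str, ...]
    child_state: str
    low: float
    high: float
    es_deltas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.low <= self.high <= 1.0:
            raise ValueError("need 0 <= low <= high <= 1")
        object.__setattr__(self, "parent_combo", tuple(self.parent_combo))
        object.__setattr__(self, "es_deltas", dict(self.es_deltas))


# ---------------------------------------------------------------------------
# operations


def expected_value(
    probs: Sequence[float],
    states: Sequence[str],
    cvm: ClassValueMap,
    percent: bool = True,
) -> float:
    """Expected indicator value sum(p_i * v_i), unrounded.

    ``probs`` are percentages by default (the tables' convention; printed
    rows are used as-is, divided by 100, without renormalizing rounding
    residue). State labels must match the class-value map exactly.
    """
    if set(states) - set(cvm.values):
        missing = sorted(set(states) - set(cvm.values))
        raise ValueError(f"class-value map for {cvm.node!r} lacks values for {missing}")
    scale = 100.0 if percent else 1.0
    return float(sum((p / scale) * cvm.values[s] for p, s in zip(probs, states)))


def change_metrics(
    expected_scenario: float,
    expected_baseline: float,
    relative_ndigits: int = 0,
) -> tuple[float, float | None]:
    """(change, relative change %) vs baseline, computed at full precision
    then rounded: change to 2 d.p., relative to ``relative_ndigits``.

    A non-positive baseline leaves the relative change undefined (None).
    """
    change = round_half_up(expected_scenario - expected_baseline, 2)
    if expected_baseline <= 0:
        return change, None
    rel = 100.0 * (expected_scenario - expected_baseline) / expected_baseline
    return change, round_half_up(rel, relative_ndigits)


def assess_distribution(
    node: str,
    states: Sequence[str],
    probs_pct: Sequence[float],
    scenario: str,
    cvm: ClassValueMap,
    baseline_expected: float | None = None,
    relative_ndigits: int = 0,
) -> ESOutcome:
    e = expected_value(probs_pct, states, cvm, percent=True)
    if baseline_expected is None:
        return ESOutcome(node, scenario, tuple(states), tuple(probs_pct), e)
    change, rel = change_metrics(e, baseline_expected, relative_ndigits)
    return ESOutcome(node, scenario, tuple(states), tuple(probs_pct), e, change, rel)


def run_assessment(
    net: NetworkDefinition,
    catchment: CatchmentRecord,
    scenarios: Sequence[Scenario],
    cvms: Mapping[str, ClassValueMap] | None = None,
    es_nodes: Sequence[str] | None = None,
    baseline_kind: str = "no_change",
) -> list[ESOutcome]:
    """One ESOutcome per (ES node, scenario); baseline rows carry no change.

    The scenario list must include the baseline (`no_change`) scenario.
    """
    cvms = dict(DEFAULT_CLASS_VALUES) if cvms is None else dict(cvms)
    es_nodes = list(cvms) if es_nodes is None else list(es_nodes)
    baselines = [sc for sc in scenarios if sc.kind == baseline_kind]
    if not baselines:
        raise ValueError(
            f"scenario list must include the baseline {baseline_kind!r} scenario"
        )
    baseline = baselines[0]

    def distributions(sc: Scenario) -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
        _, evidence = run_scenario(catchment, sc, net)
        out = {}
        for res in posterior_all(net, evidence, es_nodes):
            out[res.node] = (res.states, res.distribution * 100.0)
        return out

    base_dists = distributions(baseline)
    base_expected = {
        node: expected_value(probs, states, cvms[node], percent=True)
        for node, (states, probs) in base_dists.items()
    }

    outcomes: list[ESOutcome] = []
    for sc in scenarios:
        dists = base_dists if sc is baseline else distributions(sc)
        for node in es_nodes:
            states, probs = dists[node]
            outcomes.append(
                assess_distribution(
                    node,
                    states,
                    tuple(float(p) for p in probs),
                    sc.label,
                    cvms[node],
                    baseline_expected=None if sc is baseline else base_expected[node],
                    relative_ndigits=RELATIVE_CHANGE_DECIMALS.get(node, 1),
                )
            )
    return outcomes


def outcomes_to_frame(outcomes: Sequence[ESOutcome]) -> pd.DataFrame:
    return pd.DataFrame([o.as_row() for o in outcomes])


# ---------------------------------------------------------------------------
# min/max sensitivity scan


def sensitivity_scan(
    net: NetworkDefinition,
    records: Sequence[SensitivityRecord],
    evidence: EvidenceSet | Mapping[str, str],
    es_nodes: Sequence[str] | None = None,
    cvms: Mapping[str, ClassValueMap] | None = None,
) -> list[SensitivityRecord]:
    """Re-run the network with each uncertain CPT element at its lowest and
    highest group estimate and report the per-ES swing.

    For each record the targeted entry is substituted (the rest of its row
    rescaled proportionally to restore sum 1) first with ``low``, then with
    ``high``; the reported delta per ES node is 100*(E_high - E_low) /
    E_baseline, rounded to two decimals. Records with ``low == high``
    therefore yield exactly 0.00, and swapping low and high flips signs.
    """
    cvms = dict(DEFAULT_CLASS_VALUES) if cvms is None else dict(cvms)
    es_nodes = list(cvms) if es_nodes is None else list(es_nodes)

    def expectations(network: NetworkDefinition) -> dict[str, float]:
        out = {}
        for res in posterior_all(network, evidence, es_nodes):
            out[res.node] = expected_value(
                res.distribution, res.states, cvms[res.node], percent=False
            )
        return out

    base = expectations(net)
    results = []
    for rec in records:
        cpt = net.cpts.get(rec.node)
        if cpt is None:
            raise KeyError(f"no CPT for node {rec.node!r}")
        cpt.row(rec.parent_combo)  # raises for unknown combination
        e_low = expectations(net.with_cpt(cpt.substitute(rec.parent_combo, rec.child_state, rec.low)))
        e_high = expectations(net.with_cpt(cpt.substitute(rec.parent_combo, rec.child_state, rec.high)))
        deltas = {}
        for node in es_nodes:
            if base[node] <= 0:
                deltas[node] = float("nan")
                continue
            deltas[node] = round_half_up(
                100.0 * (e_high[node] - e_low[node]) / base[node], 2
            )
        results.append(
            SensitivityRecord(
                node=rec.node,
                parent_combo=rec.parent_combo,
                child_state=rec.child_state,
                low=rec.low,
                high=rec.high,
                es_deltas=deltas,
            )
        )
    return results


def sensitivity_to_frame(records: Sequence[SensitivityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "node": r.node,
            "parent_combination": "|".join(r.parent_combo),
            "child_state": r.child_state,
            # probabilities reported at three significant digits
            "lowest_prob": float(f"{r.low:.3g}"),
            "highest_prob": float(f"{r.high:.3g}"),
        }
        for es, d in r.es_deltas.items():
            row[f"delta_{es}_pct"] = d
        rows.append(row)
    return pd.DataFrame(rows)
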