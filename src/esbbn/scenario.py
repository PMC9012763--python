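"""Catchment nutrient scenarios: loads -> concentrations -> threshold classes -> evidence.

The upstream catchment models (a rainfall-runoff model for discharge and a
source-load-apportionment model for annual nutrient exports) are *inputs*
here, consumed as numbers. This module speciates the total-N and total-P
exports using monitored ratios, applies a management scenario as per-
nutrient load multipliers, converts loads to representative annual-average
concentrations (mg/L), classifies them against the regulatory thresholds
stored on the network's abiotic nodes, and emits the hard-evidence set for
inference.

Scenarios:

* ``no_change`` — baseline, all multipliers 1;
* ``riparian`` — vegetated buffer strips at a configurable fraction of
  their maximum trapping efficiency (defaults: 60% nitrate, 70% ammonia,
  30% phosphorus, 50% sediment, at 50% achievement);
* ``livestock_increase`` / ``livestock_decrease`` — a signed stocking
  change (+50% / -20% by default) applied to the pasture-attributed share
  of the export, or an explicit whole-export override where a calibrated
  figure is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

from .inference import EvidenceSet
from .network import NetworkDefinition, NetworkFormatError, NodeSpec

logger = logging.getLogger(__name__)

#: maximum buffer-strip trapping efficiency per constituent (fractions)
DEFAULT_MAX_EFFICIENCY = {
    "nitrate": 0.60,
    "ammonia": 0.70,
    "phosphorus": 0.30,
    "sediment": 0.50,
}

#: network node fed by each catchment-fixed attribute
FIXED_ATTRIBUTE_NODES = (
    "Alkalinity",
    "FlowVariability",
    "Light",
    "RiverReach",
    "CoarseFish",
)

SCENARIO_KINDS = ("no_change", "riparian", "livestock_increase", "livestock_decrease")


@dataclass(frozen=True)
class CatchmentRecord:
    """Annual loads, discharge, speciation ratios and fixed attributes.

    Units: discharge m3/y; total_n, total_p, sediment_load t/y and t/km/y
    respectively; BOD mg O2/L; all fractions in [0, 1].
    ``frac_inorg_as_nitrate`` is the nitrate share of inorganic N (its
    complement is the ammonia share).
    """

    name: str
    discharge: float
    total_n: float
    total_p: float
    frac_n_inorganic: float
    frac_inorg_as_nitrate: float
    frac_p_ortho: float
    pasture_fraction_n: float = 0.0
    pasture_fraction_p: float = 0.0
    sediment_load: float | None = None
    bod: float | None = None
    unionised_fraction: float | None = None
    fixed_states: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.discharge <= 0:
            raise ValueError("discharge must be > 0")
        if self.total_n < 0 or self.total_p < 0:
            raise ValueError("loads must be >= 0")
        for fname in (
            "frac_n_inorganic",
            "frac_inorg_as_nitrate",
            "frac_p_ortho",
            "pasture_fraction_n",
            "pasture_fraction_p",
        ):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{fname} must be in [0, 1], got {v}")
        object.__setattr__(self, "fixed_states", dict(self.fixed_states))


@dataclass(frozen=True)
class Scenario:
    """A management option expressed as load multipliers."""

    kind: str
    stock_change: float = 0.0
    riparian_achievement: float = 0.5
    max_efficiency: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MAX_EFFICIENCY)
    )
    export_override: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if not 0.0 <= self.riparian_achievement <= 1.0:
            raise ValueError("riparian_achievement must be in [0, 1]")
        for k, v in self.max_efficiency.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"max efficiency for {k!r} must be in [0, 1]")
        object.__setattr__(self, "max_efficiency", dict(self.max_efficiency))
        if not self.label:
            object.__setattr__(self, "label", self.kind)

    # -- canonical scenarios ---------------------------------------------

    @staticmethod
    def no_change() -> "Scenario":
        return Scenario(kind="no_change", label="no_change")

    @staticmethod
    def riparian(achievement: float = 0.5) -> "Scenario":
        return Scenario(kind="riparian", riparian_achievement=achievement)

    @staticmethod
    def livestock_increase(stock_change: float = 0.50) -> "Scenario":
        """Intensification: stocking change applied to the pasture share."""
        return Scenario(kind="livestock_increase", stock_change=abs(stock_change))

    @staticmethod
    def livestock_decrease(stock_change: float = 0.20) -> "Scenario":
        """Extensification: stocking reduction applied to the pasture share."""
        return Scenario(kind="livestock_decrease", stock_change=-abs(stock_change))

    @staticmethod
    def livestock_increase_reported() -> "Scenario":
        """Intensification with the reported +18% whole-export change."""
        return Scenario(kind="livestock_increase", stock_change=0.50, export_override=0.18)

    @staticmethod
    def livestock_decrease_reported() -> "Scenario":
        """Extensification with the reported -35% whole-export change."""
        return Scenario(kind="livestock_decrease", stock_change=-0.20, export_override=-0.35)

    @staticmethod
    def from_name(name: str) -> "Scenario":
        factories = {
            "no_change": Scenario.no_change,
            "riparian": Scenario.riparian,
            "livestock_increase": Scenario.livestock_increase,
            "livestock_decrease": Scenario.livestock_decrease,
            "livestock_increase_reported": Scenario.livestock_increase_reported,
            "livestock_decrease_reported": Scenario.livestock_decrease_reported,
        }
        if name not in factories:
            raise ValueError(f"unknown scenario {name!r}; choose from {sorted(factories)}")
        sc = factories[name]()
        return replace(sc, label=name)


@dataclass(frozen=True)
class SpeciatedLoads:
    """Annual loads of the speciated constituents, t/y (as N or as P)."""

    nitrate: float
    ammonia: float
    orthophosphate: float


@dataclass(frozen=True)
class ConcentrationProfile:
    """Annual-average concentrations and their threshold classes."""

    nitrate: float
    ammonia: float
    orthophosphate: float
    bod: float | None
    sediment: float | None
    classes: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "classes", dict(self.classes))


# ---------------------------------------------------------------------------
# operations


def speciate_loads(rec: CatchmentRecord) -> SpeciatedLoads:
    """Split total N into nitrate and ammonia and total P into orthophosphate
    using the monitored average speciation ratios.

    Mass is conserved: nitrate + ammonia = total_n * frac_n_inorganic,
    never more than the total export.
    """
    inorganic = rec.total_n * rec.frac_n_inorganic
    return SpeciatedLoads(
        nitrate=inorganic * rec.frac_inorg_as_nitrate,
        ammonia=inorganic * (1.0 - rec.frac_inorg_as_nitrate),
        orthophosphate=rec.total_p * rec.frac_p_ortho,
    )


def scenario_multipliers(sc: Scenario, rec: CatchmentRecord) -> dict[str, float]:
    """Per-constituent load multipliers for a scenario in a catchment.

    Riparian buffers act on every constituent they can trap, including
    sediment; livestock changes act on the nutrient species only (through
    the pasture-attributed export share, or as a whole-export override
    where one is given).
    """
    keys = ("nitrate", "ammonia", "phosphorus", "sediment")
    if sc.kind == "no_change":
        return {k: 1.0 for k in keys}
    if sc.kind == "riparian":
        return {
            k: 1.0 - sc.riparian_achievement * sc.max_efficiency.get(k, 0.0)
            for k in keys
        }
    # livestock scenarios
    if sc.export_override is not None:
        m = 1.0 + sc.export_override
        mult = {"nitrate": m, "ammonia": m, "phosphorus": m, "sediment": 1.0}
    else:
        mn = 1.0 + sc.stock_change * rec.pasture_fraction_n
        mp = 1.0 + sc.stock_change * rec.pasture_fraction_p
        mult = {"nitrate": mn, "ammonia": mn, "phosphorus": mp, "sediment": 1.0}
    for k, v in mult.items():
        assert v >= 0.0, f"negative multiplier for {k}"
    return mult


def apply_scenario(
    loads: SpeciatedLoads, rec: CatchmentRecord, sc: Scenario
) -> tuple[SpeciatedLoads, float | None]:
    """Adjusted speciated loads and sediment load under a scenario."""
    mult = scenario_multipliers(sc, rec)
    adjusted = SpeciatedLoads(
        nitrate=loads.nitrate * mult["nitrate"],
        ammonia=loads.ammonia * mult["ammonia"],
        orthophosphate=loads.orthophosphate * mult["phosphorus"],
    )
    sediment = None if rec.sediment_load is None else rec.sediment_load * mult["sediment"]
    return adjusted, sediment


def concentration(load: float, discharge: float) -> float:
    """Representative annual-average concentration, mg/L.

    ``load`` in t/y, ``discharge`` in m3/y; 1 t/y over 1e6 m3/y is 1 mg/L.
    """
    if discharge <= 0:
        raise ValueError("discharge must be > 0")
    if load < 0:
        raise ValueError("load must be >= 0")
    return load * 1e6 / discharge


def classify(value: float, node: NodeSpec) -> str:
    """Threshold class of a measured quantity on a node with thresholds.

    Boundary inclusivity follows each interval exactly as declared; a
    value falling in a gap left by strict inequalities on both sides is
    assigned the middle state with a logged warning.
    """
    if not node.thresholds:
        raise ValueError(f"node {node.name!r} has no thresholds")
    for state in node.states:
        iv = node.thresholds.get(state)
        if iv is not None and iv.contains(value):
            return state
    middle = node.states[len(node.states) // 2]
    logger.warning(
        "value %s for node %r falls between strict thresholds; assigning %r",
        value,
        node.name,
        middle,
    )
    return middle


def build_profile(
    rec: CatchmentRecord, sc: Scenario, net: NetworkDefinition
) -> ConcentrationProfile:
    """Scenario-adjusted concentrations plus their threshold classes."""
    loads, sediment = apply_scenario(speciate_loads(rec), rec, sc)
    nitrate = concentration(loads.nitrate, rec.discharge)
    ammonia = concentration(loads.ammonia, rec.discharge)
    ortho = concentration(loads.orthophosphate, rec.discharge)
    classes = {
        "Nitrate": classify(nitrate, net.node("Nitrate")),
        "TotalAmmonia": classify(ammonia, net.node("TotalAmmonia")),
        "Phosphorus": classify(ortho, net.node("Phosphorus")),
    }
    if rec.bod is not None:
        classes["BOD"] = classify(rec.bod, net.node("BOD"))
    if sediment is not None:
        classes["SedimentLoad"] = classify(sediment, net.node("SedimentLoad"))
    return ConcentrationProfile(
        nitrate=nitrate,
        ammonia=ammonia,
        orthophosphate=ortho,
        bod=rec.bod,
        sediment=sediment,
        classes=classes,
    )


def build_evidence(
    profile: ConcentrationProfile, rec: CatchmentRecord, net: NetworkDefinition
) -> EvidenceSet:
    """Hard-evidence set: classified water quality plus catchment-fixed nodes.

    Unionised-ammonia toxicity is classified from total ammonia only when
    the record supplies a speciation fraction; otherwise the node is
    clamped Sub-toxic, the neutral default for well-buffered rivers.
    """
    required = ("Nitrate", "TotalAmmonia", "Phosphorus")
    for node in required:
        if node not in profile.classes:
            raise ValueError(f"profile is missing a classification for {node!r}")
    assignments = dict(profile.classes)

    if "UnionisedAmmonia" in net.node_map:
        if rec.unionised_fraction is not None:
            unionised = profile.ammonia * rec.unionised_fraction
            assignments["UnionisedAmmonia"] = classify(
                unionised, net.node("UnionisedAmmonia")
            )
        else:
            assignments["UnionisedAmmonia"] = "Sub-toxic"

    for node, state in rec.fixed_states.items():
        if node not in net.node_map:
            raise ValueError(f"fixed attribute for unknown node {node!r}")
        assignments[node] = state
    ev = EvidenceSet(assignments)
    ev.validate(net)
    return ev


def run_scenario(
    rec: CatchmentRecord, sc: Scenario, net: NetworkDefinition
) -> tuple[ConcentrationProfile, EvidenceSet]:
    """Convenience: scenario-adjusted profile and its evidence set."""
    profile = build_profile(rec, sc, net)
    return profile, build_evidence(profile, rec, net)


# ---------------------------------------------------------------------------
# catchment config I/O


def load_catchment(path: str | Path) -> CatchmentRecord:
    """Read a catchment record from the YAML config dialect."""
    try:
        doc = yaml.safe_load(Path(path).read_text())
        return CatchmentRecord(
            name=doc["name"],
            discharge=float(doc["discharge_m3_per_year"]),
            total_n=float(doc["total_n_t_per_year"]),
            total_p=float(doc["total_p_t_per_year"]),
            frac_n_inorganic=float(doc["frac_n_inorganic"]),
            frac_inorg_as_nitrate=float(doc["frac_inorg_as_nitrate"]),
            frac_p_ortho=float(doc["frac_p_ortho"]),
            pasture_fraction_n=float(doc.get("pasture_fraction_n", 0.0)),
            pasture_fraction_p=float(doc.get("pasture_fraction_p", 0.0)),
            sediment_load=(
                float(doc["sediment_load_t_per_km_per_year"])
                if doc.get("sediment_load_t_per_km_per_year") is not None
                else None
            ),
            bod=float(doc["bod_mg_per_l"]) if doc.get("bod_mg_per_l") is not None else None,
            unionised_fraction=(
                float(doc["unionised_fraction"])
                if doc.get("unionised_fraction") is not None
                else None
            ),
            fixed_states=doc.get("fixed_states", {}) or {},
        )
    except (yaml.YAMLError, KeyError, TypeError) as exc:
        raise NetworkFormatError(f"malformed catchment config: {exc}") from exc
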