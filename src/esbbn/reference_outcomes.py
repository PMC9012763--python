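"""Published demonstration outcomes for the three Irish test catchments.

These are the printed scenario results of the demonstration study on the
Dodder, Moy and Suir rivers: per (catchment, management option), the
posterior class probabilities (%) of the angling and mayfly-richness ES
nodes together with the expected indicator value, the absolute change
from the no-change baseline, and the relative (%) change. The posterior
probability columns are *inputs* here (the expert CPTs behind them are
unpublished); the package's arithmetic — expected value, change and
relative change under the stated rounding — must reproduce the remaining
columns exactly, and the regression suite asserts that row by row.

Conventions encoded by the tables themselves:

* probability columns are used as printed (divided by 100, not
  renormalized, even where rounding leaves a row summing to <100%);
* expected values print to 1 d.p., changes to 2 d.p.;
* relative change prints as a whole percent for angling and to 1 d.p.
  for mayfly richness.
"""

from __future__ import annotations

from dataclasses import dataclass

from .assessment import DEFAULT_CLASS_VALUES, ClassValueMap

ANGLING_STATES = ("High", "Medium", "Low")
MAYFLY_STATES = ("8 species", "6 species", "3 species", "1 species", "none")

BASELINE = "no_change"


@dataclass(frozen=True)
class ReferenceRow:
    """One printed row: probabilities in % plus the printed derived columns."""

    catchment: str
    scenario: str
    probs_pct: tuple[float, ...]
    expected: float
    change: float | None
    relative_change: float | None


#: angling outcomes (classes valued at 5 / 2 / 1 catchable fish)
ANGLING_ROWS: tuple[ReferenceRow, ...] = (
    ReferenceRow("Dodder", "no_change", (41.8, 18.5, 39.8), 2.9, None, None),
    ReferenceRow("Dodder", "riparian", (46.5, 17.9, 35.6), 3.0, 0.18, 6),
    ReferenceRow("Dodder", "livestock_increase", (38.7, 18.7, 42.6), 2.7, -0.12, -4),
    ReferenceRow("Dodder", "livestock_decrease", (43.2, 18.2, 38.6), 2.9, 0.05, 2),
    ReferenceRow("Moy", "no_change", (40.6, 18.1, 41.2), 2.8, None, None),
    ReferenceRow("Moy", "riparian", (47.8, 17.9, 34.3), 3.1, 0.29, 10),
    ReferenceRow("Moy", "livestock_increase", (37.6, 18.0, 44.4), 2.7, -0.12, -4),
    ReferenceRow("Moy", "livestock_decrease", (43.7, 18.1, 38.1), 2.9, 0.12, 4),
    ReferenceRow("Suir", "no_change", (38.4, 18.1, 43.5), 2.7, None, None),
    ReferenceRow("Suir", "riparian", (45.6, 17.9, 36.5), 3.0, 0.29, 11),
    ReferenceRow("Suir", "livestock_increase", (34.9, 17.9, 47.2), 2.6, -0.14, -5),
    ReferenceRow("Suir", "livestock_decrease", (40.9, 18.1, 40.9), 2.8, 0.10, 4),
)

#: mayfly-richness outcomes (classes valued at 8 / 6 / 3 / 1 / 0 species)
MAYFLY_ROWS: tuple[ReferenceRow, ...] = (
    ReferenceRow("Dodder", "no_change", (13.8, 16.1, 23.6, 9.64, 36.6), 2.9, None, None),
    ReferenceRow("Dodder", "riparian", (22.0, 16.3, 22.6, 9.14, 29.9), 3.5, 0.63, 22.0),
    ReferenceRow("Dodder", "livestock_increase", (9.99, 15.6, 24.2, 9.92, 40.2), 2.6, -0.31, -10.9),
    ReferenceRow("Dodder", "livestock_decrease", (17.4, 16.0, 23.1, 9.22, 34.3), 3.1, 0.26, 9.1),
    ReferenceRow("Moy", "no_change", (20.4, 15.8, 22.1, 9.36, 32.2), 3.3, None, None),
    ReferenceRow("Moy", "riparian", (38.1, 14.5, 18.0, 7.6, 21.7), 4.5, 1.20, 35.9),
    ReferenceRow("Moy", "livestock_increase", (13.2, 15.8, 23.5, 10.0, 37.5), 2.8, -0.53, -15.8),
    ReferenceRow("Moy", "livestock_decrease", (29.4, 15.1, 20.0, 8.3, 27.2), 3.9, 0.60, 18.1),
    ReferenceRow("Suir", "no_change", (19.0, 15.5, 22.2, 9.35, 33.9), 3.2, None, None),
    ReferenceRow("Suir", "riparian", (34.5, 14.8, 18.9, 7.97, 23.7), 4.3, 1.09, 33.8),
    ReferenceRow("Suir", "livestock_increase", (12.3, 15.1, 23.3, 9.73, 39.5), 2.7, -0.52, -16.3),
    ReferenceRow("Suir", "livestock_decrease", (25.6, 15.2, 20.8, 8.61, 29.8), 3.7, 0.46, 14.4),
)

#: table metadata: (rows, state labels, class-value map, relative-change decimals)
REFERENCE_TABLES: dict[str, tuple[tuple[ReferenceRow, ...], tuple[str, ...], ClassValueMap, int]] = {
    "Angling": (ANGLING_ROWS, ANGLING_STATES, DEFAULT_CLASS_VALUES["Angling"], 0),
    "MayflyRichness": (MAYFLY_ROWS, MAYFLY_STATES, DEFAULT_CLASS_VALUES["MayflyRichness"], 1),
}


def baseline_row(rows: tuple[ReferenceRow, ...], catchment: str) -> ReferenceRow:
    for row in rows:
        if row.catchment == catchment and row.scenario == BASELINE:
            return row
    raise KeyError(f"no baseline row for {catchment!r}")
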