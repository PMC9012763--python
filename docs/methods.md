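# Methods

## Model and scope

The package implements a discrete Bayesian belief network for freshwater
ecosystem-service (ES) assessment. All variables are categorical with a
small number of ordered states (most favourable first by package
convention; the definition file always stores the order explicitly
because published state listings are not consistent about direction).
Management and catchment choice act by *clamping*: the scenario engine
produces hard evidence on water-quality and catchment-attribute root
nodes, rather than materialising "Catchment" and "Management" as network
nodes with their own CPTs. This matches the input-node description of
the framework the package follows and keeps the network a pure model of
the river system. Soft (virtual) evidence is deliberately unsupported.

Upstream hydrology and load apportionment are out of scope: annual
discharge (m³/y) and total-N/total-P exports (t/y) are consumed as
numbers. So are economic valuation, structure learning, continuous
nodes, and approximate inference — the networks involved are small
enough that exact methods are always feasible.

## Inference

`posterior` uses variable elimination over ndarray factors. The
elimination order is min-fill on the factor-interaction graph with
lexicographic tie-breaking, so orders, results and runtimes are
reproducible; results are independent of the order in exact arithmetic
and the test suite checks agreement to 1e-9 against `enumerate_joint`,
a brute-force summation of the materialised joint (guarded to ≤12 nodes,
used only as the independent oracle). Evidence with probability zero
raises `InconsistentEvidenceError` instead of returning NaNs: silent NaN
propagation hides modelling mistakes such as clamping a state a
deterministic rule forbids. The posterior of an observed node is a point
mass (after confirming the evidence as a whole is possible).

## Network files

The YAML dialect stores probabilities as percentages (the workshop
convention) with row keys joining parent states with `|`. Loading
converts to fractions and validates: acyclicity, ≥2 unique states per
node, CPT parent lists exactly matching the edge set, exhaustive and
unique parent-state combinations, entries in [0,1], and row sums within
1e-9. Percentages are written back rounded to 9 decimals, which makes
load → write → load an identity at that tolerance. Edge and node
provenance flags (`stated` vs `reconstructed`) ride along so the shipped
reference network is auditable: only edges described verbatim in the
study narrative are tagged `stated`; the links completing the graph
(e.g. food and habitat parents of salmon density, the grazer node
controlling algal scum) are tagged `reconstructed`. The mayfly-richness
node uses the published 8/6/3/1/0-species classes; dipper and algal-scum
nodes are reconstructed three-state nodes.

All shipped CPTs except the overall-angling rule are **synthetic**,
generated by the protocol generator from a fixed seed (the elicited
tables are unpublished). The angling CPT encodes the published verbal
rule deterministically: High if either trout or salmon angling is Good,
Low if both are Poor, Medium otherwise.

## Thresholds and classification

Abiotic nodes carry explicit intervals with per-boundary inclusivity
exactly as printed in the regulatory-threshold table the study used
(phosphorus High is strictly >0.035 mg/L, nitrate Low is ≤0.8 mg/L as N,
High ≥2 mg/L, sediment High >30 t/km/y, and so on). A value falling in a
gap left by strict inequalities on both sides is assigned the middle
state with a logged warning rather than erroring: such gaps are
measure-zero artefacts of the printed notation.

## Scenario engine

Speciation: nitrate = totalN·f_inorg·f_nitrate, ammonia =
totalN·f_inorg·(1−f_nitrate), orthophosphate = totalP·f_ortho, with the
monitored ratios per catchment. Concentration = load·10⁶/discharge
(t/y and m³/y to mg/L). Multipliers:

| scenario | nitrate | ammonia | phosphorus | sediment |
|---|---|---|---|---|
| no_change | 1 | 1 | 1 | 1 |
| riparian (achievement a, default 0.5) | 1−0.60a | 1−0.70a | 1−0.30a | 1−0.50a |
| livestock (stock change s) | 1+s·pastureN | 1+s·pastureN | 1+s·pastureP | 1 |
| livestock with export override o | 1+o | 1+o | 1+o | 1 |

The mechanistic pasture rule is the default; the reported whole-export
changes (+18% for +50% stocking, −35% for −20% stocking) are available
as `*_reported` presets because the −35% figure is not derivable from
the pasture rule and we prefer honouring the printed number over
inventing a reconciliation. The override is applied to the nutrient
species only — it describes *nutrient* export — while riparian buffers
also trap sediment. BOD comes from treatment-plant reporting and is
untouched by these scenarios. Unionised-ammonia toxicity is classified
from total ammonia only when the user supplies a speciation fraction
(there is no universal formula without pH and temperature); otherwise
the node is clamped Sub-toxic.

The three shipped demo catchment records carry the published discharges
(Suir 1.1×10⁹, Moy 1.8×10⁹, Dodder 8.6×10⁷ m³/y) and speciation ratios;
the export totals and pasture fractions were only ever published as
charts, so the configs carry synthetic plausible values, chosen once so
that each catchment's baseline sits near its class boundaries (a
scenario analysis in which no class ever changes would exercise
nothing) and flagged `synthetic: true`.

## Elicitation and uncertainty

Aggregation is the equally-weighted element-wise mean of the group
tables (no weighting scheme was published), renormalized per row to
guard against tables typed as rounded percentages. The relative range
(max−min)/mean is 0 exactly when all groups agree (declared 0, with a
warning, for the undefined all-zero case). Band cutoffs for the
disagreement map are not published; defaults are high ≥1.0 and low
≤0.25, both configurable — they reproduce the qualitative split of the
published example without claiming its exact rule. The protocol checker
is advisory (warnings, not errors): anchors of at least 0.9 on the best
state of the best-case row and the worst state of the worst-case row, a
5% probability grid, and monotone non-increase of P(best child state)
along each parent's favourability sweep.

## Synthetic generator

`generate_cpt` anchors the best- and worst-case rows (anchor mass 0.9 by
default, spare mass scattered in grid quanta near the modal state),
scores every parent combination by the mean normalized parent rank
s∈[0,1], applies a per-CPT random curvature s↦s^γ with γ∈[0.7,1.4], and
interpolates linearly *in cumulative distribution space* between the two
anchored rows, rounding the cumulative values to the grid. Rounding
monotone cumulative functions pointwise preserves both the simplex
constraint and first-order stochastic dominance exactly, so generated
CPTs pass the protocol checker with zero diagnostics by construction —
not approximately. Favourability can be overridden per parent per CPT
(e.g. a closed canopy is the *favourable* light state for keeping water
cool, the reverse of the node's own ordering).

`perturb_groups` jitters each element p uniformly on p±h with
h = min(scale, p, 1−p), where scale is `magnitude` (default 0.05, one
grid step) times `low_prob_bias` (default 3) for elements below the
low-probability threshold (default 0.08). Capping h at min(p, 1−p)
keeps the jitter interval symmetric inside [0,1], so element means are
exact without clipping bias; rows are renormalized afterwards (a
second-order correction). Two consequences the tests rely on: the
group average converges to the base CPT as the number of groups grows
(law of large numbers, with no bias floor), and the *relative* range
concentrates at low-probability elements — for p at the grid floor the
spread can reach the full ±p, giving relative ranges near 2, while a
0.6 entry moves by at most ±0.05. A Dirichlet-concentration jitter was
considered and rejected: it cannot bias disagreement towards chosen
elements and has zero variance at zero entries by construction, which
would make the low-probability disagreement pattern unrepresentable.

## ES assessment

Expected values use the printed class values (angling 5/2/1 fish,
mayfly 8/6/3/1/0 species; the single representative value per class
reproduces every published row, so no within-class distribution is
modelled). Dipper and algal scum have no published class quantities and
default to ordinal 2/1/0 scores, flagged as such. Probability rows are
consumed as printed, divided by 100 and *not* renormalized — several
published rows sum to slightly under 100% after rounding, and only the
/100 convention reproduces the published derived columns. Changes are
computed at full precision and then rounded half-up (not banker's):
change to 2 d.p., relative change to a whole percent for angling and
1 d.p. for mayfly, matching the published precisions; both are
configurable.

The sensitivity scan substitutes one CPT element with its lowest, then
highest group estimate, rescaling the remaining row entries
proportionally to restore sum 1 (the alternative — swapping in an
entire donor group's row — perturbs mass the record does not name, so
proportional rescaling is the default). Deltas are
100·(E_high−E_low)/E_baseline per ES node, reported to two decimals,
with probabilities carried internally at full precision and printed at
three significant digits. Zero-width records give exactly 0.00 and the
statistic is antisymmetric under swapping the bounds by construction.

## Problem sizes and numerical choices

The test and acceptance suites use: the 30-node reference network; 100
random networks of 3–12 nodes × 100 random evidence sets for the
elimination/enumeration sweep (tolerance 1e-9; pairs with impossible
evidence must raise identically on both routes); group counts
{2, 4, 16, 64} averaged over 5 seeds for the aggregation-recovery
check; 1000 random catchment records for scenario monotonicity; and the
dissolved-oxygen CPT of the reference network, evidence from the Suir
baseline, for the paired low-probability-vs-modal sensitivity
comparison (margin ±0.05 either side). Row-sum and posterior tolerances
are 1e-9 throughout; all randomness flows through explicit
`numpy.random.default_rng` seeds.

## What the synthetic data does and does not show

The generator reproduces the *structure* of elicited tables (anchoring,
grid, monotonicity, disagreement concentrated at rare outcomes), not
their values. Passing tests therefore certify the machinery —
inference exactness, aggregation consistency, scenario arithmetic,
sensitivity behaviour — and the qualitative direction-of-change
behaviour of monotone networks. They do not reproduce the original
study's posterior probabilities, which depend on the unpublished expert
tables; the published probability columns enter only as fixed inputs to
the arithmetic regression. Real elicited tables can violate
monotonicity (experts may encode genuine non-monotone ecology, e.g.
temperature optima); the protocol checker treats that as advisory, and
nothing in the inference path requires monotone CPTs.

## Known limitations

* Hard evidence only; no soft/virtual evidence or temporal dynamics.
* Annual averages only; sub-annual nutrient dynamics, storm events and
  seasonal exposure windows are invisible to the classification step.
* The reconstructed edges of the reference network are plausible, not
  authoritative; analyses of that fixture characterise the package, not
  the original expert model.
* Deposited-sediment bed cover is inferred from sediment load and flow
  regime through a reconstructed CPT rather than measured directly.
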