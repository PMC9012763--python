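"""End-to-end runs: config -> concentrations -> evidence -> posteriors -> ES table.

Every output CSV starts with a manifest header (package version, seed,
SHA-256 digests of the inputs) so identical configs produce byte-identical
files and any result can be traced back to its exact inputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .assessment import (
    change_metrics,
    expected_value,
    outcomes_to_frame,
    round_half_up,
    run_assessment,
)
from .fixtures import ES_NODES
from .inference import enumerate_joint, posterior, posterior_all
from .network import load_network
from .scenario import Scenario, load_catchment, run_scenario
from .synthetic import generate_network

logger = logging.getLogger(__name__)

DEFAULT_SCENARIOS = ("no_change", "riparian", "livestock_increase", "livestock_decrease")


@dataclass
class RunConfig:
    """Inputs of one reproducible pipeline run."""

    network_path: Path
    catchment_path: Path
    scenario_names: Sequence[str] = DEFAULT_SCENARIOS
    evidence_overrides: Mapping[str, str] = field(default_factory=dict)
    out_dir: Path = Path("esbbn_out")
    seed: int = 0
    es_nodes: Sequence[str] = ES_NODES

    def __post_init__(self) -> None:
        self.network_path = Path(self.network_path)
        self.catchment_path = Path(self.catchment_path)
        self.out_dir = Path(self.out_dir)
        for p in (self.network_path, self.catchment_path):
            if not p.exists():
                raise FileNotFoundError(p)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _manifest(cfg: RunConfig) -> str:
    lines = [
        f"# esbbn {__version__}",
        f"# seed: {cfg.seed}",
        f"# network: {cfg.network_path.name} sha256:{_digest(cfg.network_path)}",
        f"# catchment: {cfg.catchment_path.name} sha256:{_digest(cfg.catchment_path)}",
        f"# scenarios: {','.join(cfg.scenario_names)}",
    ]
    return "\n".join(lines) + "\n"


def _write_csv(frame: pd.DataFrame, path: Path, manifest: str) -> None:
    with open(path, "w") as fh:
        fh.write(manifest)
        frame.to_csv(fh, index=False, float_format="%.6g")


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run the full chain and write concentration, evidence, posterior and
    ES-outcome CSVs into ``cfg.out_dir``; returns the written paths.

    Raises ``ValueError`` naming the missing ``no_change`` baseline if the
    scenario list lacks it; any stage error propagates with its stage name.
    """
    if "no_change" not in cfg.scenario_names:
        raise ValueError("scenario list must include the baseline scenario 'no_change'")
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _manifest(cfg)
    try:
        net = load_network(cfg.network_path)
        rec = load_catchment(cfg.catchment_path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'load': {exc}") from exc

    scenarios = [Scenario.from_name(name) for name in cfg.scenario_names]
    conc_rows, ev_rows, post_rows = [], [], []
    try:
        for sc in scenarios:
            profile, evidence = run_scenario(rec, sc, net)
            if cfg.evidence_overrides:
                merged = dict(evidence.assignments)
                merged.update(cfg.evidence_overrides)
                from .inference import EvidenceSet

                evidence = EvidenceSet(merged)
                evidence.validate(net)
            conc_rows.append(
                {
                    "catchment": rec.name,
                    "scenario": sc.label,
                    "nitrate_mg_l": profile.nitrate,
                    "ammonia_mg_l": profile.ammonia,
                    "orthophosphate_mg_l": profile.orthophosphate,
                    "bod_mg_l": profile.bod,
                    "sediment_t_km_y": profile.sediment,
                    **{f"class_{k}": v for k, v in profile.classes.items()},
                }
            )
            for node, state in sorted(evidence.items()):
                ev_rows.append({"scenario": sc.label, "node": node, "state": state})
            for res in posterior_all(net, evidence, cfg.es_nodes):
                for s, p in res.as_dict().items():
                    post_rows.append(
                        {
                            "scenario": sc.label,
                            "node": res.node,
                            "state": s,
                            "probability_pct": round_half_up(100 * p, 6),
                        }
                    )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'scenario/inference': {exc}") from exc

    try:
        outcomes = run_assessment(net, rec, scenarios, es_nodes=cfg.es_nodes)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'assessment': {exc}") from exc

    paths = {}
    for name, frame in (
        ("concentrations", pd.DataFrame(conc_rows)),
        ("evidence", pd.DataFrame(ev_rows)),
        ("posteriors", pd.DataFrame(post_rows)),
        ("es_outcomes", outcomes_to_frame(outcomes)),
    ):
        path = cfg.out_dir / f"{name}.csv"
        _write_csv(frame, path, manifest)
        paths[name] = path
    logger.info("pipeline wrote %d files to %s", len(paths), cfg.out_dir)
    return paths


# ---------------------------------------------------------------------------
# selfcheck


def selfcheck(n_networks: int = 5, n_evidence: int = 10, seed: int = 1) -> dict:
    """Quick install check: the printed-table regression plus a small
    elimination-vs-enumeration sweep. Returns counts and pass/fail."""
    from .reference_outcomes import REFERENCE_TABLES, baseline_row

    report = {"regression_rows": 0, "regression_failures": 0, "oracle_pairs": 0, "oracle_failures": 0}
    for node, (rows, states, cvm, ndig) in REFERENCE_TABLES.items():
        for row in rows:
            report["regression_rows"] += 1
            e = expected_value(row.probs_pct, states, cvm)
            ok = round_half_up(e, 1) == row.expected
            if row.change is not None:
                base = expected_value(baseline_row(rows, row.catchment).probs_pct, states, cvm)
                change, rel = change_metrics(e, base, relative_ndigits=ndig)
                ok = ok and change == row.change and rel == row.relative_change
            if not ok:
                report["regression_failures"] += 1

    rng = np.random.default_rng(seed)
    for i in range(n_networks):
        net = generate_network(
            n_nodes=int(rng.integers(3, 9)), seed=int(rng.integers(0, 2**31 - 1))
        )
        names = [n.name for n in net.nodes]
        for _ in range(n_evidence):
            k = int(rng.integers(0, max(1, len(names) - 1)))
            picked = list(rng.choice(names, size=k, replace=False))
            ev = {
                n: net.node(n).states[int(rng.integers(0, len(net.node(n).states)))]
                for n in picked
            }
            query = [n for n in names if n not in ev][int(rng.integers(0, len(names) - k))]
            report["oracle_pairs"] += 1
            try:
                p = posterior(net, ev, query).distribution
            except Exception:
                p = None
            try:
                q = enumerate_joint(net, ev, query).distribution
            except Exception:
                q = None
            agree = (p is None and q is None) or (
                p is not None and q is not None and np.max(np.abs(p - q)) < 1e-9
            )
            if not agree:
                report["oracle_failures"] += 1
    report["passed"] = (
        report["regression_failures"] == 0 and report["oracle_failures"] == 0
    )
    return report
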