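"""Group aggregation, the relative-range disagreement statistic, and the
workshop fill-protocol checker."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esbbn.elicitation import (
    GroupEstimateSet,
    aggregate_groups,
    check_protocol,
    disagreement_map,
    load_groups,
    relative_range,
    save_groups,
)
from esbbn.network import CPT, NodeSpec
from esbbn.synthetic import ElicitationModel, GroupNoiseModel, generate_cpt, perturb_groups

CHILD = NodeSpec("DissolvedOxygen", ("High", "Medium", "Low"))
PARENT = NodeSpec("WaterTemp", ("Low", "Medium", "High"))


def _cpt(rows_pct):
    rows = {(s,): [x / 100 for x in row] for s, row in zip(PARENT.states, rows_pct)}
    return CPT.from_rows(CHILD.name, [PARENT.name], CHILD.states, [PARENT.states], rows)


class TestRelativeRange:
    def test_worked_example_zero_and_five_percent(self):
        # two group estimates of 0% and 5% disagree by twice their mean
        assert relative_range([0.0, 0.05]) == pytest.approx(2.00, abs=1e-12)

    def test_equal_estimates_agree_completely(self):
        assert relative_range([0.12, 0.12]) == 0.0

    def test_simple_three_group_case(self):
        assert relative_range([0.10, 0.20, 0.30]) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_is_agreement_at_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert relative_range([0.0, 0.0]) == 0.0
        assert "undefined" in caplog.text

    def test_negative_estimate_rejected(self):
        with pytest.raises(ValueError):
            relative_range([-0.1, 0.2])

    @given(
        est=st.lists(st.floats(0.001, 1.0), min_size=2, max_size=6),
        scale=st.floats(0.01, 100.0),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_scale_invariance(self, est, scale):
        assert relative_range([scale * e for e in est]) == pytest.approx(
            relative_range(est), rel=1e-9
        )

    @given(est=st.lists(st.floats(0.001, 1.0), min_size=2, max_size=6))
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_zero_iff_all_equal(self, est):
        rr = relative_range(est)
        if max(est) == min(est):
            assert rr == 0.0
        else:
            assert rr > 0.0


class TestAggregation:
    def test_two_group_mean(self):
        g1 = _cpt([(80, 10, 10), (60, 20, 20), (10, 20, 70)])
        g2 = _cpt([(60, 20, 20), (40, 40, 20), (10, 20, 70)])
        agg = aggregate_groups(GroupEstimateSet(CHILD.name, [("G1", g1), ("G2", g2)]))
        assert np.allclose(agg.row(("Low",)), [0.70, 0.15, 0.15], atol=1e-12)

    def test_single_group_is_identity(self):
        g1 = _cpt([(80, 10, 10), (60, 20, 20), (10, 20, 70)])
        agg = aggregate_groups(GroupEstimateSet(CHILD.name, [("G1", g1)]))
        assert agg.allclose(g1)

    def test_three_group_hand_arithmetic(self):
        rows = [[(100, 0, 0)] * 3, [(90, 10, 0)] * 3, [(80, 10, 10)] * 3]
        ges = GroupEstimateSet(CHILD.name, [(f"G{i}", _cpt(r)) for i, r in enumerate(rows)])
        agg = aggregate_groups(ges)
        assert np.allclose(agg.row(("Low",)), [0.90, 0.0667, 0.0333], atol=5e-5)

    def test_signature_mismatch_rejected(self):
        other_child = NodeSpec("DissolvedOxygen", ("High", "Low"))
        g1 = _cpt([(80, 10, 10), (60, 20, 20), (10, 20, 70)])
        g2 = CPT.from_rows(
            other_child.name, [PARENT.name], other_child.states, [PARENT.states],
            {(s,): [0.5, 0.5] for s in PARENT.states},
        )
        with pytest.raises(ValueError, match="signature"):
            GroupEstimateSet(CHILD.name, [("G1", g1), ("G2", g2)])

    def test_aggregation_recovery_improves_with_more_groups(self):
        """Averaging G jittered group tables converges back to the base
        CPT; the (seed-averaged) max element error shrinks as G grows."""
        base = generate_cpt(CHILD, [PARENT, NodeSpec("BOD", ("Low", "Medium", "High"))],
                            ElicitationModel(seed=11))
        errors = []
        for g in (2, 4, 16, 64):
            errs = []
            for seed in range(5):
                ges = perturb_groups(base, GroupNoiseModel(n_groups=g, seed=seed))
                agg = aggregate_groups(ges)
                errs.append(float(np.max(np.abs(agg.table - base.table))))
            errors.append(np.mean(errs))
        assert all(a > b for a, b in zip(errors, errors[1:])), errors


class TestDisagreementMap:
    def test_high_band_for_the_large_relative_range(self):
        g1 = _cpt([(90, 10, 0), (60, 20, 20), (0, 20, 80)])
        g2 = _cpt([(90, 5, 5), (60, 20, 20), (5, 15, 80)])
        dm = disagreement_map(
            GroupEstimateSet(CHILD.name, [("G1", g1), ("G2", g2)]),
            high_cutoff=1.0, low_cutoff=0.25,
        )
        assert dm.values[(("High",), "High")] == pytest.approx(2.0)
        assert dm.bands[(("High",), "High")] == "high"
        assert dm.bands[(("Medium",), "High")] == "low"  # identical rows

    def test_identical_groups_all_low(self):
        g = _cpt([(90, 10, 0), (60, 20, 20), (0, 20, 80)])
        dm = disagreement_map(GroupEstimateSet(CHILD.name, [("G1", g), ("G2", g)]))
        assert set(dm.bands.values()) == {"low"}
        assert all(v == 0.0 for v in dm.values.values())

    def test_single_group_warns_and_is_all_low(self, caplog):
        g = _cpt([(90, 10, 0), (60, 20, 20), (0, 20, 80)])
        with caplog.at_level("WARNING"):
            dm = disagreement_map(GroupEstimateSet(CHILD.name, [("G1", g)]))
        assert "single group" in caplog.text
        assert set(dm.bands.values()) == {"low"}

    def test_bad_cutoffs_rejected(self):
        g = _cpt([(90, 10, 0), (60, 20, 20), (0, 20, 80)])
        with pytest.raises(ValueError, match="cutoffs"):
            disagreement_map(GroupEstimateSet(CHILD.name, [("G1", g)]), 0.1, 0.5)

    def test_disagreement_concentrates_at_low_probability_elements(self):
        """On synthetic group sets the high-disagreement band sits mostly at
        elements whose mean probability is <= 8%."""
        parents = [PARENT, NodeSpec("BOD", ("Low", "Medium", "High")),
                   NodeSpec("EutrophicationRisk", ("Low", "Medium", "High"))]
        base = generate_cpt(CHILD, parents, ElicitationModel(seed=5))
        ges = perturb_groups(base, GroupNoiseModel(n_groups=4, low_prob_bias=3.0, seed=5))
        agg = aggregate_groups(ges)
        dm = disagreement_map(ges)
        high_keys = [k for k, b in dm.bands.items() if b == "high"]
        assert high_keys, "expected some high-disagreement elements"
        n_low_mean = sum(
            1 for combo, state in high_keys if agg.prob(combo, state) <= 0.08
        )
        assert n_low_mean > len(high_keys) - n_low_mean

    def test_csv_export_layout(self, tmp_path):
        g = _cpt([(90, 10, 0), (60, 20, 20), (0, 20, 80)])
        dm = disagreement_map(GroupEstimateSet(CHILD.name, [("G1", g), ("G2", g)]))
        path = tmp_path / "dm.csv"
        dm.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "parent_combination,child_state,relative_range,band"


class TestProtocolChecker:
    def test_protocol_shaped_cpt_is_clean(self):
        cpt = generate_cpt(CHILD, [PARENT], ElicitationModel(seed=7))
        assert check_protocol(cpt) == []

    def test_weak_best_case_anchor_flagged(self):
        cpt = _cpt([(60, 30, 10), (60, 20, 20), (5, 15, 80)])
        diags = check_protocol(cpt)
        assert any(d.rule == "anchor-best" for d in diags)

    def test_weak_worst_case_anchor_flagged(self):
        cpt = _cpt([(95, 5, 0), (60, 20, 20), (30, 30, 40)])
        assert any(d.rule == "anchor-worst" for d in check_protocol(cpt))

    def test_off_grid_probability_flagged(self):
        cpt = _cpt([(93, 7, 0), (60, 20, 20), (0, 10, 90)])
        assert any(d.rule == "grid" for d in check_protocol(cpt))

    def test_non_monotone_sweep_flagged(self):
        # P(High DO) increases again as temperature worsens: inconsistent fill
        cpt = _cpt([(90, 10, 0), (30, 40, 30), (90, 10, 0)])
        diags = check_protocol(cpt)
        assert any(d.rule == "monotone" for d in diags)
        assert any(d.rule == "anchor-worst" for d in diags)


class TestGroupIO:
    def test_group_file_round_trip(self, tmp_path):
        base = generate_cpt(CHILD, [PARENT], ElicitationModel(seed=3))
        ges = perturb_groups(base, GroupNoiseModel(n_groups=3, seed=3))
        path = tmp_path / "groups.yaml"
        save_groups(ges, path)
        again = load_groups(path, CHILD, [PARENT])
        assert again.n_groups == 3
        for (gid_a, cpt_a), (gid_b, cpt_b) in zip(ges.groups, again.groups):
            assert gid_a == gid_b
            assert np.allclose(cpt_a.table, cpt_b.table, atol=1e-9)
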