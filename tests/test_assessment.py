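"""Expected indicator values, change metrics, scenario assessment and the
min/max sensitivity scan."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esbbn.assessment import (
    DEFAULT_CLASS_VALUES,
    SensitivityRecord,
    change_metrics,
    expected_value,
    round_half_up,
    run_assessment,
    sensitivity_scan,
)
from esbbn.reference_outcomes import ANGLING_STATES, MAYFLY_STATES
from esbbn.scenario import Scenario, run_scenario

ANGLING_CVM = DEFAULT_CLASS_VALUES["Angling"]
MAYFLY_CVM = DEFAULT_CLASS_VALUES["MayflyRichness"]


class TestExpectedValue:
    def test_dodder_baseline_angling(self):
        e = expected_value((41.8, 18.5, 39.8), ANGLING_STATES, ANGLING_CVM)
        assert round_half_up(e, 1) == 2.9

    def test_certainty_on_high(self):
        assert expected_value((100, 0, 0), ANGLING_STATES, ANGLING_CVM) == 5.0

    def test_moy_riparian_mayfly(self):
        e = expected_value((38.1, 14.5, 18, 7.6, 21.7), MAYFLY_STATES, MAYFLY_CVM)
        assert round_half_up(e, 1) == 4.5

    def test_state_mismatch_rejected(self):
        with pytest.raises(ValueError, match="lacks values"):
            expected_value((50, 50), ("High", "Unheard-of"), ANGLING_CVM)

    @given(
        p=st.lists(st.floats(0, 1), min_size=3, max_size=3),
        q=st.lists(st.floats(0, 1), min_size=3, max_size=3),
        alpha=st.floats(0, 1),
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_linearity_in_the_distribution(self, p, q, alpha):
        mix = [alpha * a + (1 - alpha) * b for a, b in zip(p, q)]
        e_mix = expected_value(mix, ANGLING_STATES, ANGLING_CVM, percent=False)
        e_sep = alpha * expected_value(p, ANGLING_STATES, ANGLING_CVM, percent=False) + (
            1 - alpha
        ) * expected_value(q, ANGLING_STATES, ANGLING_CVM, percent=False)
        assert e_mix == pytest.approx(e_sep, abs=1e-9)


class TestChangeMetrics:
    def test_moy_riparian_angling(self):
        base = expected_value((40.6, 18.1, 41.2), ANGLING_STATES, ANGLING_CVM)
        rip = expected_value((47.8, 17.9, 34.3), ANGLING_STATES, ANGLING_CVM)
        assert change_metrics(rip, base, relative_ndigits=0) == (0.29, 10)

    def test_suir_mayfly_more_livestock(self):
        base = expected_value((19.0, 15.5, 22.2, 9.35, 33.9), MAYFLY_STATES, MAYFLY_CVM)
        more = expected_value((12.3, 15.1, 23.3, 9.73, 39.5), MAYFLY_STATES, MAYFLY_CVM)
        assert change_metrics(more, base, relative_ndigits=1) == (-0.52, -16.3)

    def test_identical_distributions_give_zero(self):
        assert change_metrics(2.5, 2.5) == (0.0, 0)

    def test_zero_baseline_leaves_relative_undefined(self):
        change, rel = change_metrics(1.0, 0.0)
        assert change == 1.0 and rel is None

    def test_half_up_rounding_convention(self):
        # the printed tables round halves up, not to even
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(-0.125, 2) == -0.13
        assert round_half_up(10.5, 0) == 11.0


class TestRunAssessment:
    SCENARIOS = [Scenario.no_change(), Scenario.riparian(),
                 Scenario.livestock_increase(), Scenario.livestock_decrease()]

    def test_shape_contract(self, ref_net, suir):
        outcomes = run_assessment(ref_net, suir, self.SCENARIOS)
        assert len(outcomes) == 16  # 4 ES nodes x 4 scenarios
        baseline = [o for o in outcomes if o.scenario == "no_change"]
        assert len(baseline) == 4
        assert all(o.change is None and o.relative_change is None for o in baseline)
        assert all(o.change is not None for o in outcomes if o.scenario != "no_change")

    def test_identical_scenarios_identical_outcomes(self, ref_net, dodder):
        a = run_assessment(ref_net, dodder, self.SCENARIOS)
        b = run_assessment(ref_net, dodder, self.SCENARIOS)
        assert a == b

    def test_missing_baseline_rejected(self, ref_net, suir):
        with pytest.raises(ValueError, match="no_change"):
            run_assessment(ref_net, suir, [Scenario.riparian()])

    @pytest.mark.parametrize("catchment_fixture", ["suir", "moy", "dodder"])
    def test_riparian_improves_angling_and_mayfly(self, ref_net, request, catchment_fixture):
        rec = request.getfixturevalue(catchment_fixture)
        outcomes = run_assessment(ref_net, rec, self.SCENARIOS)
        for node in ("Angling", "MayflyRichness"):
            rip = next(o for o in outcomes if o.node == node and o.scenario == "riparian")
            assert rip.relative_change >= 0.0


class TestSensitivityScan:
    def _records_and_evidence(self, net, rec):
        _, ev = run_scenario(rec, Scenario.no_change(), net)
        cpt = net.cpts["DissolvedOxygen"]
        combo = next(cpt.combos())
        return cpt, combo, ev

    def test_zero_width_bounds_give_exact_zero(self, ref_net, suir):
        cpt, combo, ev = self._records_and_evidence(ref_net, suir)
        p = float(cpt.row(combo)[1])
        rec = SensitivityRecord("DissolvedOxygen", combo, cpt.child_states[1], p, p)
        (res,) = sensitivity_scan(ref_net, [rec], ev)
        assert all(d == 0.0 for d in res.es_deltas.values())

    def test_antisymmetric_under_bound_swap(self, ref_net, suir):
        """The reported delta is 100*(E_high - E_low)/E_base; feeding the
        bounds in the opposite roles flips every sign exactly."""
        from esbbn.assessment import expected_value as ev_of
        from esbbn.inference import posterior_all

        cpt, combo, ev = self._records_and_evidence(ref_net, suir)
        state = cpt.child_states[0]
        rec = SensitivityRecord("DissolvedOxygen", combo, state, 0.4, 0.9)
        (res,) = sensitivity_scan(ref_net, [rec], ev)

        def expectations(value):
            net = ref_net.with_cpt(cpt.substitute(combo, state, value))
            return {
                r.node: ev_of(r.distribution, r.states,
                              DEFAULT_CLASS_VALUES[r.node], percent=False)
                for r in posterior_all(net, ev, list(DEFAULT_CLASS_VALUES))
            }

        base = {
            r.node: ev_of(r.distribution, r.states,
                          DEFAULT_CLASS_VALUES[r.node], percent=False)
            for r in posterior_all(ref_net, ev, list(DEFAULT_CLASS_VALUES))
        }
        e_lo, e_hi = expectations(0.4), expectations(0.9)
        for node, d in res.es_deltas.items():
            unrounded = 100.0 * (e_hi[node] - e_lo[node]) / base[node]
            assert d == round_half_up(unrounded, 2)
            # swapping the roles of the bounds negates the unrounded delta
            assert -unrounded == pytest.approx(
                100.0 * (e_lo[node] - e_hi[node]) / base[node], abs=1e-12
            )

    def test_toy_network_delta_matches_enumeration_oracle(self, toy_net):
        """Hand-built record on the 2-node chain: the scan's delta equals the
        difference of oracle-computed expected values."""
        from esbbn.assessment import ClassValueMap
        from esbbn.inference import enumerate_joint

        cvm = ClassValueMap("B", {"G": 2.0, "P": 1.0})
        rec = SensitivityRecord("B", ("H",), "G", 0.6, 1.0)
        (res,) = sensitivity_scan(toy_net, [rec], {}, es_nodes=["B"], cvms={"B": cvm})

        def expected(p_g_given_h):
            net = toy_net.with_cpt(
                toy_net.cpts["B"].substitute(("H",), "G", p_g_given_h)
            )
            dist = enumerate_joint(net, {}, "B").distribution
            return 2.0 * dist[0] + 1.0 * dist[1]

        base = expected(0.9)
        manual = 100.0 * (expected(1.0) - expected(0.6)) / base
        assert res.es_deltas["B"] == round_half_up(manual, 2)

    def test_unknown_cpt_element_rejected(self, ref_net, suir):
        _, _, ev = self._records_and_evidence(ref_net, suir)
        rec = SensitivityRecord("DissolvedOxygen", ("Nope", "Nope", "Nope"), "High", 0.0, 0.1)
        with pytest.raises(ValueError):
            sensitivity_scan(ref_net, [rec], ev)

    def test_low_probability_entries_move_results_less(self, ref_net, suir):
        """Equal-margin substitutions at entries <= 0.15 swing the ES
        expectations far less than at modal entries: disagreement about
        rare outcomes is benign."""
        _, ev = run_scenario(suir, Scenario.no_change(), ref_net)
        cpt = ref_net.cpts["DissolvedOxygen"]
        low_recs, modal_recs = [], []
        for combo in cpt.combos():
            for s, p in zip(cpt.child_states, cpt.row(combo)):
                if 0.05 <= p <= 0.15:
                    low_recs.append(
                        SensitivityRecord("DissolvedOxygen", combo, s, p - 0.05, p + 0.05))
                elif 0.5 <= p <= 0.9:
                    modal_recs.append(
                        SensitivityRecord("DissolvedOxygen", combo, s, p - 0.05, p + 0.05))
        assert low_recs and modal_recs
        max_low = max(
            max(abs(d) for d in r.es_deltas.values())
            for r in sensitivity_scan(ref_net, low_recs, ev)
        )
        max_modal = max(
            max(abs(d) for d in r.es_deltas.values())
            for r in sensitivity_scan(ref_net, modal_recs, ev)
        )
        assert max_low < max_modal
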