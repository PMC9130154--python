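"""One-way sweeps, tornado summaries and strategy-switch thresholds."""

import numpy as np
import pytest

import ceatree as ct
from ceatree.expressions import P, one_minus
from ceatree.params import ParameterSpec
from ceatree.sensitivity import one_way, switch_threshold, tornado
from ceatree.tree import (
    DecisionBranch,
    DecisionNode,
    DecisionTree,
    chance,
    terminal,
)

WTP = ct.WTP_DEFAULT


class TestOneWay:
    def test_prevalence_sweep_reproduces_published_endpoints(self, finger_model):
        frame = one_way(finger_model, "prevalence", [0.0, 1.0], WTP, force=True)

        def qaly(value, strategy):
            row = frame[(frame.value == value) & (frame.strategy == strategy)]
            return float(row.expected_qaly.iloc[0])

        assert qaly(0.0, "CBCT") == pytest.approx(8.8, abs=1e-9)
        assert qaly(0.0, "MSCT") == pytest.approx(7.9, abs=1e-9)
        assert qaly(1.0, "CBCT") == pytest.approx(9.08, abs=1e-9)
        assert qaly(1.0, "MSCT") == pytest.approx(8.18, abs=1e-9)

    def test_point_estimate_grid_reproduces_base_case(self, finger_model):
        base = ct.rollback(finger_model)
        pe = finger_model.parameters["p_arthritis"].point_estimate
        frame = one_way(finger_model, "p_arthritis", [pe], WTP)
        for s in finger_model.strategies:
            row = frame[frame.strategy == s]
            assert float(row.expected_cost.iloc[0]) == pytest.approx(
                base[s].expected_cost, abs=1e-12
            )
            assert float(row.expected_qaly.iloc[0]) == pytest.approx(
                base[s].expected_qaly, abs=1e-12
            )

    def test_unknown_parameter_rejected(self, finger_model):
        with pytest.raises(KeyError):
            one_way(finger_model, "nope", [0.1], WTP)

    def test_out_of_range_requires_force(self, finger_model):
        with pytest.raises(ValueError):
            one_way(finger_model, "prevalence", [0.99], WTP)

    def test_three_point_collinearity_for_linear_parameter(self, finger_model):
        """Outputs are affine in a parameter entering every path linearly."""
        frame = one_way(finger_model, "prevalence", [0.10, 0.175, 0.25], WTP)
        for s in finger_model.strategies:
            rows = frame[frame.strategy == s].sort_values("value")
            nmbs = rows.nmb.to_numpy()
            assert nmbs[1] == pytest.approx(0.5 * (nmbs[0] + nmbs[2]), abs=1e-9)


class TestTornado:
    def test_most_influential_parameters(self, finger_model):
        """Fracture prevalence and the CBCT unit cost dominate the tornado."""
        entries = tornado(finger_model, WTP)
        top2 = {entries[0].parameter, entries[1].parameter}
        assert top2 == {"prevalence", "cost_cbct"}

    def test_unreferenced_parameter_has_zero_width_and_sorts_last(self, finger_model):
        entries = tornado(finger_model, WTP)
        by_name = {e.parameter: e for e in entries}
        assert by_name["pretest_probability"].width == 0.0
        assert entries[-1].width == 0.0

    def test_widths_match_independent_two_point_recomputation(self, finger_model):
        entries = tornado(finger_model, WTP, outcome="qaly")
        base_env = finger_model.point_estimates()
        # base-case optimal strategy is CBCT throughout
        for e in entries:
            lo = float(ct.evaluate(finger_model, dict(base_env, **{e.parameter: e.low}))["CBCT"][1])
            hi = float(ct.evaluate(finger_model, dict(base_env, **{e.parameter: e.high}))["CBCT"][1])
            assert e.width == pytest.approx(abs(hi - lo), abs=1e-12)

    def test_width_invariant_to_range_direction(self, finger_model):
        fwd = tornado(finger_model, WTP, ranges={"prevalence": (0.10, 0.25)})
        rev = tornado(finger_model, WTP, ranges={"prevalence": (0.25, 0.10)})
        assert fwd[0].width == pytest.approx(rev[0].width, abs=1e-12)
        assert fwd[0].outcome_at_low == pytest.approx(rev[0].outcome_at_high, abs=1e-12)

    def test_entries_sorted_by_width_descending(self, finger_model):
        widths = [e.width for e in tornado(finger_model, WTP)]
        assert widths == sorted(widths, reverse=True)


def _affine_two_strategy_tree(point=0.4):
    """NMB gap between the strategies is p - 0.5 (affine); switch at p = 0.5."""
    a = chance("event", [
        ("win", P("p"), terminal("w", 0.0, 1.0)),
        ("lose", one_minus(P("p")), terminal("l", 0.0, 0.0)),
    ])
    b = terminal("flat", 0.0, 0.5)
    root = DecisionNode("d", [DecisionBranch("A", a), DecisionBranch("B", b)])
    return DecisionTree(
        root=root,
        parameters={"p": ParameterSpec("p", point, 0.0, 1.0, "probability", "beta", 0.1)},
    )


class TestSwitchThreshold:
    def test_parameter_without_effect_returns_none(self, finger_model):
        assert switch_threshold(finger_model, "pretest_probability", WTP) is None

    def test_affine_gap_matches_analytic_root(self):
        tree = _affine_two_strategy_tree()
        crossing = switch_threshold(tree, "p", wtp=30_000)
        assert crossing == pytest.approx(0.5, abs=1e-9)

    def test_cbct_cost_break_even_matches_closed_form(self, finger_model):
        """CBCT stays optimal until its unit cost reaches the analytic
        break-even C* = C_rival + λ·ΔE against the best frontier rival."""
        base = ct.rollback(finger_model)
        # best rival in NMB terms at base case is MSCT (its unconditional
        # QALYs exceed CR's flat 7.9 at the base prevalence)
        delta_e = base["CBCT"].expected_qaly - base["MSCT"].expected_qaly
        c_star = base["MSCT"].expected_cost + WTP * delta_e
        crossing = switch_threshold(
            finger_model, "cost_cbct", WTP, bounds=(67.33, 50_000.0)
        )
        assert crossing == pytest.approx(c_star, rel=1e-9)
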