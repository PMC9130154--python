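"""Tree structure, validation and expected-value rollback."""

import numpy as np
import pytest

import ceatree as ct
from ceatree.expressions import P, UnboundParameterError, one_minus
from ceatree.tree import (
    ChanceNode,
    DecisionBranch,
    DecisionNode,
    DecisionTree,
    chance,
    terminal,
)

from oracles import expected_by_enumeration, random_tree


class TestJointProbabilities:
    @pytest.mark.parametrize(
        "prev,sens,spec,expected",
        [
            (0.18, 0.96, 0.90, (0.1728, 0.0072, 0.0820, 0.7380)),
            (0.0, 0.7, 0.9, (0.0, 0.0, 0.1, 0.9)),
            (1.0, 0.90, 0.37, (0.90, 0.10, 0.0, 0.0)),
        ],
    )
    def test_values(self, prev, sens, spec, expected):
        got = ct.diagnostic_joint_probabilities(prev, sens, spec)
        assert got == pytest.approx(expected, abs=1e-12)
        assert sum(got) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [(-0.1, 0.5, 0.5), (0.5, 1.2, 0.5), (0.5, 0.5, -2)])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            ct.diagnostic_joint_probabilities(*bad)


def _simple_tree(prob_a=0.6, prob_b=0.4, qaly_expr=None):
    node = chance(
        "event",
        [
            ("a", prob_a, terminal("ta", 10.0, qaly_expr if qaly_expr is not None else 1.0)),
            ("b", prob_b, terminal("tb", 20.0, 2.0)),
        ],
    )
    root = DecisionNode("d", [DecisionBranch("only", node)])
    return DecisionTree(root=root, parameters={})


class TestValidation:
    def test_bundled_fixture_is_valid(self, finger_model):
        assert ct.validate_tree(finger_model) == []

    def test_probability_sum_violation(self):
        tree = _simple_tree(0.6, 0.5)
        violations = ct.validate_tree(tree)
        assert len(violations) == 1
        assert "sum to 1.1" in violations[0]

    def test_unbound_parameter_violation(self):
        tree = _simple_tree(P("sens_CBTC"), one_minus(P("sens_CBTC")))
        violations = ct.validate_tree(tree)
        assert violations == ["expression references undefined parameter 'sens_CBTC'"]

    def test_decision_node_below_root_rejected(self):
        inner = DecisionNode("d2", [DecisionBranch("x", terminal("t", 1.0, 1.0))])
        root = DecisionNode("d", [DecisionBranch("s", inner)])
        violations = ct.validate_tree(DecisionTree(root=root, parameters={}))
        assert any("below the root" in v for v in violations)

    def test_shared_subnode_rejected(self):
        leaf = terminal("t", 1.0, 1.0)
        node = chance("c", [("a", 0.5, leaf), ("b", 0.5, leaf)])
        root = DecisionNode("d", [DecisionBranch("s", node)])
        violations = ct.validate_tree(DecisionTree(root=root, parameters={}))
        assert any("shared" in v for v in violations)

    def test_rollback_refuses_invalid_tree(self):
        with pytest.raises(ct.TreeStructureError):
            ct.rollback(_simple_tree(0.6, 0.5))


class TestRollback:
    def test_single_terminal_identity(self):
        root = DecisionNode("d", [DecisionBranch("s", terminal("t", 10.0, 1.0))])
        out = ct.rollback(DecisionTree(root=root, parameters={}))["s"]
        assert (out.expected_cost, out.expected_qaly) == (10.0, 1.0)

    def test_matches_path_enumeration_on_fixture(self, finger_model):
        rb = ct.rollback(finger_model)
        oracle = expected_by_enumeration(finger_model)
        for s in finger_model.strategies:
            assert rb[s].expected_cost == pytest.approx(oracle[s][0], abs=1e-12)
            assert rb[s].expected_qaly == pytest.approx(oracle[s][1], abs=1e-12)

    def test_missing_parameter_raises(self, finger_model):
        env = finger_model.point_estimates()
        env.pop("prevalence")
        with pytest.raises(UnboundParameterError):
            ct.evaluate(finger_model, env)

    def test_linear_in_single_probability_parameter(self, finger_model):
        """Rollback is affine in a probability appearing once per path:
        endpoint interpolation reproduces any intermediate value."""
        env = finger_model.point_estimates()
        at0 = ct.evaluate(finger_model, dict(env, prevalence=0.0))
        at1 = ct.evaluate(finger_model, dict(env, prevalence=1.0))
        for p in (0.07, 0.18, 0.5, 0.93):
            atp = ct.evaluate(finger_model, dict(env, prevalence=p))
            for s in finger_model.strategies:
                interp = (1 - p) * at0[s][1] + p * at1[s][1]
                assert float(atp[s][1]) == pytest.approx(interp, abs=1e-12)

    def test_branch_order_permutation_invariant(self):
        from ceatree.tree import iter_nodes

        tree = ct.build_model()
        before = ct.rollback(tree)
        for node in iter_nodes(tree.root):
            if isinstance(node, (ChanceNode, DecisionNode)):
                node.branches = list(reversed(node.branches))
        after = ct.rollback(tree)
        for s in before:
            assert after[s].expected_cost == pytest.approx(before[s].expected_cost, abs=1e-12)
            assert after[s].expected_qaly == pytest.approx(before[s].expected_qaly, abs=1e-12)

    def test_vectorised_evaluation_matches_scalar(self, finger_model):
        env = finger_model.point_estimates()
        prevs = np.array([0.0, 0.18, 1.0])
        vec = ct.evaluate(finger_model, dict(env, prevalence=prevs))
        for i, p in enumerate(prevs):
            scal = ct.evaluate(finger_model, dict(env, prevalence=float(p)))
            for s in finger_model.strategies:
                assert np.asarray(vec[s][1])[i] == pytest.approx(scal[s][1], abs=1e-12)


class TestRandomTrees:
    def test_rollback_equals_enumeration(self):
        rng = np.random.default_rng(20200202)
        for _ in range(30):
            tree = random_tree(rng)
            assert ct.validate_tree(tree) == []
            rb = ct.rollback(tree)
            oracle = expected_by_enumeration(tree)
            for s in tree.strategies:
                assert rb[s].expected_cost == pytest.approx(oracle[s][0], abs=1e-12)
                assert rb[s].expected_qaly == pytest.approx(oracle[s][1], abs=1e-12)
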