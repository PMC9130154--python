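"""Distribution fitting, Monte-Carlo propagation, CEAC and scatter outputs."""

import dataclasses

import numpy as np
import pytest

import ceatree as ct
from ceatree.params import ParameterSpec
from ceatree.psa import (
    ceac,
    fit_distribution,
    incremental_scatter,
    probability_optimal,
    run_psa,
)

WTP = ct.WTP_DEFAULT


def _all_fixed(tree):
    """Copy of the model with every parameter held deterministic."""
    fixed = ct.build_model()
    for name, spec in fixed.parameters.items():
        fixed.parameters[name] = dataclasses.replace(
            spec, dist_family="fixed", dispersion=0.0
        )
    return fixed


class TestFitDistribution:
    def test_beta_moment_matching(self):
        spec = ParameterSpec("u", 0.5, 0.0, 1.0, "utility", "beta", 0.2)  # sd 0.1
        s = fit_distribution(spec)
        assert s.a == pytest.approx(12.0, abs=1e-12)
        assert s.b == pytest.approx(12.0, abs=1e-12)

    def test_beta_infeasible_dispersion(self):
        spec = ParameterSpec("u", 0.5, 0.0, 1.0, "utility", "beta", 1.1)
        with pytest.raises(ct.InfeasibleDispersionError):
            fit_distribution(spec)

    def test_gamma_moments(self):
        spec = ParameterSpec("c", 67.33, 0.0, 200.0, "cost", "gamma", 0.1)
        s = fit_distribution(spec)
        assert s.a * s.b == pytest.approx(67.33, rel=1e-12)  # mean
        assert np.sqrt(s.a) * s.b == pytest.approx(6.733, rel=1e-12)  # sd

    def test_fixed_is_degenerate(self):
        spec = ParameterSpec("p", 0.18, 0.18, 0.18, "probability", "fixed", 0.0)
        draws = fit_distribution(spec).sample(np.random.default_rng(0), 100)
        assert np.all(draws == 0.18)


class TestRunPSA:
    def test_same_seed_bitwise_identical(self, finger_model):
        a = run_psa(finger_model, 500, seed=11)
        b = run_psa(finger_model, 500, seed=11)
        assert a.draws.equals(b.draws)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)

    def test_all_fixed_single_iteration_equals_rollback(self):
        fixed = _all_fixed(None)
        result = run_psa(fixed, 1, seed=0)
        base = ct.rollback(fixed)
        for j, s in enumerate(result.strategies):
            assert result.costs[0, j] == pytest.approx(base[s].expected_cost, abs=1e-12)
            assert result.qalys[0, j] == pytest.approx(base[s].expected_qaly, abs=1e-12)

    def test_draw_bounds(self, finger_model):
        result = run_psa(finger_model, 2000, seed=5)
        for name, spec in finger_model.parameters.items():
            draws = result.draws[name].to_numpy()
            if spec.role in ("probability", "utility"):
                assert np.all((draws >= 0) & (draws <= 1))
            if spec.role == "cost":
                assert np.all(draws >= 0)
        assert result.n_rejected == 0

    def test_mc_mean_cost_near_rollback(self, finger_model):
        """Gamma/beta sampling is mean-preserving, so Monte-Carlo mean costs
        match rollback within 3 standard errors."""
        result = run_psa(finger_model, 5000, seed=13)
        base = ct.rollback(finger_model)
        for j, s in enumerate(result.strategies):
            mc = result.costs[:, j]
            se = mc.std(ddof=1) / np.sqrt(len(mc))
            assert abs(mc.mean() - base[s].expected_cost) < 3 * se


class TestCEAC:
    def test_all_fixed_gives_certainty(self):
        fixed = _all_fixed(None)
        result = run_psa(fixed, 50, seed=1)
        assert probability_optimal(result, "CBCT", WTP) == 1.0

    def test_probabilities_partition(self, finger_model):
        result = run_psa(finger_model, 1000, seed=2)
        curve = ceac(result, [0.0, 500.0, 10_000.0, 30_000.0, 50_000.0])
        totals = curve[result.strategies].sum(axis=1)
        assert np.allclose(totals, 1.0, atol=1e-12)

    def test_certainty_increases_as_dispersion_shrinks(self):
        """The dominant strategy's acceptability tends to 1 as dispersions → 0."""
        probs = []
        for disp in (0.5, 0.2, 0.05):
            tree = ct.build_model()
            for name, spec in tree.parameters.items():
                if spec.dist_family != "fixed":
                    tree.parameters[name] = dataclasses.replace(spec, dispersion=disp)
            # widen: at disp 0.5 some beta means are infeasible -> clamp those to fixed
            for name, spec in tree.parameters.items():
                if spec.dist_family == "beta":
                    s = spec.dispersion * spec.point_estimate
                    if s * s >= spec.point_estimate * (1 - spec.point_estimate):
                        tree.parameters[name] = dataclasses.replace(
                            spec, dist_family="fixed", dispersion=0.0
                        )
            result = run_psa(tree, 2000, seed=3)
            probs.append(probability_optimal(result, "CBCT", WTP))
        assert probs == sorted(probs)
        assert probs[-1] == pytest.approx(1.0, abs=0.01)

    def test_ties_split_equally(self):
        """Two identical strategies share the optimal probability."""
        from ceatree.tree import DecisionBranch, DecisionNode, DecisionTree, terminal

        root = DecisionNode("d", [
            DecisionBranch("a", terminal("ta", 5.0, 1.0)),
            DecisionBranch("b", terminal("tb", 5.0, 1.0)),
        ])
        tree = DecisionTree(root=root, parameters={})
        result = run_psa(tree, 10, seed=0, disease_parameter=None)
        curve = ceac(result, [1000.0])
        assert float(curve["a"].iloc[0]) == 0.5
        assert float(curve["b"].iloc[0]) == 0.5


class TestIncrementalScatter:
    def test_all_fixed_collapses_to_base_increments(self):
        fixed = _all_fixed(None)
        result = run_psa(fixed, 20, seed=0)
        base = ct.rollback(fixed)
        scatter = incremental_scatter(result, "CR")
        cbct = scatter[scatter.strategy == "CBCT"]
        assert np.allclose(cbct.delta_cost, base["CBCT"].expected_cost - base["CR"].expected_cost)
        assert np.allclose(cbct.delta_qaly, base["CBCT"].expected_qaly - base["CR"].expected_qaly)

    def test_cbct_vs_cr_cloud_mean_matches_published_increments(self, finger_model):
        """Mean of the CBCT-vs-CR cloud (published-table convention: QALYs
        conditional on disease present) sits at (ΔE, ΔC) ≈ (1.18, 35.33)."""
        result = run_psa(finger_model, 4000, seed=17)
        scatter = incremental_scatter(result, "CR", measure="disease_present")
        cbct = scatter[scatter.strategy == "CBCT"]
        n = len(cbct)
        for col, target in (("delta_qaly", 1.18), ("delta_cost", 35.33)):
            vals = cbct[col].to_numpy()
            se = vals.std(ddof=1) / np.sqrt(n)
            assert abs(vals.mean() - target) < 3 * se

    def test_msct_vs_cbct_mean_in_dominated_quadrant(self, finger_model):
        result = run_psa(finger_model, 2000, seed=19)
        scatter = incremental_scatter(result, "CBCT", measure="disease_present")
        msct = scatter[scatter.strategy == "MSCT"]
        assert msct.delta_cost.mean() > 0
        assert msct.delta_qaly.mean() < 0
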