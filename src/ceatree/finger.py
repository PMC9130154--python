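"""Bundled reference model: diagnostic strategies for complex phalangeal fractures.

The model compares three ways of working up a suspected complex (articular)
finger fracture after conventional radiography (CR): stop at CR alone, add
cone-beam CT (CBCT), or add multi-slice CT (MSCT).  It is a one-period
decision tree over a hypothetical cohort: fracture status at the pretest
prevalence, diagnostic outcome through the modality's sensitivity and
specificity, then — for treated true positives — a chain of complication
events (displacement, non-union, post-traumatic arthritis) versus
uncomplicated recovery.  Missed fractures (false negatives) land in a
complication-weighted reduced-utility state.

Costs follow the published unit costs (CR 32 €, CBCT 67.33 €, MSCT 106.23 €),
assigned uniformly to every terminal of a strategy, so each strategy's
expected cost equals its unit cost exactly.  Strategy-level effectiveness in
the source table is on a compressed QALY scale that cannot be recovered from
the printed utilities; the leaf QALYs are therefore *calibrated*: the
conditional expected QALYs given disease absent/present are pinned to the
published endpoint values, with fixed complication decrements (scaled to the
same compressed QALY scale, see :func:`default_decrements`) setting the
within-branch spread.  The decrement allocation is synthetic — the source
does not print leaf payoffs.
"""

from __future__ import annotations

from .expressions import P, one_minus
from .params import ParameterSpec
from .tree import DecisionBranch, DecisionNode, DecisionTree, chance, evaluate, terminal

WTP_DEFAULT = 30_000.0  # €/QALY, the base-case willingness-to-pay threshold
DEFAULT_DISPERSION = 0.10  # relative SE used for every uncertain parameter

#: Calibration targets: expected QALYs conditional on (disease absent, disease
#: present), per strategy.  The disease-present values are the published
#: per-strategy QALYs; the disease-absent values are the published
#: prevalence-0 endpoints of the one-way analysis (CR is flat: its published
#: QALY does not depend on prevalence).
QALY_TARGETS: dict[str, tuple[float, float]] = {
    "CR": (7.9, 7.9),
    "CBCT": (8.8, 9.08),
    "MSCT": (7.9, 8.18),
}

#: Disease-status QALY gap of the CT strategies (present minus absent); the
#: anchor that puts complication decrements on the model's compressed QALY scale.
DISEASE_QALY_GAP = QALY_TARGETS["CBCT"][1] - QALY_TARGETS["CBCT"][0]

FN_DELAY_FACTOR = 2.0  # missed fractures carry twice the expected complication loss

_STRATEGY_TESTS = {
    # strategy -> (sensitivity parameter, specificity parameter)
    "CR": ("sens_cr", "correct_diagnosis"),
    "CBCT": ("sens_cbct", "spec_cbct"),
    "MSCT": ("sens_msct", "spec_msct"),
}
_STRATEGY_COSTS = {"CR": "cost_cr", "CBCT": "cost_cbct", "MSCT": "cost_msct"}

_LEAVES = ("tp_none", "tp_displacement", "tp_nonunion", "tp_arthritis", "fn", "fp", "tn")


class CalibrationError(ValueError):
    """Endpoint targets cannot be met with non-negative leaf payoffs."""


def _pm20(m: float, cap_probability: bool = False) -> tuple[float, float]:
    """±20% default range; probability-role ranges are clipped to [0, 1]."""
    lo, hi = 0.8 * m, 1.2 * m
    if cap_probability:
        lo, hi = max(0.0, lo), min(1.0, hi)
    return lo, hi


def parameter_specs() -> dict[str, ParameterSpec]:
    """The model's parameter table.

    Test characteristics, population quality of life and the demographic
    parameters are held deterministic (``fixed``); the remaining probabilities
    and utilities take beta and the costs gamma distributions, all with a 0.10
    relative standard error (the sources publish no standard errors; this is
    the package's single documented uncertainty knob).  Ranges follow the
    published ranges where one exists (fracture prevalence 10–25%, pretest
    probability 1.5–2%) and default to ±20% of the point estimate otherwise.
    """
    d = DEFAULT_DISPERSION
    specs = [
        ParameterSpec("prevalence", 0.18, 0.10, 0.25, "probability", "beta", d,
                      "pretest probability of a complex finger fracture in the base case"),
        ParameterSpec("pretest_probability", 0.0175, 0.015, 0.02, "probability", "beta", d,
                      "population pretest probability of a finger fracture (reported range "
                      "1.5-2%); informational — not referenced by the base-case tree"),
        ParameterSpec("p_displacement", 0.12, *_pm20(0.12, True), "probability", "beta", d,
                      "probability that the fracture is displaced"),
        ParameterSpec("p_nonunion", 0.15, *_pm20(0.15, True), "probability", "beta", d,
                      "increased prevalence of non-union for intra-articular fracture"),
        ParameterSpec("p_arthritis", 0.784, *_pm20(0.784, True), "probability", "beta", d,
                      "increased prevalence of arthritis for intra-articular fracture"),
        ParameterSpec("correct_diagnosis", 0.98, *_pm20(0.98, True), "probability", "beta", d,
                      "baseline probability of a correct diagnosis; doubles as the "
                      "specificity of the CR-only work-up (no CR specificity is published)"),
        ParameterSpec("sens_cr", 0.70, *_pm20(0.70, True), "probability", "beta", d,
                      "sensitivity of conventional radiography"),
        ParameterSpec("sens_cbct", 0.96, *_pm20(0.96, True), "probability", "fixed", 0.0,
                      "sensitivity of CBCT (held deterministic)"),
        ParameterSpec("spec_cbct", 0.90, *_pm20(0.90, True), "probability", "fixed", 0.0,
                      "specificity of CBCT (held deterministic)"),
        ParameterSpec("sens_msct", 0.90, *_pm20(0.90, True), "probability", "fixed", 0.0,
                      "sensitivity of MSCT (held deterministic)"),
        ParameterSpec("spec_msct", 0.98, *_pm20(0.98, True), "probability", "fixed", 0.0,
                      "specificity of MSCT (held deterministic)"),
        ParameterSpec("cost_cr", 32.0, *_pm20(32.0), "cost", "gamma", d,
                      "unit cost of plain-film radiography, €"),
        ParameterSpec("cost_cbct", 67.33, *_pm20(67.33), "cost", "gamma", d,
                      "unit cost of CBCT, €"),
        ParameterSpec("cost_msct", 106.23, *_pm20(106.23), "cost", "gamma", d,
                      "unit cost of MSCT, €"),
        ParameterSpec("u_base", 0.85, *_pm20(0.85, True), "utility", "beta", d,
                      "base-case health utility"),
        ParameterSpec("u_population", 0.93, *_pm20(0.93, True), "utility", "fixed", 0.0,
                      "general-population quality of life for 30-year-olds "
                      "(held deterministic)"),
        ParameterSpec("u_immobilization", 0.759, *_pm20(0.759, True), "utility", "beta", d,
                      "utility during immobilization"),
        ParameterSpec("symptom_decrement", 0.03, *_pm20(0.03, True), "utility", "beta", d,
                      "instantaneous utility decrease from residual symptoms (magnitude)"),
        ParameterSpec("age_injury", 35.0, 35.0, 35.0, "other", "fixed", 0.0,
                      "mean age at time of injury, years (held deterministic)"),
        ParameterSpec("age_death", 80.0, 80.0, 80.0, "other", "fixed", 0.0,
                      "mean age at death, years (held deterministic)"),
    ]
    out = {s.name: s for s in specs}
    # Calibrated leaf payoffs (filled in by calibrate_endpoints); role "other"
    # because they live on the compressed strategy-level QALY scale, not [0, 1].
    for strategy in QALY_TARGETS:
        for leaf in _LEAVES:
            name = _leaf_param(strategy, leaf)
            out[name] = ParameterSpec(
                name, 0.0, 0.0, 0.0, "other", "fixed", 0.0,
                f"calibrated terminal QALYs, {strategy} strategy, {leaf} leaf "
                "(synthetic allocation)",
            )
    return out


def _leaf_param(strategy: str, leaf: str) -> str:
    return f"q_{strategy.lower()}_{leaf}"


def _strategy_subtree(strategy: str):
    sens, spec = _STRATEGY_TESTS[strategy]
    cost = P(_STRATEGY_COSTS[strategy])

    def leaf(label: str, key: str):
        return terminal(label, cost, P(_leaf_param(strategy, key)))

    complication_chain = chance("complication", [
        ("displacement", P("p_displacement"), leaf("treated, displacement", "tp_displacement")),
        ("no displacement", one_minus(P("p_displacement")), chance("complication", [
            ("non-union", P("p_nonunion"), leaf("treated, non-union", "tp_nonunion")),
            ("no non-union", one_minus(P("p_nonunion")), chance("complication", [
                ("arthritis", P("p_arthritis"), leaf("treated, arthritis", "tp_arthritis")),
                ("none", one_minus(P("p_arthritis")), leaf("treated, uncomplicated", "tp_none")),
            ])),
        ])),
    ])
    return chance("fracture_status", [
        ("fracture", P("prevalence"), chance("test_result", [
            ("positive", P(sens), complication_chain),
            ("negative", one_minus(P(sens)), leaf("missed fracture", "fn")),
        ])),
        ("no fracture", one_minus(P("prevalence")), chance("test_result", [
            ("positive", one_minus(P(spec)), leaf("false positive", "fp")),
            ("negative", P(spec), leaf("no fracture, correctly ruled out", "tn")),
        ])),
    ])


def default_decrements(specs: dict[str, ParameterSpec]) -> dict[str, float]:
    """Fixed leaf QALY decrements (synthetic allocation).

    Utility losses from the parameter table — the immobilization loss
    (population utility minus immobilization utility) for displacement and
    non-union, the symptom decrement for arthritis and false positives — are
    rescaled by the disease-status QALY gap so they live on the model's
    compressed strategy-level QALY scale.  The missed-fracture (false
    negative) state carries :data:`FN_DELAY_FACTOR` times the
    complication-probability-weighted mean loss, reflecting delayed treatment.
    """
    pt = {name: s.point_estimate for name, s in specs.items()}
    loss_immob = pt["u_population"] - pt["u_immobilization"]
    loss_symptom = pt["symptom_decrement"]
    p_d, p_n, p_a = pt["p_displacement"], pt["p_nonunion"], pt["p_arthritis"]
    weighted_loss = (
        p_d * loss_immob
        + (1 - p_d) * p_n * loss_immob
        + (1 - p_d) * (1 - p_n) * p_a * loss_symptom
    )
    scale = DISEASE_QALY_GAP
    per_leaf = {
        "tp_none": 0.0,
        "tp_displacement": -loss_immob * scale,
        "tp_nonunion": -loss_immob * scale,
        "tp_arthritis": -loss_symptom * scale,
        "fn": -FN_DELAY_FACTOR * weighted_loss * scale,
        "fp": -loss_symptom * scale,
        "tn": 0.0,
    }
    return {
        _leaf_param(strategy, leaf): dec
        for strategy in QALY_TARGETS
        for leaf, dec in per_leaf.items()
    }


def _conditional_leaf_probabilities(node, env) -> list[tuple[str, float]]:
    """(qaly-parameter-name, conditional path probability) for each terminal."""
    from .tree import ChanceNode, TerminalNode
    from .expressions import Param

    out: list[tuple[str, float]] = []

    def walk(n, p):
        if isinstance(n, TerminalNode):
            if not isinstance(n.qaly, Param):
                raise CalibrationError(
                    f"terminal {n.label!r}: calibration needs a bare parameter "
                    "reference as the QALY payoff"
                )
            out.append((n.qaly.name, p))
        elif isinstance(n, ChanceNode):
            for br in n.branches:
                walk(br.node, p * float(br.probability.eval(env)))
        else:
            raise CalibrationError("decision node inside a strategy subtree")

    walk(node, 1.0)
    return out


def calibrate_endpoints(
    tree: DecisionTree,
    targets: dict[str, tuple[float, float]],
    decrements: dict[str, float] | None = None,
    disease_node_label: str = "fracture_status",
    present_branch: str = "fracture",
) -> DecisionTree:
    """Pin per-strategy conditional expected QALYs to endpoint targets.

    For each strategy and each disease branch (absent/present), the leaf
    payoffs are set to ``target - mean_decrement + decrement(leaf)`` where
    ``mean_decrement`` is the conditional-probability-weighted mean of the
    fixed leaf decrements: the relative spread between leaves equals the given
    decrements, and the conditional expectation equals the target exactly.
    The system is underdetermined; this uniform-shift resolution is the
    package's documented choice.  Targets that would force a negative leaf
    payoff raise :class:`CalibrationError`.  The tree is modified in place and
    returned.
    """
    if decrements is None:
        decrements = default_decrements(tree.parameters)
    env = tree.point_estimates()
    for strategy, (t_absent, t_present) in targets.items():
        subtree = tree.subtree(strategy)
        from .tree import ChanceNode

        if not (isinstance(subtree, ChanceNode) and subtree.label == disease_node_label):
            raise CalibrationError(
                f"strategy {strategy!r}: subtree root must be the "
                f"{disease_node_label!r} chance node"
            )
        for br in subtree.branches:
            target = t_present if br.name == present_branch else t_absent
            leaves = _conditional_leaf_probabilities(br.node, env)
            total_p = sum(p for _, p in leaves)
            if total_p <= 0:
                raise CalibrationError(
                    f"strategy {strategy!r}, branch {br.name!r}: no reachable leaves"
                )
            mean_dec = sum(p * decrements.get(name, 0.0) for name, p in leaves) / total_p
            for name, _ in leaves:
                value = target - mean_dec + decrements.get(name, 0.0)
                if value < 0:
                    raise CalibrationError(
                        f"leaf {name!r}: calibrated payoff {value:.4g} < 0 "
                        f"(target {target} infeasible with the given decrements)"
                    )
                tree.set_parameter(name, value)
    return tree


def build_model(calibrated: bool = True) -> DecisionTree:
    """The bundled phalangeal-fracture model, optionally endpoint-calibrated."""
    tree = DecisionTree(
        root=DecisionNode(
            "diagnosis",
            [DecisionBranch(s, _strategy_subtree(s)) for s in QALY_TARGETS],
        ),
        parameters=parameter_specs(),
    )
    if calibrated:
        calibrate_endpoints(tree, QALY_TARGETS)
    return tree


def disease_conditional_qalys(
    tree: DecisionTree, assignment: dict[str, float] | None = None
) -> dict[str, tuple[float, float]]:
    """Per-strategy expected QALYs conditional on disease (absent, present),
    obtained by evaluating the tree at prevalence 0 and 1."""
    env = tree.point_estimates() if assignment is None else dict(assignment)
    absent = evaluate(tree, dict(env, prevalence=0.0))
    present = evaluate(tree, dict(env, prevalence=1.0))
    return {
        s: (float(absent[s][1]), float(present[s][1])) for s in tree.strategies
    }
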