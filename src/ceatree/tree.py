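"""Decision-tree model: node types, structural validation, and expected-value rollback.

The model is a one-period decision tree.  A single :class:`DecisionNode` at the
root enumerates the strategies under comparison; below it, :class:`ChanceNode`
levels carry branch probabilities (expressions over named parameters) and
:class:`TerminalNode` leaves carry a cost (€) and an effectiveness payoff
(QALYs).  Rolling the tree back computes, for every strategy, the expected
cost and expected QALYs per patient — the cohort distributed across the final
health states in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .expressions import Expression, UnboundParameterError, as_expression
from .params import ParameterSpec

PROB_SUM_TOL = 1e-9  # chance-node probabilities must sum to 1 within this


class TreeStructureError(ValueError):
    """The tree violates a structural invariant."""


@dataclass
class TerminalNode:
    """Leaf health state with a cost and a QALY payoff."""

    label: str
    cost: Expression
    qaly: Expression

    def __post_init__(self) -> None:
        self.cost = as_expression(self.cost)
        self.qaly = as_expression(self.qaly)


@dataclass
class ChanceBranch:
    name: str
    probability: Expression
    node: "Node"

    def __post_init__(self) -> None:
        self.probability = as_expression(self.probability)


@dataclass
class ChanceNode:
    """Random event; branch probabilities must sum to one."""

    label: str
    branches: list[ChanceBranch]


@dataclass
class DecisionBranch:
    name: str
    node: "Node"


@dataclass
class DecisionNode:
    """Choice between strategies; only admitted at the root."""

    label: str
    branches: list[DecisionBranch]


Node = TerminalNode | ChanceNode | DecisionNode


def chance(label: str, branches: list[tuple[str, object, Node]]) -> ChanceNode:
    """Build a chance node from ``(name, probability, subtree)`` triples."""
    return ChanceNode(label, [ChanceBranch(n, p, s) for n, p, s in branches])


def terminal(label: str, cost, qaly) -> TerminalNode:
    return TerminalNode(label, cost, qaly)


@dataclass
class StrategyOutcome:
    """Per-strategy expected cost (€) and effectiveness (QALYs) per patient."""

    strategy: str
    expected_cost: float
    expected_qaly: float


@dataclass
class DecisionTree:
    """A decision node over strategies plus the parameter set its expressions reference."""

    root: DecisionNode
    parameters: dict[str, ParameterSpec] = field(default_factory=dict)

    @property
    def strategies(self) -> list[str]:
        return [b.name for b in self.root.branches]

    def subtree(self, strategy: str) -> Node:
        for b in self.root.branches:
            if b.name == strategy:
                return b.node
        raise KeyError(strategy)

    def point_estimates(self) -> dict[str, float]:
        return {name: spec.point_estimate for name, spec in self.parameters.items()}

    def referenced_parameters(self) -> set[str]:
        names: set[str] = set()
        for node in iter_nodes(self.root):
            if isinstance(node, ChanceNode):
                for br in node.branches:
                    names |= br.probability.params()
            elif isinstance(node, TerminalNode):
                names |= node.cost.params()
                names |= node.qaly.params()
        return names

    def set_parameter(self, name: str, value: float) -> None:
        """Move a parameter's point estimate (range widened if needed)."""
        self.parameters[name] = self.parameters[name].with_point(value)


def iter_nodes(node: Node) -> Iterator[Node]:
    """Depth-first, branch-order traversal."""
    yield node
    if isinstance(node, ChanceNode):
        for br in node.branches:
            yield from iter_nodes(br.node)
    elif isinstance(node, DecisionNode):
        for br in node.branches:
            yield from iter_nodes(br.node)


def validate_tree(tree: DecisionTree) -> list[str]:
    """Check structural invariants; return a (possibly empty) list of violations.

    Checks: the root is the unique decision node; the graph is a tree (no node
    object reachable twice); every referenced parameter exists; at the point
    estimates, every chance node's probabilities lie in [0, 1] and sum to 1
    within ``PROB_SUM_TOL``.
    """
    violations: list[str] = []
    if not isinstance(tree.root, DecisionNode):
        violations.append("root must be a decision node")
        return violations
    if len(tree.root.branches) < 1:
        violations.append("root decision node has no strategies")
    seen: set[int] = set()
    for node in iter_nodes(tree.root):
        if id(node) in seen:
            violations.append(
                f"node {getattr(node, 'label', '?')!r} is shared or revisited: "
                "the graph must be a tree"
            )
            continue
        seen.add(id(node))
        if isinstance(node, DecisionNode) and node is not tree.root:
            violations.append(
                f"decision node {node.label!r} below the root: the one-period "
                "model admits exactly one decision node, at the root"
            )
    unbound = tree.referenced_parameters() - set(tree.parameters)
    for name in sorted(unbound):
        violations.append(f"expression references undefined parameter {name!r}")
    if not unbound:
        env = tree.point_estimates()
        for node in iter_nodes(tree.root):
            if not isinstance(node, ChanceNode):
                continue
            probs = [float(br.probability.eval(env)) for br in node.branches]
            for br, p in zip(node.branches, probs):
                if not (0.0 <= p <= 1.0):
                    violations.append(
                        f"chance node {node.label!r}, branch {br.name!r}: "
                        f"probability {p:.6g} outside [0, 1] at point estimates"
                    )
            total = sum(probs)
            if abs(total - 1.0) > PROB_SUM_TOL:
                violations.append(
                    f"chance node {node.label!r}: probabilities sum to {total:.10g}, not 1"
                )
    return violations


def diagnostic_joint_probabilities(
    prevalence: float, sensitivity: float, specificity: float
) -> tuple[float, float, float, float]:
    """Joint probabilities (TP, FN, FP, TN) of disease status and test result.

    ``TP = prevalence * sensitivity``, ``FN = prevalence * (1 - sensitivity)``,
    ``FP = (1 - prevalence) * (1 - specificity)``,
    ``TN = (1 - prevalence) * specificity``; the four sum to one.
    """
    for label, v in (
        ("prevalence", prevalence),
        ("sensitivity", sensitivity),
        ("specificity", specificity),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{label} must lie in [0, 1], got {v}")
    tp = prevalence * sensitivity
    fn = prevalence * (1.0 - sensitivity)
    fp = (1.0 - prevalence) * (1.0 - specificity)
    tn = (1.0 - prevalence) * specificity
    return tp, fn, fp, tn


def _expected(node: Node, env: Mapping[str, object]):
    """Expected (cost, qaly) of a subtree; values broadcast over array draws."""
    if isinstance(node, TerminalNode):
        return node.cost.eval(env), node.qaly.eval(env)
    if isinstance(node, ChanceNode):
        cost = 0.0
        qaly = 0.0
        for br in node.branches:
            p = br.probability.eval(env)
            c, q = _expected(br.node, env)
            cost = cost + p * c
            qaly = qaly + p * q
        return cost, qaly
    raise TreeStructureError("decision node encountered below the root during rollback")


def evaluate(tree: DecisionTree, env: Mapping[str, object]) -> dict[str, tuple]:
    """Per-strategy expected (cost, qaly) at an arbitrary assignment.

    Environment values may be scalars or equal-length NumPy arrays; in the
    array case the returned pairs are arrays (one rollback per draw).
    """
    missing = tree.referenced_parameters() - set(env)
    if missing:
        raise UnboundParameterError(
            f"assignment missing parameters: {sorted(missing)}"
        )
    return {b.name: _expected(b.node, env) for b in tree.root.branches}


def rollback(
    tree: DecisionTree, assignment: Mapping[str, float] | None = None
) -> dict[str, StrategyOutcome]:
    """Expected-value rollback: one :class:`StrategyOutcome` per strategy.

    With no assignment the tree's point estimates are used.  Raises
    :class:`TreeStructureError` if the tree fails validation, and
    :class:`~ceatree.expressions.UnboundParameterError` on a missing parameter.
    """
    violations = validate_tree(tree)
    if violations:
        raise TreeStructureError("; ".join(violations))
    env = tree.point_estimates() if assignment is None else dict(assignment)
    results = evaluate(tree, env)
    return {
        name: StrategyOutcome(name, float(c), float(q))
        for name, (c, q) in results.items()
    }


def chance_probabilities(tree: DecisionTree, env: Mapping[str, object]):
    """Yield (node label, branch name, probability) for every chance branch.

    Used by the PSA rejection step: under sampled parameters every branch
    probability must remain in [0, 1].
    """
    for node in iter_nodes(tree.root):
        if isinstance(node, ChanceNode):
            for br in node.branches:
                yield node.label, br.name, br.probability.eval(env)
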