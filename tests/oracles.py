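"""Independent oracles for the test suite.

``expected_by_enumeration`` recomputes strategy expectations by brute-force
root-to-leaf path enumeration (sum over paths of probability-product times
payoff), deliberately sharing no aggregation code with the recursive rollback
it validates.  ``random_tree`` generates small random valid decision trees.
"""

from __future__ import annotations

import itertools

import numpy as np

from ceatree.expressions import P, one_minus
from ceatree.params import ParameterSpec
from ceatree.tree import (
    ChanceNode,
    DecisionBranch,
    DecisionNode,
    DecisionTree,
    TerminalNode,
    chance,
    terminal,
)


def _paths(node, env, prob):
    if isinstance(node, TerminalNode):
        yield prob, float(node.cost.eval(env)), float(node.qaly.eval(env))
    elif isinstance(node, ChanceNode):
        for br in node.branches:
            yield from _paths(br.node, env, prob * float(br.probability.eval(env)))
    else:
        raise AssertionError("decision node below root")


def expected_by_enumeration(tree: DecisionTree, env=None):
    """Per-strategy (expected cost, expected qaly) by path enumeration."""
    if env is None:
        env = tree.point_estimates()
    out = {}
    for br in tree.root.branches:
        paths = list(_paths(br.node, env, 1.0))
        out[br.name] = (
            sum(p * c for p, c, _ in paths),
            sum(p * q for p, _, q in paths),
        )
    return out


def random_tree(rng: np.random.Generator, max_depth: int = 3) -> DecisionTree:
    """A small random valid tree: 2-3 strategies, mixed constant and
    parameter-referencing probabilities, random terminal payoffs."""
    params: dict[str, ParameterSpec] = {}
    counter = itertools.count()

    def make_node(depth):
        if depth >= max_depth or rng.random() < 0.3:
            return terminal(
                f"leaf{next(counter)}",
                float(rng.uniform(0.0, 200.0)),
                float(rng.uniform(0.0, 10.0)),
            )
        k = int(rng.integers(2, 4))
        if k == 2 and rng.random() < 0.5:
            name = f"p{next(counter)}"
            params[name] = ParameterSpec(
                name, float(rng.uniform(0.05, 0.95)), 0.0, 1.0,
                "probability", "beta", 0.1,
            )
            probs = [P(name), one_minus(P(name))]
        else:
            probs = [float(w) for w in rng.dirichlet(np.ones(k))]
        return chance(
            f"c{next(counter)}",
            [(f"b{i}", probs[i], make_node(depth + 1)) for i in range(k)],
        )

    n_strat = int(rng.integers(2, 4))
    root = DecisionNode(
        "root", [DecisionBranch(f"s{i}", make_node(1)) for i in range(n_strat)]
    )
    return DecisionTree(root=root, parameters=params)
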