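"""Patient-level microsimulation: an independent stochastic oracle for rollback.

Instead of computing expectations analytically, a cohort of individual
patients is routed through every strategy's subtree by categorical draws at
each chance node.  By the law of large numbers the per-strategy mean cost and
mean QALYs converge to the rollback expectations, which makes the
microsimulation a validation oracle for the analytic engine (and a generator
of realistic patient-level records: fracture status at the stated prevalence,
test outcome via sensitivity/specificity, complication, accrued cost and
QALYs).

Draw order is fixed — patient sex first, then strategies in root order, each
subtree in depth-first branch order — so a seed fully determines the output.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .tree import (
    ChanceNode,
    DecisionTree,
    Node,
    TerminalNode,
    TreeStructureError,
    validate_tree,
)

# Branch-name conventions used by the bundled fixture; recognised labels are
# lifted into typed record columns, unknown labels are simply ignored.
_FRACTURE_LABEL = "fracture_status"
_TEST_LABEL = "test_result"
_COMPLICATION_LABEL = "complication"
_COMPLICATIONS = {"displacement", "non-union", "arthritis", "none"}


def _route(
    node: Node,
    idx: np.ndarray,
    env: Mapping[str, float],
    rng: np.random.Generator,
    cols: dict[str, np.ndarray],
) -> None:
    if isinstance(node, TerminalNode):
        cols["accrued_cost"][idx] = float(node.cost.eval(env))
        cols["accrued_qaly"][idx] = float(node.qaly.eval(env))
        cols["terminal"][idx] = node.label
        return
    if not isinstance(node, ChanceNode):
        raise TreeStructureError("decision node below the root during microsimulation")
    probs = np.array([float(br.probability.eval(env)) for br in node.branches])
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise TreeStructureError(
            f"chance node {node.label!r}: inadmissible probabilities {probs}"
        )
    edges = np.cumsum(probs)
    edges[-1] = 1.0  # guard against round-off at the top edge
    u = rng.random(idx.size)
    choice = np.searchsorted(edges, u, side="right")
    for k, br in enumerate(node.branches):
        sub = idx[choice == k]
        if sub.size == 0:
            continue
        if node.label == _FRACTURE_LABEL:
            cols["true_fracture"][sub] = br.name == "fracture"
        elif node.label == _TEST_LABEL:
            cols["test_result"][sub] = br.name == "positive"
        elif node.label == _COMPLICATION_LABEL and br.name in _COMPLICATIONS:
            cols["complication"][sub] = br.name
        _route(br.node, sub, env, rng, cols)


def microsimulate(
    tree: DecisionTree,
    n: int,
    seed: int,
    assignment: Mapping[str, float] | None = None,
    male_fraction: float = 2.0 / 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``n`` patients through every strategy subtree.

    Returns ``(records, summary)``: one record per patient per strategy with
    the realised path (fracture status, test result, complication where the
    tree labels expose them, accrued cost and QALYs, and patient sex — drawn
    2:1 male by default, carried as metadata only), and a per-strategy summary
    of mean cost and mean QALYs.

    Chance draws are independent across patients, nodes and strategies; the
    probabilities come from ``assignment`` (default: point estimates).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    violations = validate_tree(tree)
    if violations:
        raise TreeStructureError("; ".join(violations))
    env = tree.point_estimates() if assignment is None else dict(assignment)
    rng = np.random.default_rng(seed)
    sex = np.where(rng.random(n) < male_fraction, "male", "female")

    frames = []
    all_idx = np.arange(n)
    for branch in tree.root.branches:
        cols = {
            "accrued_cost": np.full(n, np.nan),
            "accrued_qaly": np.full(n, np.nan),
            "terminal": np.full(n, "", dtype=object),
            "true_fracture": np.full(n, None, dtype=object),
            "test_result": np.full(n, None, dtype=object),
            "complication": np.full(n, None, dtype=object),
        }
        _route(branch.node, all_idx, env, rng, cols)
        frames.append(
            pd.DataFrame(
                {
                    "patient": all_idx,
                    "sex": sex,
                    "strategy": branch.name,
                    "true_fracture": cols["true_fracture"],
                    "test_result": cols["test_result"],
                    "complication": cols["complication"],
                    "terminal": cols["terminal"],
                    "accrued_cost": cols["accrued_cost"],
                    "accrued_qaly": cols["accrued_qaly"],
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    summary = (
        records.groupby("strategy", sort=False)
        .agg(
            n=("patient", "size"),
            mean_cost=("accrued_cost", "mean"),
            mean_qaly=("accrued_qaly", "mean"),
            sd_cost=("accrued_cost", "std"),
            sd_qaly=("accrued_qaly", "std"),
        )
        .reset_index()
    )
    return records, summary
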