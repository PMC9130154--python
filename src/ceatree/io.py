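"""Model configuration I/O: the JSON document format.

A model file has three top-level keys: ``parameters`` (a list of parameter
records), ``strategies`` (names; the order defines report order) and ``tree``
(the nested node structure).  Node objects carry ``kind`` ("decision",
"chance" or "terminal"), a ``label``, and either ``branches`` (with ``name``
and, for chance branches, a ``probability`` expression) or, for terminals,
``cost`` and ``qaly`` expressions.  Expressions use the JSON forms of
:mod:`ceatree.expressions`.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import expressions
from .params import ParameterSpec
from .tree import (
    ChanceBranch,
    ChanceNode,
    DecisionBranch,
    DecisionNode,
    DecisionTree,
    Node,
    TerminalNode,
)


def node_to_dict(node: Node) -> dict:
    if isinstance(node, TerminalNode):
        return {
            "kind": "terminal",
            "label": node.label,
            "cost": node.cost.to_json(),
            "qaly": node.qaly.to_json(),
        }
    if isinstance(node, ChanceNode):
        return {
            "kind": "chance",
            "label": node.label,
            "branches": [
                {
                    "name": br.name,
                    "probability": br.probability.to_json(),
                    "node": node_to_dict(br.node),
                }
                for br in node.branches
            ],
        }
    if isinstance(node, DecisionNode):
        return {
            "kind": "decision",
            "label": node.label,
            "branches": [
                {"name": br.name, "node": node_to_dict(br.node)} for br in node.branches
            ],
        }
    raise TypeError(f"unknown node type {type(node).__name__}")


def node_from_dict(d: dict) -> Node:
    kind = d.get("kind")
    if kind == "terminal":
        return TerminalNode(
            label=d.get("label", ""),
            cost=expressions.from_json(d["cost"]),
            qaly=expressions.from_json(d["qaly"]),
        )
    if kind == "chance":
        return ChanceNode(
            label=d.get("label", ""),
            branches=[
                ChanceBranch(
                    name=br["name"],
                    probability=expressions.from_json(br["probability"]),
                    node=node_from_dict(br["node"]),
                )
                for br in d["branches"]
            ],
        )
    if kind == "decision":
        return DecisionNode(
            label=d.get("label", ""),
            branches=[
                DecisionBranch(name=br["name"], node=node_from_dict(br["node"]))
                for br in d["branches"]
            ],
        )
    raise ValueError(f"unknown node kind {kind!r}")


def tree_to_dict(tree: DecisionTree) -> dict:
    return {
        "strategies": tree.strategies,
        "parameters": [spec.to_dict() for spec in tree.parameters.values()],
        "tree": node_to_dict(tree.root),
    }


def tree_from_dict(d: dict) -> DecisionTree:
    root = node_from_dict(d["tree"])
    if not isinstance(root, DecisionNode):
        raise ValueError("model root must be a decision node")
    params = {p["name"]: ParameterSpec.from_dict(p) for p in d.get("parameters", [])}
    tree = DecisionTree(root=root, parameters=params)
    declared = d.get("strategies")
    if declared is not None and list(declared) != tree.strategies:
        # Honour the declared report order where it is a permutation.
        if sorted(declared) != sorted(tree.strategies):
            raise ValueError(
                f"strategies key {declared} does not match tree branches {tree.strategies}"
            )
        by_name = {br.name: br for br in root.branches}
        root.branches = [by_name[name] for name in declared]
    return tree


def save_model(tree: DecisionTree, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree_to_dict(tree), indent=2) + "\n")


def load_model(path: str | Path) -> DecisionTree:
    return tree_from_dict(json.loads(Path(path).read_text()))
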