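"""Decision-tree containers and serialization (JSON round-trip, DOT, text).

A tree node jointly records a biomarker split and, through its branches,
the drug recommended on each side.  Leaves are plain drug-name strings.
Binary splits (mutation present/absent) carry no threshold; continuous
splits route patients with ``x >= threshold`` to the true branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Union

__all__ = ["DecisionNode", "DecisionTree", "read_tree", "write_tree"]

from .exceptions import NotFittedError, TreeSchemaError

Child = Union["DecisionNode", str]


@dataclass
class DecisionNode:
    marker: str
    threshold: float | None
    if_true: Child
    if_false: Child
    n_patients: int | None = None
    # fit-time A + B on the benefit scale; a diagnostic, excluded from
    # equality so identical structures compare equal across summation orders
    objective: float | None = field(default=None, compare=False)

    @property
    def kind(self) -> str:
        return "binary" if self.threshold is None else "continuous"

    def __post_init__(self) -> None:
        if self.threshold is not None:
            self.threshold = float(self.threshold)
            if not (self.threshold == self.threshold and abs(self.threshold) != float("inf")):
                raise TreeSchemaError("continuous split threshold must be finite")
        if isinstance(self.if_true, str) and isinstance(self.if_false, str):
            if self.if_true == self.if_false:
                raise TreeSchemaError(
                    f"node on {self.marker!r} has the same leaf drug "
                    f"{self.if_true!r} on both branches (should have collapsed)"
                )


@dataclass
class DecisionTree:
    """A fitted optimal decision tree (or a single-leaf constant policy)."""

    root: Child
    min_group_size: int = 10
    response_transform: str = "identity"  # identity | signed_sqrt
    sense: str = "minimize"  # sense of the *input* scale

    def __post_init__(self) -> None:
        if self.response_transform not in ("identity", "signed_sqrt"):
            raise TreeSchemaError(f"unknown transform {self.response_transform!r}")
        if self.sense not in ("minimize", "maximize"):
            raise TreeSchemaError(f"unknown sense {self.sense!r}")
        self._check_marker_reuse(self.root, frozenset())

    @staticmethod
    def _check_marker_reuse(node: Child, used: frozenset) -> None:
        if isinstance(node, str):
            return
        if node.marker in used:
            raise TreeSchemaError(
                f"marker {node.marker!r} used more than once on a root-to-leaf path"
            )
        for child in (node.if_true, node.if_false):
            DecisionTree._check_marker_reuse(child, used | {node.marker})

    # -- structure queries --------------------------------------------
    def nodes(self) -> Iterator[DecisionNode]:
        stack: list[Child] = [self.root]
        while stack:
            n = stack.pop()
            if isinstance(n, DecisionNode):
                yield n
                stack.extend([n.if_false, n.if_true])

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(n: Child) -> None:
            if isinstance(n, str):
                out.append(n)
            else:
                walk(n.if_true)
                walk(n.if_false)

        walk(self.root)
        return out

    def markers_used(self) -> list[str]:
        seen: dict[str, None] = {}
        for n in self.nodes():
            seen.setdefault(n.marker, None)
        return list(seen)

    def depth(self) -> int:
        def d(n: Child) -> int:
            return 0 if isinstance(n, str) else 1 + max(d(n.if_true), d(n.if_false))

        return d(self.root)

    def n_splits(self) -> int:
        return sum(1 for _ in self.nodes())


# ---------------------------------------------------------------------------
# serialization


def _node_to_dict(node: Child) -> dict:
    if isinstance(node, str):
        return {"type": "leaf", "drug": node}
    d = {
        "type": "split",
        "marker": node.marker,
        "kind": node.kind,
        "threshold": node.threshold,
        "if_true": _node_to_dict(node.if_true),
        "if_false": _node_to_dict(node.if_false),
    }
    if node.n_patients is not None:
        d["n_patients"] = node.n_patients
    if node.objective is not None:
        d["objective"] = node.objective
    return d


def _node_from_dict(d: dict, drug_names: list[str] | None) -> Child:
    if not isinstance(d, dict) or "type" not in d:
        raise TreeSchemaError(f"malformed node: {d!r}")
    if d["type"] == "leaf":
        drug = d.get("drug")
        if not isinstance(drug, str):
            raise TreeSchemaError("leaf without a drug name")
        if drug_names is not None and drug not in drug_names:
            raise TreeSchemaError(f"leaf drug {drug!r} not in the supplied drug set")
        return drug
    if d["type"] != "split":
        raise TreeSchemaError(f"unknown node type {d['type']!r}")
    kind = d.get("kind")
    threshold = d.get("threshold")
    if kind == "binary" and threshold is not None:
        raise TreeSchemaError(
            f"binary split on {d.get('marker')!r} must not carry a threshold"
        )
    if kind == "continuous" and threshold is None:
        raise TreeSchemaError(
            f"continuous split on {d.get('marker')!r} requires a threshold"
        )
    try:
        return DecisionNode(
            marker=str(d["marker"]),
            threshold=threshold,
            if_true=_node_from_dict(d["if_true"], drug_names),
            if_false=_node_from_dict(d["if_false"], drug_names),
            n_patients=d.get("n_patients"),
            objective=d.get("objective"),
        )
    except KeyError as e:
        raise TreeSchemaError(f"split node missing field {e}") from None


def write_tree(tree: DecisionTree, format: str = "json") -> str:
    """Serialize a fitted tree as ``json`` (lossless), ``dot`` or ``text``."""
    if tree.root is None:
        raise NotFittedError("tree has no root; fit it first")
    if format == "json":
        payload = {
            "min_group_size": tree.min_group_size,
            "transform": tree.response_transform,
            "sense": tree.sense,
            "root": _node_to_dict(tree.root),
        }
        return json.dumps(payload, indent=2, sort_keys=True)
    if format == "dot":
        return _to_dot(tree)
    if format == "text":
        return _to_text(tree)
    raise ValueError(f"unknown format {format!r}")


def read_tree(serialized: str, drug_names: list[str] | None = None) -> DecisionTree:
    """Inverse of ``write_tree(..., format='json')``.

    If ``drug_names`` is given, every leaf drug must belong to it.
    """
    try:
        payload = json.loads(serialized)
    except json.JSONDecodeError as e:
        raise TreeSchemaError(f"invalid JSON: {e}") from None
    if not isinstance(payload, dict) or "root" not in payload:
        raise TreeSchemaError("tree JSON must be an object with a 'root' field")
    return DecisionTree(
        root=_node_from_dict(payload["root"], drug_names),
        min_group_size=int(payload.get("min_group_size", 10)),
        response_transform=payload.get("transform", "identity"),
        sense=payload.get("sense", "minimize"),
    )


def _split_label(node: DecisionNode) -> str:
    if node.threshold is None:
        return f"{node.marker} == 1"
    return f"{node.marker} >= {node.threshold:g}"


def _to_dot(tree: DecisionTree) -> str:
    lines = ["digraph odt {", "  node [fontname=Helvetica];"]
    counter = [0]

    def walk(node: Child) -> str:
        name = f"n{counter[0]}"
        counter[0] += 1
        if isinstance(node, str):
            lines.append(f'  {name} [label="{node}", shape=box];')
        else:
            extra = f"\\nn={node.n_patients}" if node.n_patients is not None else ""
            lines.append(f'  {name} [label="{_split_label(node)}{extra}", shape=ellipse];')
            t = walk(node.if_true)
            f = walk(node.if_false)
            lines.append(f'  {name} -> {t} [label="true"];')
            lines.append(f'  {name} -> {f} [label="false"];')
        return name

    walk(tree.root)
    lines.append("}")
    return "\n".join(lines)


def _to_text(tree: DecisionTree) -> str:
    lines: list[str] = []

    def walk(node: Child, indent: int, prefix: str) -> None:
        pad = "  " * indent
        if isinstance(node, str):
            lines.append(f"{pad}{prefix}<{node}>")
            return
        n = f" (n={node.n_patients})" if node.n_patients is not None else ""
        lines.append(f"{pad}{prefix}{_split_label(node)}?{n}")
        walk(node.if_true, indent + 1, "yes: ")
        walk(node.if_false, indent + 1, "no:  ")

    walk(tree.root, 0, "")
    return "\n".join(lines)
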