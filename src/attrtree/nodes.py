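"""Addresses for nodes of the infinitely deep, infinitely branching tree.

A node is identified by the sequence of 1-based child indices on the path
from the root: ``()`` is the root, ``(2,)`` its second child, ``(2, 1)``
that child's first child, and so on.  Tuples compare lexicographically,
which gives a deterministic total order used throughout the samplers.
"""

from __future__ import annotations

from typing import Iterator, Tuple

NodeId = Tuple[int, ...]

ROOT: NodeId = ()


def depth(node: NodeId) -> int:
    return len(node)


def parent(node: NodeId) -> NodeId:
    if not node:
        raise ValueError("root has no parent")
    return node[:-1]


def child(node: NodeId, index: int) -> NodeId:
    if index < 1:
        raise ValueError("child indices are 1-based")
    return node + (index,)


def ancestors(node: NodeId) -> Iterator[NodeId]:
    """Yield the strict ancestors of ``node``, root first."""
    for k in range(len(node)):
        yield node[:k]


def path(node: NodeId) -> Iterator[NodeId]:
    """Yield the root-to-node path inclusive, root first."""
    for k in range(len(node) + 1):
        yield node[:k]


def is_ancestor(a: NodeId, b: NodeId) -> bool:
    """True iff ``a`` is a strict ancestor of ``b``."""
    return len(a) < len(b) and b[: len(a)] == a


def in_subtree(a: NodeId, b: NodeId) -> bool:
    """True iff ``b`` lies in the subtree rooted at ``a`` (inclusive)."""
    return b[: len(a)] == a


def path_str(node: NodeId) -> str:
    """Serialize as dot-joined 0-based child indices; the root is ''."""
    return ".".join(str(i - 1) for i in node)


def parse_path(text: str) -> NodeId:
    if text == "":
        return ROOT
    parts = text.split(".")
    out = []
    for p in parts:
        i = int(p)
        if i < 0:
            raise ValueError(f"invalid node path {text!r}")
        out.append(i + 1)
    return tuple(out)
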