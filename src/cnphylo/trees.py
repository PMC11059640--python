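"""Rooted ultrametric time trees with branch-rate annotations.

The tree container used throughout the package: a rooted binary tree whose
nodes carry heights (time before sampling; leaves at height 0), per-branch
random-local-clock annotations (a rate-change indicator and a rate
multiplier), and a root stem of length ``root_stem_d`` connecting the
most recent common ancestor of the sampled cells to their diploid ancestor.

A branch is identified with its child node; the stem is the branch above the
root.  The *effective* length of a branch, used by the copy-number transition
kernel, is its time duration multiplied by the branch's effective clock rate
(the multiplier of the nearest ancestor-or-self branch whose indicator is on,
else 1; the stem always uses rate 1).
"""

from __future__ import annotations

import re
from typing import Callable, Iterator

import numpy as np

__all__ = [
    "TreeNode",
    "RootedTimeTree",
    "random_ultrametric_tree",
    "upgma_tree",
]


class TreeNode:
    """Node of a :class:`RootedTimeTree`; also represents the branch above it."""

    __slots__ = ("parent", "children", "height", "rate_multiplier",
                 "rate_change", "label", "id")

    def __init__(self, label: str | None = None, height: float = 0.0):
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []
        self.height = float(height)
        self.rate_multiplier = 1.0
        self.rate_change = False
        self.label = label
        self.id: int = -1

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.label!r}, h={self.height:.4g})"


class RootedTimeTree:
    """Rooted binary ultrametric tree with node heights and a diploid stem.

    Parameters
    ----------
    root:
        Root node (the MRCA of the sampled cells).
    root_stem_d:
        Time from the diploid ancestor down to the root.
    """

    def __init__(self, root: TreeNode, root_stem_d: float = 0.5):
        self.root = root
        self.root_stem_d = float(root_stem_d)
        self.reindex()

    # ------------------------------------------------------------------
    # traversal and bookkeeping
    # ------------------------------------------------------------------
    def reindex(self) -> None:
        """Assign stable postorder ids; leaves keep their labels."""
        for i, node in enumerate(self.postorder()):
            node.id = i

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))
        return out

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def nodes(self) -> list[TreeNode]:
        return self.postorder()

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    # ------------------------------------------------------------------
    # branch quantities
    # ------------------------------------------------------------------
    def branch_duration(self, node: TreeNode) -> float:
        if node.is_root:
            return self.root_stem_d
        return node.parent.height - node.height

    def effective_rate(self, node: TreeNode) -> float:
        """Random-local-clock rate of the branch above ``node``.

        Nearest ancestor-or-self branch with an active indicator supplies the
        multiplier; the stem (root branch) always has rate 1.
        """
        cur = node
        while cur is not None and not cur.is_root:
            if cur.rate_change:
                return cur.rate_multiplier
            cur = cur.parent
        return 1.0

    def effective_branch_length(self, node: TreeNode) -> float:
        if node.is_root:
            return self.root_stem_d
        return self.branch_duration(node) * self.effective_rate(node)

    def n_rate_changes(self) -> int:
        return sum(1 for n in self.postorder() if not n.is_root and n.rate_change)

    # ------------------------------------------------------------------
    # clades
    # ------------------------------------------------------------------
    def clade_map(self) -> dict[TreeNode, frozenset]:
        """Map every node to the frozenset of leaf labels beneath it."""
        out: dict[TreeNode, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[node] = frozenset([node.label])
            else:
                s: frozenset = frozenset()
                for c in node.children:
                    s = s | out[c]
                out[node] = s
        return out

    def clades(self, include_leaves: bool = False) -> set[frozenset]:
        cm = self.clade_map()
        return {cl for n, cl in cm.items() if include_leaves or not n.is_leaf}

    def clade_heights(self) -> dict[frozenset, float]:
        cm = self.clade_map()
        return {cl: n.height for n, cl in cm.items() if not n.is_leaf}

    # ------------------------------------------------------------------
    # structure checks / copying
    # ------------------------------------------------------------------
    def validate(self) -> None:
        for node in self.postorder():
            if node.children and len(node.children) != 2:
                raise ValueError("tree is not binary")
            if node.is_leaf and abs(node.height) > 1e-12:
                raise ValueError("leaf heights must be 0 (ultrametric sampling)")
            if not node.is_root and not node.parent.height > node.height:
                raise ValueError("child height must be below parent height")
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate leaf labels")

    def copy(self) -> "RootedTimeTree":
        def rec(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.height)
            new.rate_multiplier = node.rate_multiplier
            new.rate_change = node.rate_change
            new.id = node.id
            for c in node.children:
                new.add_child(rec(c))
            return new

        t = RootedTimeTree.__new__(RootedTimeTree)
        t.root = rec(self.root)
        t.root_stem_d = self.root_stem_d
        return t

    # ------------------------------------------------------------------
    # Newick serialization
    # ------------------------------------------------------------------
    def to_newick(self, annotations: bool = False, include_stem: bool = True,
                  digits: int = 12) -> str:
        def fmt(x: float) -> str:
            return f"{x:.{digits}g}"

        def rec(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.label or ""
            else:
                core = "(" + ",".join(rec(c) for c in node.children) + ")"
                if node.label:
                    core += node.label
            if annotations:
                core += (f"[&rate={fmt(node.rate_multiplier)},"
                         f"change={1 if node.rate_change else 0}]")
            blen = self.root_stem_d if node.is_root else self.branch_duration(node)
            if node.is_root and not include_stem:
                return core
            return core + ":" + fmt(blen)

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "RootedTimeTree":
        """Parse a Newick string (optionally with [&rate=..,change=..] comments).

        Heights are reconstructed from branch lengths assuming leaves at
        height 0; a trailing length on the root is taken as the stem length.
        """
        text = text.strip()
        if not text.endswith(";"):
            raise ValueError("Newick string must end with ';'")
        s = text[:-1]
        pos = 0
        edge_len: dict[int, float] = {}

        token_re = re.compile(r"[^,():\[\];]+")

        def parse_clause() -> tuple[TreeNode, float | None]:
            nonlocal pos
            node = TreeNode()
            if pos < len(s) and s[pos] == "(":
                pos += 1
                while True:
                    child, blen = parse_clause()
                    node.add_child(child)
                    edge_len[id(child)] = blen if blen is not None else 0.0
                    if pos >= len(s):
                        raise ValueError(f"unmatched parenthesis at position {pos}")
                    if s[pos] == ",":
                        pos += 1
                        continue
                    if s[pos] == ")":
                        pos += 1
                        break
                    raise ValueError(f"unexpected character {s[pos]!r} at position {pos}")
            m = token_re.match(s, pos)
            if m:
                node.label = m.group(0)
                pos = m.end()
            if pos < len(s) and s[pos] == "[":
                end = s.find("]", pos)
                if end < 0:
                    raise ValueError(f"unterminated comment at position {pos}")
                comment = s[pos + 1:end]
                pos = end + 1
                for kv in comment.lstrip("&").split(","):
                    if "=" not in kv:
                        continue
                    key, val = kv.split("=", 1)
                    if key == "rate":
                        node.rate_multiplier = float(val)
                    elif key == "change":
                        node.rate_change = bool(int(float(val)))
            blen: float | None = None
            if pos < len(s) and s[pos] == ":":
                pos += 1
                m = token_re.match(s, pos)
                if not m:
                    raise ValueError(f"missing branch length at position {pos}")
                blen = float(m.group(0))
                pos = m.end()
            return node, blen

        root, stem = parse_clause()
        if pos != len(s):
            raise ValueError(f"trailing characters at position {pos}")

        # depths -> heights (leaves at 0)
        depth: dict[TreeNode, float] = {root: 0.0}
        order: list[TreeNode] = []
        stack = [root]
        while stack:
            n = stack.pop()
            order.append(n)
            for c in n.children:
                depth[c] = depth[n] + edge_len.get(id(c), 0.0)
                stack.append(c)
        maxd = max(depth.values())
        for n in order:
            n.height = maxd - depth[n]
        for n in order:
            if n.is_leaf:
                n.height = 0.0
        tree = cls(root, root_stem_d=stem if stem is not None else 0.5)
        return tree


# ----------------------------------------------------------------------
# tree generators
# ----------------------------------------------------------------------

def random_ultrametric_tree(n_leaves: int, rng: np.random.Generator,
                            root_height: float = 1.0,
                            labels: list[str] | None = None,
                            root_stem_d: float = 0.5) -> RootedTimeTree:
    """Random binary ultrametric tree via sequential pairwise coalescence.

    Merge times are i.i.d. uniform order statistics rescaled so the last
    coalescence sits at ``root_height``; pairs to merge are chosen uniformly.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    if labels is None:
        labels = [f"cell{i}" for i in range(n_leaves)]
    active = [TreeNode(lbl, 0.0) for lbl in labels]
    heights = np.sort(rng.uniform(0.0, 1.0, size=n_leaves - 1))
    heights = heights / heights[-1] * root_height
    for h in heights:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[i], active[j]
        parent = TreeNode(height=float(h))
        parent.add_child(a)
        parent.add_child(b)
        active = [n for idx, n in enumerate(active) if idx not in (i, j)]
        active.append(parent)
    return RootedTimeTree(active[0], root_stem_d=root_stem_d)


def upgma_tree(dist: np.ndarray, labels: list[str],
               root_stem_d: float = 0.5) -> RootedTimeTree:
    """Ultrametric tree by average-linkage clustering of a distance matrix.

    Used as a deterministic MCMC starting tree; heights are half the linkage
    merge distances, perturbed minimally to keep parent > child strict.
    """
    from scipy.cluster.hierarchy import average
    from scipy.spatial.distance import squareform

    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    Z = average(squareform(dist, checks=False))
    nodes: dict[int, TreeNode] = {i: TreeNode(labels[i], 0.0) for i in range(n)}
    eps = max(1e-9, float(dist.max()) * 1e-9) if dist.max() > 0 else 1e-9
    for m, (a, b, h, _cnt) in enumerate(Z):
        parent = TreeNode(height=h / 2.0)
        ca, cb = nodes[int(a)], nodes[int(b)]
        floor = max(ca.height, cb.height)
        if parent.height <= floor:
            parent.height = floor + eps
        parent.add_child(ca)
        parent.add_child(cb)
        nodes[n + m] = parent
    return RootedTimeTree(nodes[n + len(Z) - 1], root_stem_d=root_stem_d)
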