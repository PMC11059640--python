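"""Posterior summarization and evaluation statistics.

Summaries: maximum clade credibility (MCC) tree — the sampled tree
maximizing the product of its clades' posterior frequencies — with median
node heights per clade, clade supports, and highest-posterior-density (HPD)
intervals.  Evaluation: no-intercept OLS scaling between inferred and true
node heights, branch true-positive rate by true-branch-length decile,
min-max-normalized pairwise-distance error in mutation units, HPD coverage
of true node heights, and per-profile Hamming/L1 errors (in
:mod:`cnphylo.ancestral`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .trees import RootedTimeTree, TreeNode

__all__ = [
    "CladeSet",
    "mcc_tree",
    "median_node_heights",
    "hpd_interval",
    "ols_scale",
    "matched_clade_heights",
    "branch_tpr_by_decile",
    "pairwise_mutation_distances",
    "normalized_pairwise_distance_error",
    "posterior_coverage",
]


@dataclass
class CladeSet:
    """Clade posterior frequencies and per-sample node heights.

    Keys are frozensets of leaf labels; ``frequency[c]`` is the proportion of
    sampled trees containing clade ``c``; ``heights[c]`` lists the clade's
    node height in each tree that contains it.
    """

    n_samples: int
    frequency: dict[frozenset, float] = field(default_factory=dict)
    heights: dict[frozenset, list[float]] = field(default_factory=dict)

    @classmethod
    def from_samples(cls, samples: list[RootedTimeTree]) -> "CladeSet":
        if not samples:
            raise ValueError("need at least one sampled tree")
        leaf_sets = {frozenset(t.leaf_labels()) for t in samples}
        if len(leaf_sets) != 1:
            raise ValueError("sampled trees have inconsistent leaf sets")
        counts: dict[frozenset, int] = {}
        heights: dict[frozenset, list[float]] = {}
        for t in samples:
            for cl, h in t.clade_heights().items():
                counts[cl] = counts.get(cl, 0) + 1
                heights.setdefault(cl, []).append(h)
        n = len(samples)
        return cls(n, {cl: c / n for cl, c in counts.items()}, heights)


def mcc_tree(samples: list[RootedTimeTree]) -> tuple[RootedTimeTree, dict[frozenset, float]]:
    """Maximum clade credibility tree among the samples, with clade supports.

    Returns a copy of the best sampled tree and the mapping from each of its
    clades to that clade's posterior frequency.
    """
    cs = CladeSet.from_samples(samples)
    best, best_score = None, -np.inf
    for t in samples:
        score = sum(math.log(cs.frequency[cl]) for cl in t.clades())
        if score > best_score:
            best, best_score = t, score
    tree = best.copy()
    supports = {cl: cs.frequency[cl] for cl in tree.clades()}
    return tree, supports


def median_node_heights(mcc: RootedTimeTree,
                        samples: list[RootedTimeTree]
                        ) -> tuple[RootedTimeTree, list[frozenset]]:
    """Annotate the MCC tree with per-clade median heights across samples.

    Each clade's height becomes the median over the samples containing it.
    Medians can violate parent > child ordering; violating clades are
    returned (flagged, not silently fixed).
    """
    cs = CladeSet.from_samples(samples)
    tree = mcc.copy()
    cm = tree.clade_map()
    for node, cl in cm.items():
        if node.is_leaf:
            continue
        if cl not in cs.heights:
            raise ValueError(f"clade {sorted(cl)} absent from all samples")
        node.height = float(np.median(cs.heights[cl]))
    violations = [cm[n] for n in tree.postorder()
                  if not n.is_root and not n.is_leaf
                  and n.height >= n.parent.height]
    return tree, violations


def hpd_interval(values, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted samples."""
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    if n < 2:
        raise ValueError("need at least 2 values for an HPD interval")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must be in (0, 1)")
    m = int(math.ceil(mass * n))
    widths = values[m - 1:] - values[:n - m + 1]
    i = int(np.argmin(widths))
    return float(values[i]), float(values[i + m - 1])


def ols_scale(inferred_heights, true_heights) -> float:
    """No-intercept least squares: beta = sum(x*y) / sum(x^2)."""
    x = np.asarray(inferred_heights, dtype=float)
    y = np.asarray(true_heights, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one shared clade height")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("inferred heights are all zero")
    return float(np.sum(x * y) / sxx)


def matched_clade_heights(inferred: RootedTimeTree,
                          true: RootedTimeTree,
                          include_root: bool = False
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Heights (inferred, true) of clades present in both trees."""
    hi = inferred.clade_heights()
    ht = true.clade_heights()
    root = frozenset(true.leaf_labels())
    shared = sorted((cl for cl in hi if cl in ht
                     and (include_root or cl != root)),
                    key=lambda c: sorted(c))
    x = np.array([hi[cl] for cl in shared])
    y = np.array([ht[cl] for cl in shared])
    return x, y


def branch_tpr_by_decile(true_tree: RootedTimeTree,
                         sampled_trees: list[RootedTimeTree]) -> pd.DataFrame:
    """Per-decile recovery rate of true-tree internal branches.

    A branch is identified by the clade below it; recovery = fraction of
    sampled trees containing the clade.  Branches are assigned to deciles of
    their true length by rank (ties broken by average rank); the root clade
    is excluded.
    """
    if {frozenset(t.leaf_labels()) for t in sampled_trees} != \
            {frozenset(true_tree.leaf_labels())}:
        raise ValueError("sampled trees and true tree must share the leaf set")
    cs = CladeSet.from_samples(sampled_trees)
    cm = true_tree.clade_map()
    rows = []
    for node, cl in cm.items():
        if node.is_leaf or node.is_root:
            continue
        rows.append((cl, true_tree.branch_duration(node),
                     cs.frequency.get(cl, 0.0)))
    if not rows:
        raise ValueError("true tree has no non-root internal branches")
    lengths = np.array([r[1] for r in rows])
    recovery = np.array([r[2] for r in rows])
    ranks = rankdata(lengths, method="average")
    deciles = np.ceil(ranks * 10.0 / len(rows)).astype(int)
    deciles = np.clip(deciles, 1, 10)
    df = pd.DataFrame({"decile": deciles, "length": lengths,
                       "recovery": recovery})
    return (df.groupby("decile")
              .agg(mean_length=("length", "mean"),
                   recovery=("recovery", "mean"),
                   n_branches=("length", "size"))
              .reset_index())


def pairwise_mutation_distances(tree: RootedTimeTree) -> tuple[list[str], np.ndarray]:
    """Leaf x leaf path distances in mutation units (duration x branch rate)."""
    leaves = tree.leaves()
    labels = [l.label for l in leaves]
    # distance of every node to the root in mutation units
    mut_depth: dict[int, float] = {id(tree.root): 0.0}
    for node in tree.preorder():
        if node.is_root:
            continue
        mut_depth[id(node)] = (mut_depth[id(node.parent)]
                               + tree.effective_branch_length(node))

    def ancestors(node: TreeNode) -> list[TreeNode]:
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    n = len(leaves)
    D = np.zeros((n, n))
    anc = [ancestors(l) for l in leaves]
    anc_sets = [set(id(a) for a in chain) for chain in anc]
    for i in range(n):
        for j in range(i + 1, n):
            common = next(a for a in anc[i] if id(a) in anc_sets[j])
            dij = (mut_depth[id(leaves[i])] + mut_depth[id(leaves[j])]
                   - 2.0 * mut_depth[id(common)])
            D[i, j] = D[j, i] = dij
    return labels, D


def normalized_pairwise_distance_error(inferred: RootedTimeTree,
                                       true: RootedTimeTree) -> float:
    """||N_T - N_R||_2 / (|L|-1)^2 between min-max-normalized distance matrices."""
    labels_t, Dt = pairwise_mutation_distances(inferred)
    labels_r, Dr = pairwise_mutation_distances(true)
    if set(labels_t) != set(labels_r):
        raise ValueError("trees must share the same leaf set")
    if len(labels_t) < 3:
        raise ValueError("need at least 3 leaves")
    order = [labels_t.index(l) for l in labels_r]
    Dt = Dt[np.ix_(order, order)]

    def norm_offdiag(D: np.ndarray) -> np.ndarray:
        mask = ~np.eye(len(D), dtype=bool)
        vals = D[mask]
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            raise ValueError("constant pairwise distances cannot be normalized")
        out = np.zeros_like(D)
        out[mask] = (vals - lo) / (hi - lo)
        return out

    Nt, Nr = norm_offdiag(Dt), norm_offdiag(Dr)
    L = len(labels_r)
    return float(np.linalg.norm(Nt - Nr) / (L - 1) ** 2)


def posterior_coverage(true_tree: RootedTimeTree,
                       scaled_samples: list[RootedTimeTree],
                       mass: float = 0.95
                       ) -> tuple[float, dict[frozenset, bool]]:
    """Fraction of matched true clades whose height lies in the samples' HPD.

    A true-tree clade is matched if it appears (with >= 2 height samples) in
    the sampled trees; unmatched clades are excluded from the denominator.
    """
    cs = CladeSet.from_samples(scaled_samples)
    flags: dict[frozenset, bool] = {}
    for cl, h_true in true_tree.clade_heights().items():
        hs = cs.heights.get(cl)
        if hs is None or len(hs) < 2:
            continue
        lo, hi = hpd_interval(hs, mass)
        flags[cl] = bool(lo <= h_true <= hi)
    if not flags:
        raise ValueError("no true clades matched in the samples")
    return float(np.mean(list(flags.values()))), flags
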