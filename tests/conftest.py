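"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorized code paths:
likelihoods are computed by exhaustive enumeration over all joint state
assignments using the scalar transition probability, and the kernel itself
is cross-checked elsewhere against the matrix exponential of the truncated
birth-death generator.
"""

import itertools
import math

import numpy as np
import pytest

from cnphylo import (CopyNumberMatrix, RootedTimeTree, TreeNode,
                     log_error_density, transition_probability)


def make_tree(newick: str, d: float = 0.5) -> RootedTimeTree:
    t = RootedTimeTree.from_newick(newick)
    t.root_stem_d = d
    return t


@pytest.fixture
def two_leaf_tree() -> RootedTimeTree:
    return make_tree("(a:0.3,b:0.3);", d=0.2)


@pytest.fixture
def three_leaf_tree() -> RootedTimeTree:
    # heights 0.2 (cherry) and 0.5 (root)
    return make_tree("((a:0.2,b:0.2):0.3,c:0.5);", d=0.3)


@pytest.fixture
def four_leaf_trees() -> list[RootedTimeTree]:
    balanced = make_tree("((a:0.2,b:0.2):0.4,(c:0.35,d:0.35):0.25);", d=0.25)
    caterpillar = make_tree("(((a:0.15,b:0.15):0.2,c:0.35):0.25,d:0.6);",
                            d=0.4)
    return [balanced, caterpillar]


def enumerate_bin_likelihood(tree: RootedTimeTree, column: dict[str, float],
                             k: int, sigma: float, r: float = 1.0) -> float:
    """Log likelihood of one bin by exhaustive enumeration over assignments.

    Sums, over every assignment of states {0..k} to every node (leaves
    included), the product of the diploid-stem probability at the root, the
    scalar birth-death transition along each branch, and the Gaussian error
    density at each leaf.
    """
    nodes = tree.postorder()
    idx = {id(n): i for i, n in enumerate(nodes)}
    n_states = k + 1

    # scalar probability tables per branch (closed form, not the matrix path)
    stem = np.array([transition_probability(x, 2, tree.root_stem_d, r)
                     for x in range(n_states)])
    branch_tab = {}
    for node in nodes:
        if node.is_root:
            continue
        t_eff = tree.effective_branch_length(node)
        branch_tab[id(node)] = np.array(
            [[transition_probability(i, j, t_eff, r) for i in range(n_states)]
             for j in range(n_states)])
    leaf_dens = {}
    for leaf in tree.leaves():
        leaf_dens[id(leaf)] = np.exp([
            log_error_density(column[leaf.label], s, sigma)
            for s in range(n_states)])

    grids = np.meshgrid(*([np.arange(n_states)] * len(nodes)), indexing="ij")
    grids = [g.ravel() for g in grids]
    prob = stem[grids[idx[id(tree.root)]]].astype(float)
    for node in nodes:
        if not node.is_root:
            prob *= branch_tab[id(node)][grids[idx[id(node.parent)]],
                                         grids[idx[id(node)]]]
        if node.is_leaf:
            prob *= leaf_dens[id(node)][grids[idx[id(node)]]]
    return math.log(prob.sum())


def enumerate_joint_argmax(tree: RootedTimeTree, column: dict[str, float],
                           k: int, sigma: float,
                           r: float = 1.0) -> tuple[dict[str, int], float]:
    """Best joint assignment by exhaustive search; returns (states, log lik)."""
    nodes = tree.postorder()
    idx = {id(n): i for i, n in enumerate(nodes)}
    n_states = k + 1
    best_logp, best_assign = -np.inf, None
    tabs = {}
    for node in nodes:
        if not node.is_root:
            t_eff = tree.effective_branch_length(node)
            tabs[id(node)] = [[transition_probability(i, j, t_eff, r)
                               for i in range(n_states)]
                              for j in range(n_states)]
    for assign in itertools.product(range(n_states), repeat=len(nodes)):
        p = transition_probability(assign[idx[id(tree.root)]], 2,
                                   tree.root_stem_d, r)
        if p == 0:
            continue
        logp = math.log(p)
        ok = True
        for node in nodes:
            if not node.is_root:
                q = tabs[id(node)][assign[idx[id(node.parent)]]][assign[idx[id(node)]]]
                if q == 0:
                    ok = False
                    break
                logp += math.log(q)
            if node.is_leaf:
                logp += log_error_density(column[node.label],
                                          assign[idx[id(node)]], sigma)
        if ok and logp > best_logp:
            best_logp = logp
            best_assign = assign
    labels = {}
    for node in nodes:
        if node.label:
            labels[node.label] = best_assign[idx[id(node)]]
    return labels, best_logp


def matrix_from_columns(columns: list[dict[str, float]]) -> CopyNumberMatrix:
    cells = sorted(columns[0])
    values = np.array([[col[c] for col in columns] for c in cells],
                      dtype=float)
    return CopyNumberMatrix(values, cells)
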