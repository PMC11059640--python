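"""Phylogenetic likelihood of copy-number profiles by modified pruning.

Bins are assumed independent, so the tree likelihood is the product over
bins of a per-bin likelihood computed by Felsenstein's pruning recursion
with two modifications: leaf partials are Gaussian error densities of the
observed (real-valued) copy numbers around each integer state, and the root
is weighted by the transition probability from the diploid ancestor,
``P(x | 2, d)``, over the stem of length ``d`` instead of a stationary
distribution.  Branch transition matrices are evaluated at the branch's
effective length (time duration x local-clock rate multiplier); the stem
uses rate 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cn_model import BirthDeathCNModel, log_error_density
from .trees import RootedTimeTree, TreeNode

__all__ = [
    "CopyNumberMatrix",
    "leaf_partials",
    "bin_log_likelihood",
    "per_bin_log_likelihood",
    "tree_log_likelihood",
]


@dataclass
class CopyNumberMatrix:
    """Cells x bins observed copy numbers with per-bin genomic coordinates.

    ``values[c, b]`` is the (possibly non-integer) estimated copy number of
    cell ``c`` in bin ``b``; NaN marks a missing observation.  ``bins`` is a
    DataFrame with columns CHR/START/END, 0-based half-open.
    """

    values: np.ndarray
    cell_ids: list[str]
    bins: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x bins array")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length must match number of rows")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("copy numbers cannot be negative")
        if self.bins is None:
            n = self.values.shape[1]
            self.bins = pd.DataFrame({
                "CHR": ["linear"] * n,
                "START": np.arange(n, dtype=int),
                "END": np.arange(1, n + 1, dtype=int),
            })
        if len(self.bins) != self.values.shape[1]:
            raise ValueError("bin table length must match number of columns")
        for chrom, grp in self.bins.groupby("CHR"):
            g = grp.sort_values("START")
            if (g["END"].values[:-1] > g["START"].values[1:]).any():
                raise ValueError(f"overlapping bins on {chrom}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def column(self, b: int) -> dict[str, float]:
        return dict(zip(self.cell_ids, self.values[:, b]))

    def subsample_bins(self, stride: int = 20, offset: int = 0) -> "CopyNumberMatrix":
        """Keep every ``stride``-th bin (deterministic; decorrelates neighbours)."""
        if stride < 1:
            raise ValueError("stride must be >= 1")
        idx = np.arange(offset, self.n_bins, stride)
        return CopyNumberMatrix(self.values[:, idx], list(self.cell_ids),
                                self.bins.iloc[idx].reset_index(drop=True))


def leaf_partials(c_obs: float, sigma: float, k: int) -> np.ndarray:
    """Log partial-likelihood vector over states 0..k for one observation.

    A missing (NaN) observation yields the all-zero log vector
    (uninformative leaf).
    """
    states = np.arange(k + 1, dtype=float)
    if np.isnan(c_obs):
        return np.zeros(k + 1)
    return log_error_density(float(c_obs), states, sigma)


def _leaf_partial_matrix(obs_row: np.ndarray, sigma: float, k: int) -> np.ndarray:
    """(k+1, n_bins) log partials for one cell across all bins."""
    states = np.arange(k + 1, dtype=float)[:, None]
    out = log_error_density(obs_row[None, :], states, sigma)
    missing = np.isnan(obs_row)
    if missing.any():
        out[:, missing] = 0.0
    return out


def per_bin_log_likelihood(tree: RootedTimeTree, D: CopyNumberMatrix,
                           model: BirthDeathCNModel, sigma: float,
                           _leaf_cache: dict | None = None) -> np.ndarray:
    """Vector of per-bin log likelihoods under the pruning recursion.

    Partials are propagated in linear space with a per-bin max rescaling at
    every node (the scale accumulates in log space), which is what keeps
    15k-bin profiles from underflowing.  ``_leaf_cache`` (optional, keyed by
    sigma) memoizes rescaled leaf partials across repeated calls on the same
    matrix, e.g. along an MCMC chain.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    leaf_set = set(tree.leaf_labels())
    if leaf_set != set(D.cell_ids):
        missing = leaf_set.symmetric_difference(D.cell_ids)
        raise ValueError(f"tree leaves and matrix cells differ: {sorted(missing)}")
    row_of = {cid: i for i, cid in enumerate(D.cell_ids)}
    k = model.k
    n_bins = D.n_bins

    cached = None if _leaf_cache is None else _leaf_cache.get(sigma)
    if cached is None:
        cached = {}
        for cid in D.cell_ids:
            logp = _leaf_partial_matrix(D.values[row_of[cid]], sigma, k)
            mx = logp.max(axis=0)
            cached[cid] = (np.exp(logp - mx[None, :]), mx)
        if _leaf_cache is not None:
            if len(_leaf_cache) > 64:
                _leaf_cache.clear()
            _leaf_cache[sigma] = cached

    partial: dict[TreeNode, np.ndarray] = {}
    scale: dict[TreeNode, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            p, mx = cached[node.label]
            partial[node] = p
            scale[node] = mx.copy()
        else:
            acc = np.ones((k + 1, n_bins))
            sc = np.zeros(n_bins)
            for child in node.children:
                P = model.transition_matrix(tree.effective_branch_length(child))
                acc = acc * (P @ partial.pop(child))
                sc += scale.pop(child)
            mx = acc.max(axis=0)
            # all-zero column can only arise from an impossible configuration
            ok = mx > 0
            if not ok.all():
                bad = int(np.argmin(ok))
                raise FloatingPointError(f"non-finite partials at bin {bad}")
            partial[node] = acc / mx[None, :]
            scale[node] = sc + np.log(mx)

    root_weights = model.transition_matrix(tree.root_stem_d)[2, :]
    lik = root_weights @ partial[tree.root]
    with np.errstate(divide="ignore"):
        out = np.log(lik) + scale[tree.root]
    bad = ~np.isfinite(out)
    if bad.any():
        raise FloatingPointError(f"non-finite likelihood at bin {int(np.argmax(bad))}")
    return out


def bin_log_likelihood(tree: RootedTimeTree, column: dict[str, float],
                       model: BirthDeathCNModel, sigma: float) -> float:
    """Log likelihood of a single bin given per-cell observed values."""
    cells = list(column)
    D = CopyNumberMatrix(np.array([[column[c]] for c in cells]), cells)
    return float(per_bin_log_likelihood(tree, D, model, sigma)[0])


def tree_log_likelihood(tree: RootedTimeTree, D: CopyNumberMatrix,
                        model: BirthDeathCNModel, sigma: float,
                        _leaf_cache: dict | None = None) -> float:
    """Total log likelihood: sum of per-bin log likelihoods (independent bins)."""
    return float(per_bin_log_likelihood(tree, D, model, sigma,
                                        _leaf_cache=_leaf_cache).sum())
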