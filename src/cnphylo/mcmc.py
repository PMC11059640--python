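"""Metropolis-Hastings sampling of the posterior over trees and model scalars.

The target is

    P(T, d, theta, sigma | D)  ∝  f(D | T, d, sigma) P(T | theta, R)
                                   f(theta) f(d) f(R)

with a two-parameter constant-rate birth-death prior on the ultrametric tree
(parameterized by diversification rate ``r_d`` and extinction fraction
``r_e``, conditioned on the number of tips with an improper uniform prior on
the origin time), uniform priors d ~ U(0.001, 5), sigma ~ U(0, 9),
r_d ~ U(0, 1e6), r_e ~ U(0, 1), and a random-local-clock (RLC) prior on
branch rates: Poisson(lambda_R = log 2) on the number of rate changes
(placing prior probability 0.5 on "no change"), uniform over placements,
and Gamma(0.5, scale 2) multipliers on the changed branches.

The move set is the standard repertoire for rooted time trees: narrow and
wide exchange, Wilson-Balding, a within-branch subtree height slide, uniform
internal-node height draws, root and whole-tree scalers, scale/random-walk
moves on the scalars, and reversible-jump flips of the RLC indicators (the
multiplier of a newly activated branch is proposed from its Gamma prior, so
the Hastings term cancels the prior density).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cn_model import BirthDeathCNModel
from .likelihood import CopyNumberMatrix, tree_log_likelihood
from .trees import RootedTimeTree, TreeNode, upgma_tree

__all__ = [
    "TreePriorParams",
    "ClockModelParams",
    "PriorConfig",
    "PosteriorState",
    "PosteriorTrace",
    "tree_prior_log_density",
    "log_prior",
    "step",
    "run_mcmc",
    "coupled_chains",
    "DEFAULT_MOVE_WEIGHTS",
]


# ----------------------------------------------------------------------
# parameter containers and priors
# ----------------------------------------------------------------------

@dataclass
class TreePriorParams:
    """Tree-generating birth-death prior: diversification rate and extinction fraction."""

    r_d: float = 1.0
    r_e: float = 0.5


@dataclass
class ClockModelParams:
    """Random-local-clock hyperparameters.

    ``lambda_R`` is the Poisson mean of the number of rate changes (log 2 by
    default, i.e. prior probability 0.5 of a strict clock); multipliers are
    Gamma(``alpha_R``, scale ``beta_R``).
    """

    lambda_R: float = math.log(2.0)
    alpha_R: float = 0.5
    beta_R: float = 2.0


@dataclass
class PriorConfig:
    """Support bounds of the uniform priors."""

    d_bounds: tuple[float, float] = (0.001, 5.0)
    sigma_bounds: tuple[float, float] = (0.0, 9.0)
    rd_bounds: tuple[float, float] = (0.0, 1.0e6)
    re_bounds: tuple[float, float] = (0.0, 1.0)


def tree_prior_log_density(tree: RootedTimeTree, r_d: float, r_e: float) -> float:
    """Log density of the conditioned reconstructed birth-death tree prior.

    Constant-rate birth-death with speciation ``lam = r_d/(1-r_e)`` and
    extinction ``mu = lam*r_e``, conditioned on the number of extant tips
    ``n`` under an improper uniform prior on the origin time.  Up to
    constants in ``n``,

        f ∝ n * lam * [r e^{-r x1} / (lam (lam - mu e^{-r x1}))]
              * prod_i lam * p1(x_i),
        p1(t) = r^2 e^{-rt} / (lam - mu e^{-rt})^2,

    where ``x1`` is the root height and the product runs over all internal
    node heights (including the root).  The density depends on heights only,
    never on the topology, so given the heights all labeled histories are
    equally likely.
    """
    if r_d <= 0 or not (0 <= r_e < 1):
        return -np.inf
    r = r_d
    lam = r / (1.0 - r_e)
    mu = lam * r_e
    heights = np.array([n.height for n in tree.internal_nodes()])
    x1 = tree.root.height
    if (heights <= 0).any():
        return -np.inf
    e = np.exp(-r * heights)
    denom = lam - mu * e
    if (denom <= 0).any():
        return -np.inf
    log_p1 = 2.0 * np.log(r) - r * heights - 2.0 * np.log(denom)
    e1 = math.exp(-r * x1)
    log_origin = (math.log(r) - r * x1 - math.log(lam)
                  - math.log(lam - mu * e1))
    n = tree.n_leaves
    return (math.log(n) + math.log(lam) + log_origin
            + float(np.sum(math.log(lam) + log_p1)))


def _gamma_logpdf(x: float, a: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return ((a - 1.0) * math.log(x) - x / scale
            - math.lgamma(a) - a * math.log(scale))


def rlc_log_prior(tree: RootedTimeTree, clock: ClockModelParams) -> float:
    """Poisson count x uniform placement x Gamma multipliers, active branches only."""
    branches = [n for n in tree.postorder() if not n.is_root]
    B = len(branches)
    active = [n for n in branches if n.rate_change]
    m = len(active)
    lp = m * math.log(clock.lambda_R) - clock.lambda_R - math.lgamma(m + 1)
    lp -= (math.lgamma(B + 1) - math.lgamma(m + 1) - math.lgamma(B - m + 1))
    for node in active:
        if node.rate_multiplier <= 0:
            return -np.inf
        lp += _gamma_logpdf(node.rate_multiplier, clock.alpha_R, clock.beta_R)
    return float(lp)


def _log_uniform(x: float, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    if not (lo <= x <= hi):
        return -np.inf
    return -math.log(hi - lo)


@dataclass
class PosteriorState:
    """Full sampler state with cached log densities."""

    tree: RootedTimeTree
    sigma: float
    tree_prior: TreePriorParams
    clock: ClockModelParams
    log_likelihood: float = np.nan
    log_prior_value: float = np.nan

    @property
    def d(self) -> float:
        return self.tree.root_stem_d

    @property
    def log_posterior(self) -> float:
        return self.log_likelihood + self.log_prior_value

    def copy(self) -> "PosteriorState":
        return PosteriorState(self.tree.copy(), self.sigma,
                              replace(self.tree_prior), self.clock,
                              self.log_likelihood, self.log_prior_value)


def log_prior(state: PosteriorState,
              priors: PriorConfig | None = None) -> float:
    """Joint log prior; returns -inf outside the support, never raises."""
    priors = priors or PriorConfig()
    lp = _log_uniform(state.tree.root_stem_d, priors.d_bounds)
    lp += _log_uniform(state.sigma, priors.sigma_bounds)
    lp += _log_uniform(state.tree_prior.r_d, priors.rd_bounds)
    lp += _log_uniform(state.tree_prior.r_e, priors.re_bounds)
    if not np.isfinite(lp):
        return -np.inf
    lp += tree_prior_log_density(state.tree, state.tree_prior.r_d,
                                 state.tree_prior.r_e)
    if not np.isfinite(lp):
        return -np.inf
    lp += rlc_log_prior(state.tree, state.clock)
    return float(lp)


# ----------------------------------------------------------------------
# proposal moves: each returns (mutated-in-place proposal ok?, log Hastings)
# operating on an already-copied state; None signals auto-reject.
# ----------------------------------------------------------------------

def _scale_factor(rng: np.random.Generator, tune: float = 0.5) -> float:
    return math.exp(tune * (rng.uniform() - 0.5))


def _mv_sigma(state, rng, tune=0.5):
    s = _scale_factor(rng, tune)
    state.sigma *= s
    return math.log(s)


def _mv_sigma_walk(state, rng, window=1.5):
    # additive walk: traverses the bounded uniform prior far faster than
    # the multiplicative move when the posterior is flat in sigma
    state.sigma += rng.uniform(-window, window)
    return 0.0


def _mv_d_walk(state, rng, window=1.0):
    state.tree.root_stem_d += rng.uniform(-window, window)
    return 0.0


def _mv_d(state, rng, tune=0.5):
    s = _scale_factor(rng, tune)
    state.tree.root_stem_d *= s
    return math.log(s)


def _mv_rd(state, rng, tune=1.0):
    s = _scale_factor(rng, tune)
    state.tree_prior.r_d *= s
    return math.log(s)


def _mv_re(state, rng, window=0.15):
    state.tree_prior.r_e += rng.uniform(-window, window)
    return 0.0


def _internal_nonroot(tree: RootedTimeTree) -> list[TreeNode]:
    return [n for n in tree.internal_nodes() if not n.is_root]


def _mv_node_height_uniform(state, rng):
    cands = _internal_nonroot(state.tree)
    if not cands:
        return None
    node = cands[rng.integers(len(cands))]
    lo = max(c.height for c in node.children)
    hi = node.parent.height
    node.height = rng.uniform(lo, hi)
    return 0.0


def _mv_subtree_slide(state, rng, window=0.1):
    # height slide restricted to the branch interval; no topology change
    cands = _internal_nonroot(state.tree)
    if not cands:
        return None
    node = cands[rng.integers(len(cands))]
    h = node.height + rng.uniform(-window, window) * state.tree.root.height
    lo = max(c.height for c in node.children)
    hi = node.parent.height
    if not (lo < h < hi):
        return None
    node.height = h
    return 0.0


def _mv_root_scale(state, rng, tune=0.3):
    s = _scale_factor(rng, tune)
    root = state.tree.root
    h = root.height * s
    if h <= max(c.height for c in root.children):
        return None
    root.height = h
    return math.log(s)


def _mv_tree_scale(state, rng, tune=0.3):
    s = _scale_factor(rng, tune)
    internal = state.tree.internal_nodes()
    for n in internal:
        n.height *= s
    return len(internal) * math.log(s)


def _replace_child(parent: TreeNode, old: TreeNode, new: TreeNode) -> None:
    parent.children[parent.children.index(old)] = new
    new.parent = parent


def _mv_narrow_exchange(state, rng):
    cands = _internal_nonroot(state.tree)
    if not cands:
        return None
    node = cands[rng.integers(len(cands))]
    parent = node.parent
    uncle = parent.children[0] if parent.children[1] is node else parent.children[1]
    child = node.children[rng.integers(2)]
    if uncle.height >= node.height:
        return None
    _replace_child(parent, uncle, child)
    _replace_child(node, child, uncle)
    return 0.0


def _mv_wide_exchange(state, rng):
    nodes = [n for n in state.tree.postorder() if not n.is_root]
    if len(nodes) < 4:
        return None
    i, j = rng.choice(len(nodes), size=2, replace=False)
    a, b = nodes[i], nodes[j]
    if a.parent is b.parent:
        return None
    # reject ancestor-descendant pairs
    for x, y in ((a, b), (b, a)):
        p = y.parent
        while p is not None:
            if p is x:
                return None
            p = p.parent
    if a.height >= b.parent.height or b.height >= a.parent.height:
        return None
    pa, pb = a.parent, b.parent
    _replace_child(pa, a, b)
    _replace_child(pb, b, a)
    return 0.0


def _mv_wilson_balding(state, rng):
    tree = state.tree
    all_nodes = tree.postorder()
    cands = [n for n in all_nodes
             if not n.is_root and n.parent is not None and not n.parent.is_root]
    if not cands:
        return None
    i = cands[rng.integers(len(cands))]
    p = i.parent
    g = p.parent
    sib = p.children[0] if p.children[1] is i else p.children[1]
    j = all_nodes[rng.integers(len(all_nodes))]
    if j is i or j is p or j.is_root:
        return None
    # j must not be inside the pruned subtree
    anc = j
    while anc is not None:
        if anc is i:
            return None
        anc = anc.parent
    old_len = g.height - max(i.height, sib.height)
    # detach p: sib takes p's place under g
    _replace_child(g, p, sib)
    pj = j.parent
    lo = max(i.height, j.height)
    if pj.height <= lo:
        # undo and reject
        _replace_child(g, sib, p)
        sib.parent = p
        return None
    new_len = pj.height - lo
    p.height = rng.uniform(lo, pj.height)
    _replace_child(pj, j, p)
    _replace_child(p, sib, j)
    return math.log(new_len) - math.log(old_len)


def _mv_rlc_flip(state, rng):
    branches = [n for n in state.tree.postorder() if not n.is_root]
    node = branches[rng.integers(len(branches))]
    clock = state.clock
    if node.rate_change:
        logh = _gamma_logpdf(node.rate_multiplier, clock.alpha_R, clock.beta_R)
        node.rate_change = False
        node.rate_multiplier = 1.0
        return float(logh)
    mult = float(rng.gamma(clock.alpha_R, clock.beta_R))
    if mult <= 0:
        return None
    node.rate_change = True
    node.rate_multiplier = mult
    return -_gamma_logpdf(mult, clock.alpha_R, clock.beta_R)


def _mv_rlc_scale(state, rng, tune=0.7):
    active = [n for n in state.tree.postorder()
              if not n.is_root and n.rate_change]
    if not active:
        return None
    node = active[rng.integers(len(active))]
    s = _scale_factor(rng, tune)
    node.rate_multiplier *= s
    return math.log(s)


_MOVE_CHOICE_CACHE: dict[int, tuple] = {}

_MOVES = {
    "sigma_scale": _mv_sigma,
    "sigma_walk": _mv_sigma_walk,
    "d_scale": _mv_d,
    "d_walk": _mv_d_walk,
    "rd_scale": _mv_rd,
    "re_walk": _mv_re,
    "node_height": _mv_node_height_uniform,
    "subtree_slide": _mv_subtree_slide,
    "root_scale": _mv_root_scale,
    "tree_scale": _mv_tree_scale,
    "narrow_exchange": _mv_narrow_exchange,
    "wide_exchange": _mv_wide_exchange,
    "wilson_balding": _mv_wilson_balding,
    "rlc_flip": _mv_rlc_flip,
    "rlc_scale": _mv_rlc_scale,
}

DEFAULT_MOVE_WEIGHTS = {
    "sigma_scale": 3.0,
    "sigma_walk": 2.0,
    "d_scale": 3.0,
    "d_walk": 2.0,
    "rd_scale": 3.0,
    "re_walk": 3.0,
    "node_height": 20.0,
    "subtree_slide": 10.0,
    "root_scale": 5.0,
    "tree_scale": 5.0,
    "narrow_exchange": 15.0,
    "wide_exchange": 5.0,
    "wilson_balding": 15.0,
    "rlc_flip": 5.0,
    "rlc_scale": 4.0,
}


# ----------------------------------------------------------------------
# the sampler
# ----------------------------------------------------------------------

class _Target:
    """Bundles data/model/prior so likelihood+prior can be recomputed anywhere."""

    def __init__(self, D: CopyNumberMatrix | None, model: BirthDeathCNModel,
                 priors: PriorConfig, likelihood_weight: float = 1.0):
        self.D = D
        self.model = model
        self.priors = priors
        self.likelihood_weight = likelihood_weight
        self._leaf_cache: dict = {}

    def evaluate(self, state: PosteriorState) -> None:
        state.log_prior_value = log_prior(state, self.priors)
        if not np.isfinite(state.log_prior_value):
            state.log_likelihood = 0.0
            return
        if self.likelihood_weight == 0.0 or self.D is None:
            state.log_likelihood = 0.0
        else:
            try:
                ll = tree_log_likelihood(state.tree, self.D, self.model,
                                         state.sigma,
                                         _leaf_cache=self._leaf_cache)
            except (FloatingPointError, ValueError):
                ll = -np.inf
            state.log_likelihood = self.likelihood_weight * ll


def step(state: PosteriorState, rng: np.random.Generator, target: _Target,
         move_weights: dict[str, float] | None = None,
         beta: float = 1.0) -> tuple[PosteriorState, bool, str]:
    """One Metropolis-Hastings update; returns (state, accepted, move name).

    ``beta`` is the inverse temperature applied to the whole posterior (1 for
    the cold chain).  Proposals that leave the support or fail validity are
    auto-rejected.
    """
    weights = move_weights or DEFAULT_MOVE_WEIGHTS
    key = id(weights)
    cached = _MOVE_CHOICE_CACHE.get(key)
    if cached is None or cached[0] is not weights:
        names = list(weights)
        w = np.array([weights[n] for n in names], dtype=float)
        cached = (weights, names, np.cumsum(w) / w.sum())
        _MOVE_CHOICE_CACHE[key] = cached
    _, names, cum = cached
    name = names[int(np.searchsorted(cum, rng.uniform()))]
    proposal = state.copy()
    logh = _MOVES[name](proposal, rng)
    if logh is None:
        return state, False, name
    target.evaluate(proposal)
    if not np.isfinite(proposal.log_prior_value):
        return state, False, name
    log_alpha = beta * (proposal.log_posterior - state.log_posterior) + logh
    if log_alpha >= 0 or rng.uniform() < math.exp(max(log_alpha, -745.0)):
        return proposal, True, name
    return state, False, name


@dataclass
class PosteriorTrace:
    """Scalar trace plus sampled trees from one (cold) chain."""

    scalars: pd.DataFrame
    trees: list[RootedTimeTree]
    tree_sample_iterations: list[int]
    acceptance: dict[str, tuple[int, int]] = field(default_factory=dict)
    burnin_fraction: float = 0.2
    seed: int | None = None

    def burned_trees(self, burnin_fraction: float | None = None) -> list[RootedTimeTree]:
        frac = self.burnin_fraction if burnin_fraction is None else burnin_fraction
        start = int(math.ceil(frac * len(self.trees)))
        return self.trees[start:]

    def burned_scalars(self, burnin_fraction: float | None = None) -> pd.DataFrame:
        frac = self.burnin_fraction if burnin_fraction is None else burnin_fraction
        start = int(math.ceil(frac * len(self.scalars)))
        return self.scalars.iloc[start:]


def _initial_state(D: CopyNumberMatrix | None, priors: PriorConfig,
                   clock: ClockModelParams,
                   n_leaves_if_no_data: int = 5,
                   cell_ids: list[str] | None = None,
                   init_root_height: float = 0.5) -> PosteriorState:
    """Deterministic start: average-linkage tree on per-cell L1 distances."""
    if D is not None:
        ids = D.cell_ids
        n = len(ids)
        dist = np.zeros((n, n))
        for a in range(n):
            diff = np.abs(D.values[a][None, :] - D.values)
            dist[a] = np.nanmean(diff, axis=1)
        tree = upgma_tree(dist, list(ids))
    else:
        ids = cell_ids or [f"cell{i}" for i in range(n_leaves_if_no_data)]
        n = len(ids)
        dist = np.abs(np.subtract.outer(np.arange(n, dtype=float),
                                        np.arange(n, dtype=float)))
        tree = upgma_tree(dist, list(ids))
    if tree.root.height > 0:
        f = init_root_height / tree.root.height
        for node in tree.internal_nodes():
            node.height *= f
    tree.root_stem_d = 0.5
    return PosteriorState(tree, sigma=0.5,
                          tree_prior=TreePriorParams(1.0, 0.5), clock=clock)


def run_mcmc(D: CopyNumberMatrix | None, config, seed: int | None = None,
             initial_state: PosteriorState | None = None) -> PosteriorTrace:
    """Run a single chain and return the posterior trace.

    ``config`` is a :class:`cnphylo.io.RunConfig` (or anything with the same
    fields).  ``seed`` overrides ``config.seed``.  A chain of length 0
    yields a trace containing only the initial state.
    """
    if config.chain_length < 0:
        raise ValueError("chain length must be non-negative")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    model = BirthDeathCNModel(r=1.0, k=config.k)
    priors = config.prior_config()
    clock = config.clock_params()
    target = _Target(D, model, priors, config.likelihood_weight)
    state = initial_state.copy() if initial_state is not None else \
        _initial_state(D, priors, clock)
    target.evaluate(state)
    if not np.isfinite(state.log_prior_value):
        raise RuntimeError("initial state outside the prior support")

    sample_every = max(1, int(config.sample_every))
    rows = []
    trees: list[RootedTimeTree] = []
    tree_iters: list[int] = []
    acc: dict[str, list[int]] = {name: [0, 0] for name in _MOVES}

    def record(it: int) -> None:
        rows.append((it, state.log_posterior, state.log_likelihood,
                     state.log_prior_value, state.d, state.sigma,
                     state.tree_prior.r_d, state.tree_prior.r_e,
                     state.tree.n_rate_changes(), state.tree.root.height))
        trees.append(state.tree.copy())
        tree_iters.append(it)

    record(0)
    weights = getattr(config, "move_weights", None) or DEFAULT_MOVE_WEIGHTS
    for it in range(1, config.chain_length + 1):
        state, accepted, name = step(state, rng, target, weights)
        acc[name][1] += 1
        acc[name][0] += int(accepted)
        if it % sample_every == 0:
            record(it)

    scalars = pd.DataFrame(rows, columns=[
        "iteration", "log_posterior", "log_likelihood", "log_prior", "d",
        "sigma", "r_d", "r_e", "n_rate_changes", "root_height"])
    return PosteriorTrace(scalars, trees, tree_iters,
                          {k: (v[0], v[1]) for k, v in acc.items()},
                          burnin_fraction=config.burnin_fraction, seed=seed)


def coupled_chains(D: CopyNumberMatrix | None, config,
                   seed: int | None = None) -> PosteriorTrace:
    """Metropolis-coupled chains; only the cold chain is logged.

    ``config.n_chains`` chains run at inverse temperatures
    ``beta_i = 1/(1 + i * delta_T)``; every ``config.swap_every`` steps a
    random adjacent pair proposes a state swap with the standard tempered
    acceptance ratio.  With one chain this reduces exactly to
    :func:`run_mcmc`.
    """
    n_chains = config.n_chains
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if n_chains == 1:
        return run_mcmc(D, config, seed=seed)
    seed = config.seed if seed is None else seed
    betas = [1.0 / (1.0 + i * config.delta_T) for i in range(n_chains)]
    if any(b2 >= b1 for b1, b2 in zip(betas, betas[1:])):
        raise ValueError("temperature ladder must be strictly decreasing in beta")
    rng = np.random.default_rng(seed)
    model = BirthDeathCNModel(r=1.0, k=config.k)
    priors = config.prior_config()
    clock = config.clock_params()
    target = _Target(D, model, priors, config.likelihood_weight)
    base = _initial_state(D, priors, clock)
    states = [base.copy() for _ in range(n_chains)]
    for s in states:
        target.evaluate(s)
    weights = getattr(config, "move_weights", None) or DEFAULT_MOVE_WEIGHTS

    sample_every = max(1, int(config.sample_every))
    rows = []
    trees: list[RootedTimeTree] = []
    tree_iters: list[int] = []

    def record(it: int) -> None:
        s = states[0]
        rows.append((it, s.log_posterior, s.log_likelihood, s.log_prior_value,
                     s.d, s.sigma, s.tree_prior.r_d, s.tree_prior.r_e,
                     s.tree.n_rate_changes(), s.tree.root.height))
        trees.append(s.tree.copy())
        tree_iters.append(it)

    record(0)
    for it in range(1, config.chain_length + 1):
        for c in range(n_chains):
            states[c], _, _ = step(states[c], rng, target, weights,
                                   beta=betas[c])
        if it % config.swap_every == 0 and n_chains >= 2:
            a = int(rng.integers(n_chains - 1))
            b = a + 1
            ua = states[a].log_posterior
            ub = states[b].log_posterior
            log_alpha = (betas[a] - betas[b]) * (ub - ua)
            if log_alpha >= 0 or rng.uniform() < math.exp(max(log_alpha, -745.0)):
                states[a], states[b] = states[b], states[a]
        if it % sample_every == 0:
            record(it)

    scalars = pd.DataFrame(rows, columns=[
        "iteration", "log_posterior", "log_likelihood", "log_prior", "d",
        "sigma", "r_d", "r_e", "n_rate_changes", "root_height"])
    return PosteriorTrace(scalars, trees, tree_iters, {},
                          burnin_fraction=config.burnin_fraction, seed=seed)
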