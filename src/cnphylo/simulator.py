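"""Ground-truth CNA simulation along a tree and a parametric noise model.

Copy-number aberrations are simulated on a user-supplied rooted time tree
(including the diploid stem): the number of events on a branch of length
``t`` is Poisson(``c*t``); each event picks a parental allele uniformly, a
genomic position on the linearized unit-interval genome from a sum-of-sines
density, a size of 2 Mbp plus an Exponential(mean 10 Mbp) excess, and a
gain/loss sign uniformly.  Each allele starts with one copy at the diploid
root; a gain adds one copy over its interval, a loss removes one with a
floor at zero (consistent with the absorbing zero state of the birth-death
kernel).  Leaf and ancestral profiles are the events accumulated along the
root-to-node path, binned into equal-width bins by overlap-weighted mean and
rounded half-up.

Observed profiles are produced by a calibrated rounded-Gaussian perturbation
standing in for the read-alignment and CN-calling noise of a real pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .likelihood import CopyNumberMatrix
from .trees import RootedTimeTree, TreeNode

__all__ = [
    "CNAEvent",
    "PositionDensity",
    "sample_position",
    "simulate_events",
    "events_to_profiles",
    "overlap_fraction",
    "add_estimation_noise",
    "SimulatedDataset",
]

GENOME_LENGTH = 3.0e9  # bp; the linearized genome maps to [0, 1)
DEFAULT_N_BINS = 15_000
SIZE_MEAN_BP = 10.0e6
MIN_SIZE_BP = 2.0e6


@dataclass
class CNAEvent:
    """One simulated amplification (+1) or deletion (-1) on one allele."""

    branch_id: int            # id of the child node of the branch (root id = stem)
    allele: int               # 0 = maternal, 1 = paternal
    start: float              # linearized coordinate in [0, 1)
    length_bp: float          # >= MIN_SIZE_BP
    sign: int                 # +1 gain, -1 loss
    time: float               # pseudo-time in [0, 1) ordering events within a branch

    def interval(self, genome_length: float = GENOME_LENGTH) -> tuple[float, float]:
        """Unit-interval [start, end) clipped at the genome end."""
        end = min(self.start + self.length_bp / genome_length, 1.0)
        return self.start, end


@dataclass
class PositionDensity:
    """Sum-of-sines position density f(x) ∝ exp(Σ_i sin(1000x + φ_i) λ_i) on [0,1).

    ``a`` controls non-uniformity: phases are Uniform(-π, π) and amplitudes
    Uniform(0, a); ``a = 0`` is exactly uniform.  Sampling is by inverse CDF
    on a fixed fine grid (midpoint normalization).
    """

    a: float
    phases: np.ndarray
    amplitudes: np.ndarray
    grid_size: int = 2 ** 20
    _grid: np.ndarray = field(init=False, repr=False)
    _pdf: np.ndarray = field(init=False, repr=False)
    _cdf: np.ndarray = field(init=False, repr=False)

    @classmethod
    def build(cls, a: float, rng: np.random.Generator, n_terms: int = 30,
              grid_size: int = 2 ** 20) -> "PositionDensity":
        if a < 0:
            raise ValueError("non-uniformity parameter a must be >= 0")
        phases = rng.uniform(-math.pi, math.pi, size=n_terms)
        amplitudes = rng.uniform(0.0, a, size=n_terms) if a > 0 else np.zeros(n_terms)
        return cls(a, phases, amplitudes, grid_size)

    def __post_init__(self):
        mid = (np.arange(self.grid_size) + 0.5) / self.grid_size
        logf = np.sin(1000.0 * mid[:, None] + self.phases[None, :]) @ self.amplitudes
        logf -= logf.max()
        f = np.exp(logf)
        f /= f.sum() / self.grid_size  # integrates to 1 on [0,1)
        self._grid = mid
        self._pdf = f
        cdf = np.cumsum(f) / self.grid_size
        cdf /= cdf[-1]
        self._cdf = cdf

    def pdf(self, x: np.ndarray) -> np.ndarray:
        idx = np.clip((np.asarray(x) * self.grid_size).astype(int), 0,
                      self.grid_size - 1)
        return self._pdf[idx]

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        u = rng.uniform(size=size)
        idx = np.searchsorted(self._cdf, u)
        # uniform within the selected grid cell
        return (idx + rng.uniform(size=size)) / self.grid_size


def sample_position(density: PositionDensity, rng: np.random.Generator) -> float:
    """One draw from the position density, in [0, 1)."""
    return float(density.sample(rng, 1)[0])


def simulate_events(tree: RootedTimeTree, c: float, density: PositionDensity,
                    rng: np.random.Generator,
                    size_mean: float = SIZE_MEAN_BP,
                    min_size: float = MIN_SIZE_BP,
                    genome_length: float = GENOME_LENGTH,
                    include_stem: bool = True) -> list[CNAEvent]:
    """Poisson(c * branch length) CNA events on every branch of the tree."""
    if c <= 0:
        raise ValueError("event multiplier c must be positive")
    events: list[CNAEvent] = []
    for node in tree.postorder():
        if node.is_root and not include_stem:
            continue
        t = tree.branch_duration(node)
        n = int(rng.poisson(c * t)) if t > 0 else 0
        if n == 0:
            continue
        starts = density.sample(rng, n)
        lengths = min_size + rng.exponential(size_mean, size=n)
        alleles = rng.integers(0, 2, size=n)
        signs = np.where(rng.integers(0, 2, size=n) == 1, 1, -1)
        times = rng.uniform(size=n)
        for s, ln, al, sg, tm in zip(starts, lengths, alleles, signs, times):
            events.append(CNAEvent(node.id, int(al), float(s), float(ln),
                                   int(sg), float(tm)))
    return events


def overlap_fraction(events: list[CNAEvent],
                     genome_length: float = GENOME_LENGTH) -> float:
    """Fraction of events whose interval intersects at least one other event's.

    Allele-agnostic and genome-wide, over all branches.
    """
    if not events:
        raise ValueError("overlap fraction of an empty event list is undefined")
    if len(events) == 1:
        return 0.0
    iv = np.array([e.interval(genome_length) for e in events])
    order = np.argsort(iv[:, 0], kind="stable")
    starts = iv[order, 0]
    ends = iv[order, 1]
    overlapped = np.zeros(len(events), dtype=bool)
    # sweep: an event overlaps a predecessor iff its start < running max end
    run_max = -np.inf
    run_argmax = -1
    for pos in range(len(order)):
        if starts[pos] < run_max:
            overlapped[order[pos]] = True
            overlapped[order[run_argmax]] = True
        if ends[pos] > run_max:
            run_max = ends[pos]
            run_argmax = pos
    # the sweep marks the running-max holder; events ending before it that
    # still overlap a later start are caught because max end only grows
    return float(overlapped.mean())


@dataclass
class SimulatedDataset:
    """True leaf profiles, per-node ancestral truth, and the generating events."""

    true_profiles: CopyNumberMatrix
    node_profiles: dict[str, np.ndarray]
    events: list[CNAEvent]
    tree: RootedTimeTree


def events_to_profiles(tree: RootedTimeTree, events: list[CNAEvent],
                       n_bins: int = DEFAULT_N_BINS,
                       genome_length: float = GENOME_LENGTH) -> SimulatedDataset:
    """Apply events along root-to-node paths and bin the resulting copy numbers.

    Both alleles start with one copy at the diploid ancestor; events on a
    branch are applied in pseudo-time order, losses flooring at 0 per
    affected sub-interval.  Bin value = overlap-length-weighted mean of the
    total (maternal + paternal) per-base copy number, rounded half-up.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    from .ancestral import label_internal_nodes
    tree = tree.copy()
    label_internal_nodes(tree)
    by_branch: dict[int, list[CNAEvent]] = {}
    cuts = {0.0, 1.0}
    for e in events:
        s, t = e.interval(genome_length)
        cuts.add(s)
        cuts.add(t)
        by_branch.setdefault(e.branch_id, []).append(e)
    for evs in by_branch.values():
        evs.sort(key=lambda e: e.time)
    bounds = np.array(sorted(cuts))
    widths = np.diff(bounds)
    n_atoms = len(widths)

    def apply_branch(counts: np.ndarray, node_id: int) -> np.ndarray:
        out = counts.copy()
        for e in by_branch.get(node_id, ()):
            s, t = e.interval(genome_length)
            a = np.searchsorted(bounds, s, side="left")
            b = np.searchsorted(bounds, t, side="left")
            if e.sign > 0:
                out[e.allele, a:b] += 1
            else:
                seg = out[e.allele, a:b]
                out[e.allele, a:b] = np.maximum(seg - 1, 0)
        return out

    bin_edges = np.linspace(0.0, 1.0, n_bins + 1)

    def binned(counts: np.ndarray) -> np.ndarray:
        total = counts.sum(axis=0).astype(float)
        cum = np.concatenate([[0.0], np.cumsum(total * widths)])
        integral = np.interp(bin_edges, bounds, cum)
        means = np.diff(integral) * n_bins
        return np.floor(means + 0.5).astype(int)

    node_profiles: dict[str, np.ndarray] = {}
    order = list(tree.preorder())
    counts_at: dict[int, np.ndarray] = {}
    base = np.ones((2, n_atoms), dtype=np.int32)
    for node in order:
        parent_counts = base if node.is_root else counts_at[id(node.parent)]
        counts = apply_branch(parent_counts, node.id)
        counts_at[id(node)] = counts
        node_profiles[node.label] = binned(counts)

    leaves = tree.leaves()
    values = np.array([node_profiles[l.label] for l in leaves], dtype=float)
    import pandas as pd
    starts = (bin_edges[:-1] * genome_length).astype(np.int64)
    ends = (bin_edges[1:] * genome_length).astype(np.int64)
    bins = pd.DataFrame({"CHR": ["linear"] * n_bins, "START": starts, "END": ends})
    true_matrix = CopyNumberMatrix(values, [l.label for l in leaves], bins)
    return SimulatedDataset(true_matrix, node_profiles, events, tree)


def _noise_sd_for_error_rate(target: float) -> float:
    """SD of the rounded Gaussian jitter giving per-entry error prob ``target``."""
    if target <= 0:
        return 0.0
    # P(round(N(0, s)) != 0) = 2 Phi(-0.5/s) = target
    return 0.5 / -norm.ppf(target / 2.0)


def add_estimation_noise(true_matrix: CopyNumberMatrix,
                         target_error_rate: float,
                         rng: np.random.Generator,
                         sigma_noise: float | None = None,
                         k: int = 9) -> CopyNumberMatrix:
    """Perturb true profiles so the expected per-entry error rate ≈ target.

    Each entry gets independent Gaussian jitter, is rounded half-up, and
    clipped to [0, k].  ``sigma_noise`` overrides the calibrated SD.
    """
    if not (0.0 <= target_error_rate < 1.0):
        raise ValueError("target_error_rate must be in [0, 1)")
    sd = _noise_sd_for_error_rate(target_error_rate) if sigma_noise is None \
        else sigma_noise
    vals = true_matrix.values.copy()
    if sd > 0:
        vals = vals + rng.normal(0.0, sd, size=vals.shape)
    vals = np.clip(np.floor(vals + 0.5), 0, k)
    return CopyNumberMatrix(vals, list(true_matrix.cell_ids),
                            true_matrix.bins.copy())
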