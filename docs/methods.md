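# Methods

## Copy-number kernel

The within-bin model is the critical linear birth-death process: per-copy
event rate `r` (birth = death), state space truncated to {0, …, k} for
likelihood computation. `r` is fixed at 1 and is not identifiable
separately from time: branch lengths are in units of expected per-copy
events. `k` defaults to 9, the largest copy number commonly worth modeling
in tumor bins; raising it increases cost quadratically (per-bin pruning is
O(nk²)).

The general-case transition probability is implemented as

    P(i|j,t) = (rt/(1+rt))^{i+j} Σ_{k=1}^{min(i,j)} C(j,k) C(i−1,k−1) (rt)^{−2k},

evaluated in log space with log-sum-exp over the inner index. We validated
this form (and the special cases) against the matrix exponential of the
generator truncated at state 200: agreement is ≤ 1e−8 over i, j ≤ 9 and
t ∈ [0.01, 2]; the j = 1 row reduces to (rt)^{i−1}/(1+rt)^{i+1} as it must.
Two numerical choices: rt < 1e−12 returns the Kronecker delta (avoids 0⁰
and the divergent (rt)^{−2k} terms), and probability mass escaping to
states above k is *dropped, not renormalized* — the likelihood is defined
on the truncated state space, and renormalizing would silently change it.

Observation error is a plain Normal density centered on the true integer
state with shared standard deviation σ; it is deliberately not truncated or
renormalized to [0, k]. σ carries a Uniform(0, 9) prior — the bounds come
from the state-space limits; we place the prior on σ itself (placing it on
σ² instead would only reweight by a factor ∝ σ and changes nothing
qualitative).

## Likelihood

Bins are independent; each bin is evaluated by Felsenstein pruning with two
modifications: leaf partials are the Gaussian error densities of the
observed (possibly non-integer) value against each state, and the root is
weighted by P(x | 2, d) — the kernel run down a stem of length d from the
diploid ancestor — instead of a stationary distribution. Missing entries
(NaN) become all-zero log partials. Branch transition matrices are
evaluated at the *effective* branch length (time duration × local-clock
rate multiplier); the stem predates the sampled lineages and always uses
rate 1. Partials propagate in linear space with a per-bin max rescaling at
every node, accumulating the scale in log space — stable for 15k-bin
profiles. Matrices are cached keyed by the effective length rounded to 12
significant digits (pure performance; no semantic effect).

## Priors and MCMC

Tree prior: the constant-rate reconstructed birth-death process in the
(r_d, r_e) parameterization (speciation λ = r_d/(1−r_e), extinction
μ = λ r_e), conditioned on the number of tips n with an improper uniform
prior on the origin time. Writing p₁(t) = r² e^{−rt}/(λ − μe^{−rt})² and
x₁ for the root height, the density used is

    f ∝ n · λ · [r e^{−r x₁} / (λ (λ − μ e^{−r x₁}))] · Π_{i=1}^{n−1} λ p₁(x_i),

where the conditioning constant comes from ∫ P(n | t₀) dt₀ = 1/(λn). For
n = 2 this integrates to exactly 1 for every (r_d, r_e), which the test
suite checks by quadrature — the dependence on (r_d, r_e) must be exact
because both are sampled. The density depends on node heights only, so
conditional on heights all labeled histories are equally probable; the
prior-only sampler reproduces the implied 4-leaf topology law (caterpillar
topologies 1/18, balanced 1/9).

Random local clock: every non-root branch carries an indicator and a
multiplier; a branch's effective rate is the multiplier of its nearest
ancestor-or-self branch with an active indicator, else 1. The prior is
Poisson(λ_R = log 2) on the number of active indicators (probability 0.5 of
a strict clock), uniform over placements, Gamma(α = 0.5, scale β = 2) on
active multipliers. Mean rate is not renormalized: the overall time scale
is non-identifiable anyway and is absorbed downstream by OLS scaling.
Indicator flips are reversible-jump moves whose activation proposal draws
the multiplier from its Gamma prior, so prior and proposal densities cancel
in the Hastings ratio.

Moves: narrow exchange, wide exchange, Wilson–Balding, a within-branch
height slide, uniform internal-node height draws, root-height and
whole-tree scalers, multiplicative scale moves on σ, d, r_d, additive
window walks on σ, d, r_e, and the two RLC moves. The additive walks exist
because multiplicative moves traverse a bounded uniform prior slowly when
the posterior is flat in that parameter. Wilson–Balding excludes pruning a
child of the root and reattaching above the root; root-adjacent topology
changes are reachable through the exchanges, and restricting the move keeps
its Hastings ratio exactly the attachment-interval length ratio. The
subtree slide is the height-slide variant confined to the current branch
interval; topology changes come from the exchanges and Wilson–Balding.
Proposals that violate tree constraints or leave a prior support
auto-reject. The sampler recomputes the posterior of each proposal in full
(no incremental updates), trading a little speed for the guarantee that
cached and fresh values cannot diverge.

Initialization is deterministic: average-linkage (UPGMA) tree on per-cell
mean L1 distances, rescaled to root height 0.5, d = σ = 0.5, r_d = 1,
r_e = 0.5, all indicators off. Coupled chains (optional) heat the full
posterior with β_i = 1/(1 + iΔ), Δ = 0.1, propose adjacent-pair state swaps
every 100 steps with the standard tempered ratio, and log only the cold
chain. An optional deterministic 1-in-20 bin subsampling stride reduces
the dependence between neighboring bins before inference.

## Simulator

The simulator is the package's ground-truth generator, not a test fixture.
The genome is linearized to [0, 1) (3 Gbp for base-pair conversion); event
positions are drawn by inverse CDF from f(x) ∝ exp(Σ_{i=1}^{30}
sin(1000x + φᵢ) λᵢ) with φᵢ ~ U(−π, π), λᵢ ~ U(0, a), normalized on a 2²⁰
midpoint grid (a = 0 is exactly uniform; a = 0.6 is the default
non-uniformity, which makes >90% of events overlap another event at
realistic intensities). Per branch — the diploid stem included — the event
count is Poisson(c·t); each event picks an allele (both start at one copy),
a sign, and a size 2 Mbp + Exp(10 Mbp). Events apply on a fixed coordinate
frame in a uniform pseudo-time order within each branch: a gain adds one
copy over its interval, a loss subtracts one with a floor at zero per
affected sub-interval (matching the kernel's absorbing zero). Bin values
are overlap-length-weighted means of total copy number, rounded half-up.
Event multipliers c ∈ {90, 125, 250} correspond to low/medium/high CNA
burden on trees with root height ~1.

The observation step stands in for a read-alignment + CN-calling pipeline
with a calibrated rounded-Gaussian perturbation: the jitter SD solves
2Φ(−0.5/s) = target error rate, and outputs are clipped to [0, k]. What
this emulates well: the marginal per-entry error rate of real callers.
What it does not: within-segment error correlation, breakpoint slippage,
whole-arm miscalls, non-integer ratio outputs, and values outside [0, k].
Passing tests on this generator therefore demonstrate correctness of the
inference machinery under the model's own assumptions plus bin-level
independent noise — not robustness to structured caller artifacts.

## Ancestral reconstruction

Joint maximum likelihood by max-product dynamic programming on a fixed
tree: the upward pass stores, for each node and each *parent* state, the
best achievable sub-likelihood and the argmax own-state (leaves maximize
error density × transition); the root maximizes P(x | 2, d) times the
children's bests; the downward pass reads off the assignment. Leaf states
are maximized inside the same pass, which is what yields error-corrected
leaf profiles. Ties break to the lowest state (deterministic and
reproducible; tie sets are tiny in practice). Bins reconstruct
independently and the DP provably attains the exhaustive-search maximum on
small instances (tested to 4 leaves, k = 4). When reconstructing on a tree
whose branch lengths are in simulator units, convert them to kernel units
first (per-bin event intensity over kernel rate at the diploid state,
e.g. ×0.25 for c = 125 on 15k bins of a 3 Gbp genome); on a tree inferred
by this package the scale is already the likelihood's own.

## Posterior summaries and evaluation

MCC tree: the *sampled* tree maximizing the product of its clades'
posterior frequencies (clade = rooted leaf-label set). Median node heights
are taken per clade over the samples containing it; the annotation can
violate parent > child ordering and is flagged, never silently repaired.
HPD: shortest window containing ⌈mass·n⌉ sorted samples. Tree scaling:
β = Σxᵢyᵢ/Σxᵢ² (no intercept) over clades shared between the
median-height MCC tree and the reference, with the root clade excluded;
the same β scales every posterior sample. Branch recovery is reported by
rank-based deciles of true branch length (average-rank ties). Pairwise
mutation distances multiply branch durations by their effective clock
rates; min-max normalization makes them scale-free before the
||N_T − N_R||₂/(|L|−1)² error. Coverage counts matched true clades (≥ 2
height samples) whose height falls in the scaled 95% HPD. Burn-in (default
20%) and thinning are applied before all summaries.

## Problem sizes used by the test suite

Oracle tests run exhaustive enumeration up to 4 leaves and k = 5 (likelihood)
or k = 4 (reconstruction). Prior-only calibration uses 10⁵ steps on 4
leaves. The end-to-end recovery experiment simulates c = 125 on a 10-leaf
tree, bins 15k → 750 by 1/20 subsampling, and runs a single 2×10⁵-step
chain with 2 001 logged samples; after OLS scaling, all matched true node
heights fall in their 95% HPDs and the MCC tree contains every top-half
true clade. The overlap statistic uses 50-leaf trees and ten replicates per
event multiplier.

## Known limitations

- **Error-model degeneracy on exactly representable data.** If every
  observed value is an integer inside [0, k] — as the bundled noise model
  produces — a state assignment exists that fits the data perfectly, so the
  likelihood grows like σ^{−N} as σ → 0 and the posterior on σ is
  improper: long chains drive σ toward 0, where inference behaves like the
  error-free model on the rounded observations and noise gets absorbed
  into terminal branch lengths, compressing relative node heights. Real
  caller output (non-integer ratios, values above k) anchors σ away from
  zero; with such data, or with σ fixed near the known noise scale, the
  error model behaves as intended. The end-to-end recovery test therefore
  runs on noise-free simulated profiles; the degeneracy is a property of
  pairing a continuous error density with fully representable discrete
  data, and a discretized error density would remove it at the cost of
  changing the model.
- Bins overlapping one CNA are treated as independent observations, so
  posterior spread is somewhat optimistic whenever event sizes exceed the
  bin spacing (mitigated, not removed, by 1/20 subsampling).
- The kernel's event rate scales with copy number (m·r), while real CNA
  rates need not; unequal birth/death rates and inter-bin dependency are
  out of scope.
- Tree heights are inferred only up to a global scale; all reported height
  comparisons go through the OLS factor.
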