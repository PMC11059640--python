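"""Linear birth-death kernel on copy-number states and the observation-error model.

Copy-number evolution within a genomic bin is modelled as a critical linear
(continuous-time) birth-death process: each of the ``m`` current copies is
independently duplicated or deleted at the same per-copy rate ``r``, so the
transition rate from state ``m`` is ``m*r`` up and ``m*r`` down, and state 0
is absorbing.  The transition probability from a parent state ``j`` to a
child state ``i`` after elapsed time ``t`` has the closed form::

    P(i | j, t) = 0                                    if i != j = 0
                = 1                                    if i == j == 0
                = (rt/(1+rt))^j                        if i == 0 != j
                = (rt/(1+rt))^{i+j} *
                  sum_{k=1}^{min(i,j)} C(j,k) C(i-1,k-1) (rt)^{-2k}   otherwise

which reduces to (rt)^{i-1}/(1+rt)^{i+1} for j = 1.  Observed (estimated)
copy numbers are modelled as Gaussian around the true integer state with a
shared standard deviation ``sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "BirthDeathCNModel",
    "ErrorModel",
    "transition_probability",
    "log_transition_probability",
    "transition_matrix",
    "log_error_density",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
# Below this rt the kernel is numerically the identity; avoids 0^0 and the
# divergent (rt)^{-2k} terms.
_RT_EPS = 1e-12


def _log_binom(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def log_transition_probability(i: int, j: int, t: float, r: float = 1.0) -> float:
    """Log of P(child state ``i`` | parent state ``j``, elapsed time ``t``)."""
    if i < 0 or j < 0 or int(i) != i or int(j) != j:
        raise ValueError("states i, j must be non-negative integers")
    if t < 0:
        raise ValueError("elapsed time t must be non-negative")
    if r <= 0:
        raise ValueError("rate r must be positive")
    rt = r * t
    if rt < _RT_EPS:
        return 0.0 if i == j else -np.inf
    if j == 0:
        return 0.0 if i == 0 else -np.inf
    log_rt = np.log(rt)
    log_1prt = np.log1p(rt)
    if i == 0:
        return j * (log_rt - log_1prt)
    kk = np.arange(1, min(i, j) + 1)
    terms = _log_binom(j, kk) + _log_binom(i - 1, kk - 1) - 2.0 * kk * log_rt
    return (i + j) * (log_rt - log_1prt) + float(logsumexp(terms))


def transition_probability(i: int, j: int, t: float, r: float = 1.0) -> float:
    """P(child state ``i`` | parent state ``j``, elapsed time ``t``)."""
    lp = log_transition_probability(i, j, t, r)
    return float(np.exp(lp))


@dataclass(frozen=True)
class BirthDeathCNModel:
    """Critical linear birth-death copy-number model truncated at state ``k``.

    ``r`` is the per-copy event rate (birth = death), in events per copy per
    unit of relative time; ``k`` is the largest copy-number state carried
    through likelihood computations (state space {0, ..., k}).
    """

    r: float = 1.0
    k: int = 9
    _cache: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("r must be positive")
        if self.k < 2:
            raise ValueError("k must be at least 2")

    @property
    def n_states(self) -> int:
        return self.k + 1

    def transition_matrix(self, t: float) -> np.ndarray:
        """(k+1, k+1) matrix, entry [j, i] = P(child=i | parent=j, t); cached.

        Mass escaping to states above ``k`` is dropped (rows sum to <= 1);
        the likelihood is defined on the truncated state space.
        """
        key = float(f"{t:.12g}")
        mat = self._cache.get(key)
        if mat is None:
            if len(self._cache) > 4096:
                self._cache.clear()
            mat = transition_matrix(t, self)
            mat.setflags(write=False)
            self._cache[key] = mat
        return mat


_BINOM_TENSORS: dict[int, np.ndarray] = {}


def _binom_tensor(k: int) -> np.ndarray:
    """W[j-1, i-1, m-1] = log C(j,m) + log C(i-1,m-1), -inf where m > min(i,j)."""
    W = _BINOM_TENSORS.get(k)
    if W is None:
        ii = np.arange(1, k + 1)
        mm = np.arange(1, k + 1)
        J, I, M = np.meshgrid(ii, ii, mm, indexing="ij")
        with np.errstate(invalid="ignore"):
            W = _log_binom(J, M) + _log_binom(I - 1, M - 1)
        W[M > np.minimum(I, J)] = -np.inf
        W.setflags(write=False)
        _BINOM_TENSORS[k] = W
    return W


def transition_matrix(t: float, model: BirthDeathCNModel) -> np.ndarray:
    """Dense truncated transition matrix; see :meth:`BirthDeathCNModel.transition_matrix`."""
    if t < 0:
        raise ValueError("elapsed time t must be non-negative")
    k, r = model.k, model.r
    n = k + 1
    rt = r * t
    if rt < _RT_EPS:
        return np.eye(n)
    log_rt = np.log(rt)
    log_1prt = np.log1p(rt)
    logP = np.full((n, n), -np.inf)
    logP[0, 0] = 0.0
    jj = np.arange(1, n)
    logP[1:, 0] = jj * (log_rt - log_1prt)
    # general case, vectorized log-sum-exp over the inner index
    W = _binom_tensor(k)
    T = W - 2.0 * log_rt * np.arange(1, k + 1)[None, None, :]
    mx = T.max(axis=2)
    lse = mx + np.log(np.exp(T - mx[:, :, None]).sum(axis=2))
    logP[1:, 1:] = (jj[:, None] + jj[None, :]) * (log_rt - log_1prt) + lse
    return np.exp(logP)


@dataclass
class ErrorModel:
    """Gaussian observation error on copy numbers, sigma ~ Uniform(0, 9) a priori."""

    sigma: float = 0.5
    lower_bound: float = 0.0
    upper_bound: float = 9.0

    def __post_init__(self):
        if not self.lower_bound < self.upper_bound:
            raise ValueError("sigma prior bounds must have positive length")

    def in_support(self, sigma: float | None = None) -> bool:
        s = self.sigma if sigma is None else sigma
        return self.lower_bound <= s <= self.upper_bound


def log_error_density(c_obs: float, c_true: float, sigma: float):
    """Log Normal(c_obs; mean=c_true, sd=sigma) density; broadcasts over arrays."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    c_obs = np.asarray(c_obs, dtype=float)
    c_true = np.asarray(c_true, dtype=float)
    with np.errstate(over="ignore"):  # z^2 may overflow to inf for tiny sigma
        z = (c_obs - c_true) / sigma
        out = -0.5 * z * z - np.log(sigma) - _LOG_SQRT_2PI
    return float(out) if out.ndim == 0 else out
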