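"""Parametric complexities for NML / DNML code lengths.

The normalized maximum likelihood (NML) code length of a model class adds
to the negative maximized likelihood the log *parametric complexity* — the
normalizer that sums/integrates the maximized likelihood over all data
realizations.  For Gaussian mixtures scored with the complete likelihood,
the complexity factorizes over hard cluster assignments, giving

    C_mix(K, N) = sum_{n_1+..+n_K=N} N!/(prod n_k!) prod (n_k/N)^{n_k}
                  * prod C_gauss(n_k),

computable by a binomial recursion in K, and the decomposed variant (DNML)
replaces the sum by the observed assignment: log C_mult(K, N) +
sum_k log C_gauss(N_k).

The multinomial complexity C_mult uses the exact linear-in-K two-term
recursion.  The Gaussian complexity diverges over an unbounded parameter
domain, so it is defined over an explicit bounded domain: the mean in a
Euclidean ball of radius ``r`` and the covariance constrained through its
Cholesky factor L (diagonal entries in [sqrt(lambda_min), sqrt(lambda_max)],
off-diagonals bounded by sqrt(lambda_max)).  That domain makes the exact
finite-n normalizer separable in closed form; the hyperparameters are
explicit, logged, and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp, multigammaln

__all__ = [
    "NMLHyperparams",
    "multinomial_parametric_complexity",
    "log_gaussian_pc",
    "log_mixture_pc",
    "log_multinomial_pc",
]


@dataclass(frozen=True)
class NMLHyperparams:
    """Bounded-domain constants of the Gaussian parametric complexity.

    ``r`` bounds the mean (Euclidean ball radius); covariance eigenvalue
    scale is confined to [``lambda_min``, ``lambda_max``] through the
    Cholesky-factor box described in the module docstring.  ``lambda_max``
    defaults to ``r``.
    """

    r: float = 1e4
    lambda_min: float = 1e-2
    lambda_max: float | None = None

    @property
    def lam_max(self) -> float:
        return self.r if self.lambda_max is None else self.lambda_max


# ---------------------------------------------------------------------------
# multinomial complexity
# ---------------------------------------------------------------------------

def _log_binomial_pc(n: int) -> float:
    """log C_mult(2, n) by the exact sum over the 2-composition of n."""
    if n == 0:
        return 0.0
    r = np.arange(n + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(r > 0, r * np.log(r / n), 0.0) + np.where(
            n - r > 0, (n - r) * np.log((n - r) / n), 0.0
        )
    logbin = gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)
    return float(logsumexp(logbin + t))


@lru_cache(maxsize=4096)
def log_multinomial_pc(n: int, k: int) -> float:
    """log parametric complexity of a k-outcome multinomial over n draws.

    Exact, via the two-term recursion in k:
    C(k+1, n) = C(k, n) + (n / (k-1)) C(k-1, n), seeded by C(1, n) = 1 and
    the explicit binomial sum for C(2, n).
    """
    if n < 0 or k < 1:
        raise ValueError("need n >= 0 and k >= 1")
    if k == 1 or n == 0:
        return 0.0
    log_prev = 0.0  # C(1)
    log_cur = _log_binomial_pc(n)  # C(2)
    for j in range(2, k):
        log_prev, log_cur = log_cur, np.logaddexp(
            log_cur, np.log(n / (j - 1)) + log_prev
        )
    return float(log_cur)


def multinomial_parametric_complexity(n: int, k: int) -> float:
    """The multinomial parametric complexity itself (not its log)."""
    return float(np.exp(log_multinomial_pc(n, k)))


# ---------------------------------------------------------------------------
# Gaussian complexity over the bounded domain
# ---------------------------------------------------------------------------

def _log_domain_volume(d: int, hp: NMLHyperparams) -> float:
    """log of V_mu * I_Sigma for the bounded parameter domain.

    V_mu is the volume of the mean ball; I_Sigma is the exact integral of
    det(Sigma)^{-(d+2)/2} over the Cholesky box, which separates into 1-D
    factors:  2^d * prod_i (lambda_min^{-i/2} - lambda_max^{-i/2}) / i
    times (2 sqrt(lambda_max))^{d(d-1)/2} for the off-diagonal entries.
    """
    lam_min, lam_max = hp.lambda_min, hp.lam_max
    if not (0 < lam_min < lam_max):
        raise ValueError("need 0 < lambda_min < lambda_max")
    log_v_mu = (d / 2) * np.log(np.pi) + d * np.log(hp.r) - gammaln(d / 2 + 1)
    i = np.arange(1, d + 1)
    diag = np.log(lam_min ** (-i / 2) - lam_max ** (-i / 2)) - np.log(i)
    log_i_sigma = d * np.log(2.0) + diag.sum() + (d * (d - 1) / 2) * np.log(
        2 * np.sqrt(lam_max)
    )
    return float(log_v_mu + log_i_sigma)


def log_gaussian_pc(n: int, d: int, hp: NMLHyperparams = NMLHyperparams()) -> float:
    """log parametric complexity of a d-variate Gaussian over n points.

    Exact for n >= d + 1 (where the ML covariance is a.s. nonsingular):

        log C = log V + (d/2) log(n / 2 pi) + (d (n-1) / 2) log(n / 2)
                - n d / 2 - log Gamma_d((n-1)/2),

    with V the bounded-domain volume above; derived from the sampling
    density of the ML estimator (Gaussian mean, Wishart covariance).
    For 1 <= n <= d the ML covariance is singular and the exact normalizer
    degenerates; the Rissanen asymptotic (D/2) log(n / 2 pi) + log V with
    D = d(d+3)/2 is used instead.  n = 0 returns 0 (empty cluster).
    """
    if n < 0 or d < 1:
        raise ValueError("need n >= 0 and d >= 1")
    if n == 0:
        return 0.0
    log_v = _log_domain_volume(d, hp)
    if n <= d:
        free = d * (d + 3) / 2
        return float(log_v + (free / 2) * np.log(n / (2 * np.pi)))
    nu = n - 1
    return float(
        log_v
        + (d / 2) * np.log(n / (2 * np.pi))
        + (d * nu / 2) * np.log(n / 2)
        - n * d / 2
        - multigammaln(nu / 2, d)
    )


# ---------------------------------------------------------------------------
# complete-likelihood NML complexity of a Gaussian mixture
# ---------------------------------------------------------------------------

_TABLE_CACHE: dict = {}


def _mixture_pc_table(n: int, k_max: int, d: int, hp: NMLHyperparams) -> np.ndarray:
    """Table T[k, m] = log C_mix(k, m) for k = 1..k_max, m = 0..n (cached,
    grown on demand so successive candidate sizes share work)."""
    key = (n, d, hp)
    cached = _TABLE_CACHE.get(key)
    if cached is not None and cached.shape[0] > k_max:
        return cached
    k_max = max(k_max, cached.shape[0] - 1 if cached is not None else 0)
    m_all = np.arange(n + 1)
    log_cg = np.array([log_gaussian_pc(int(m), d, hp) for m in m_all])
    with np.errstate(divide="ignore", invalid="ignore"):
        xlx = np.where(m_all > 0, m_all * np.log(m_all), 0.0)
    lgam = gammaln(m_all + 1.0)

    table = np.empty((k_max + 1, n + 1))
    table[1] = log_cg
    for k in range(2, k_max + 1):
        prev = table[k - 1]
        for m in range(n + 1):
            r = np.arange(m + 1)
            # log [ binom(m, r) (r/m)^r ((m-r)/m)^(m-r) ]
            log_split = (
                lgam[m] - lgam[r] - lgam[m - r] + xlx[r] + xlx[m - r]
                - (m * np.log(m) if m > 0 else 0.0)
            )
            table[k, m] = logsumexp(log_split + log_cg[r] + prev[m - r])
    _TABLE_CACHE[key] = table
    return table


def log_mixture_pc(
    n: int, k: int, d: int, hp: NMLHyperparams = NMLHyperparams()
) -> float:
    """log C_mix(k, n): complete-likelihood NML complexity of a k-component
    d-variate Gaussian mixture over n points (binomial recursion in k)."""
    if k < 1 or n < 0:
        raise ValueError("need k >= 1 and n >= 0")
    if k == 1:
        return log_gaussian_pc(n, d, hp)
    return float(_mixture_pc_table(n, k, d, hp)[k, n])
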