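"""Mixture complexity (MC): a continuous effective cluster count.

Given a finite mixture model and data, the posterior responsibility matrix
``gamma`` (N points x K components, rows summing to one) is a plug-in
estimate of the joint behaviour of the observed variable X and the latent
component label Z.  MC is the plug-in estimate of the mutual information
I(Z; X),

    MC = H~(Z) - H~(Z|X)
       = -sum_k rho_k log rho_k + (1/W) sum_n w_n sum_k gamma_nk log gamma_nk,

with rho_k the (weighted) column means of ``gamma`` and W the total weight.
``exp(MC)`` lies in [1, K] and behaves as a continuous cluster count:
it equals K for K balanced, fully separated components and 1 when all
components coincide (or all weight sits on one component).  All logarithms
are natural, so MC is reported in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MCValue",
    "estimate_proportions",
    "mixture_complexity",
    "mc_from_model",
    "validate_posterior",
]

#: absolute slack used when clamping MC into [0, log K]
_CLAMP_TOL = 1e-12
#: tolerance for the row-sum check of a posterior matrix
_ROW_SUM_TOL = 1e-9


def validate_posterior(gamma: np.ndarray) -> np.ndarray:
    """Validate and return an N x K posterior responsibility matrix.

    Entries must lie in [0, 1] and every row must sum to one within 1e-9.
    Exact zeros are allowed (no clamping is applied).
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 2:
        raise ValueError(f"posterior matrix must be 2-D, got shape {gamma.shape}")
    n, k = gamma.shape
    if n < 1 or k < 1:
        raise ValueError(f"posterior matrix must be at least 1x1, got {n}x{k}")
    if np.any(gamma < 0.0) or np.any(gamma > 1.0):
        raise ValueError("posterior entries must lie in [0, 1]")
    row_sums = gamma.sum(axis=1)
    bad = np.abs(row_sums - 1.0) > _ROW_SUM_TOL
    if np.any(bad):
        idx = int(np.argmax(bad))
        raise ValueError(
            f"posterior rows must sum to 1 (row {idx} sums to {row_sums[idx]!r})"
        )
    return gamma


def _validate_weights(weights, n: int) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights must have shape ({n},), got {w.shape}")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if not w.sum() > 0:
        raise ValueError("weights must not all be zero")
    return w


def estimate_proportions(gamma: np.ndarray, weights=None) -> np.ndarray:
    """Plug-in mixture proportions: (weighted) column means of ``gamma``.

    rho_k = sum_n w_n gamma_nk / sum_n w_n.  With no weights this is the
    ordinary column mean.  The result sums to one.
    """
    gamma = validate_posterior(gamma)
    n = gamma.shape[0]
    if weights is None:
        return gamma.mean(axis=0)
    w = _validate_weights(weights, n)
    return w @ gamma / w.sum()


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p*log(p) with the 0*log0 := 0 convention, entrywise."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


@dataclass(frozen=True)
class MCValue:
    """Mixture complexity in nats and its exponential (effective clusters)."""

    mc: float
    exp_mc: float

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.mc


def mixture_complexity(gamma: np.ndarray, weights=None, *, validate: bool = True) -> MCValue:
    """Compute the mixture complexity of a posterior responsibility matrix.

    Parameters
    ----------
    gamma : array-like, shape (N, K)
        Posterior responsibilities; rows sum to one.
    weights : array-like of shape (N,), optional
        Nonnegative per-point weights (not all zero).  Omitted means
        uniform weights, which gives an identical result.
    validate : bool
        Skip input validation when False (internal hot paths).

    Returns
    -------
    MCValue
        ``mc`` in nats, guaranteed in [0, log K] up to clamping of float
        error below 1e-12, and ``exp_mc = exp(mc)`` in [1, K].
    """
    gamma = validate_posterior(gamma) if validate else np.asarray(gamma, dtype=float)
    n, k = gamma.shape
    if weights is not None:
        w_arr = np.asarray(weights, dtype=float)
        if w_arr.size and np.all(w_arr == w_arr.flat[0]) and w_arr.flat[0] > 0:
            weights = None  # uniform weights are exactly the unweighted case
    per_point = _xlogx(gamma).sum(axis=1)  # sum_k gamma log gamma, per row
    if weights is None:
        rho = gamma.mean(axis=0)
        cond = per_point.mean()
    else:
        w = _validate_weights(weights, n) if validate else np.asarray(weights, float)
        total = w.sum()
        rho = w @ gamma / total
        cond = (w @ per_point) / total
    mc = -_xlogx(rho).sum() + cond
    # clamp pure floating-point excursions outside the provable range
    log_k = np.log(k)
    if -_CLAMP_TOL < mc < _CLAMP_TOL:
        mc = 0.0
    elif log_k < mc < log_k + _CLAMP_TOL:
        mc = log_k
    return MCValue(mc=float(mc), exp_mc=float(np.exp(mc)))


def mc_from_model(data: np.ndarray, params, weights=None) -> MCValue:
    """MC of ``data`` under a fitted Gaussian mixture.

    Composes the posterior-responsibility computation with
    :func:`mixture_complexity`; ``params`` is a :class:`~mixcomplex.gmm.GMMParams`.
    """
    from .gmm import posterior  # local import to avoid a cycle

    gamma = posterior(params, data)
    return mixture_complexity(gamma, weights, validate=False)
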