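"""Hierarchical decomposition of mixture complexity.

A two-level mixture hierarchy assigns each of the K lower components softly
to L upper components through a row-stochastic K x L matrix Q (Q[k, l] is
the share of component k belonging to upper component l).  MC then splits
exactly into a between-group term and weighted within-group terms:

    MC(total) = MC(interaction) + sum_l W_l * MC(component l),

where the interaction term is the MC of the aggregated N x L posterior
``gamma @ Q``, W_l is the total plug-in weight of upper component l, and
MC(component l) is the MC of the local responsibilities within group l
under the data weights w_n^(l) = w_n * (gamma @ Q)[n, l].  The identity is
algebraic and holds for arbitrary valid (gamma, Q, weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mc import _validate_weights, mixture_complexity, validate_posterior

__all__ = ["DecompositionResult", "decompose", "validate_partition"]


def validate_partition(q: np.ndarray, k: int | None = None) -> np.ndarray:
    """Validate a K x L hierarchy partition: nonnegative, rows sum to one."""
    q = np.asarray(q, dtype=float)
    if q.ndim != 2:
        raise ValueError(f"partition matrix must be 2-D, got shape {q.shape}")
    if k is not None and q.shape[0] != k:
        raise ValueError(
            f"partition has {q.shape[0]} rows but the posterior has {k} components"
        )
    if np.any(q < 0):
        raise ValueError("partition entries must be nonnegative")
    if np.any(np.abs(q.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("partition rows must sum to 1")
    return q


@dataclass(frozen=True)
class DecompositionResult:
    """MC split along a two-level hierarchy.

    Satisfies ``total == interaction + contributions.sum()`` and
    ``contributions == weights * component_mcs`` (all in nats);
    ``weights`` sums to one.
    """

    total: float
    interaction: float
    weights: np.ndarray
    component_mcs: np.ndarray
    contributions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.contributions is None:
            object.__setattr__(
                self, "contributions", self.weights * self.component_mcs
            )

    @property
    def n_upper(self) -> int:
        return len(self.weights)

    def to_dict(self) -> dict:
        d = {"total": self.total, "interaction": self.interaction}
        for l in range(self.n_upper):  # 1-based labels, matching user-facing output
            d[f"W_{l + 1}"] = float(self.weights[l])
            d[f"mc_{l + 1}"] = float(self.component_mcs[l])
            d[f"contribution_{l + 1}"] = float(self.contributions[l])
        return d


def decompose(gamma: np.ndarray, q: np.ndarray, weights=None) -> DecompositionResult:
    """Decompose MC along the hierarchy given by partition ``q``.

    Parameters
    ----------
    gamma : array-like, shape (N, K)
        Lower-level posterior responsibilities.
    q : array-like, shape (K, L)
        Row-stochastic soft assignment of lower to upper components.
    weights : array-like of shape (N,), optional
        Nonnegative data weights.

    Notes
    -----
    When a point has zero aggregate mass in some upper component
    (``(gamma @ q)[n, l] == 0``) its local responsibility row is undefined;
    it is set to the uniform row, which is irrelevant because its local
    weight w_n^(l) is zero.  An upper component with W_l == 0 reports
    MC(component l) = 0 (the weight->0 limit of W_l * MC).
    """
    gamma = validate_posterior(gamma)
    n, k = gamma.shape
    q = validate_partition(q, k)
    n_upper = q.shape[1]
    w = np.ones(n) if weights is None else _validate_weights(weights, n)

    upper_gamma = gamma @ q  # N x L, rows sum to 1
    total = mixture_complexity(gamma, w, validate=False).mc
    interaction = mixture_complexity(upper_gamma, w, validate=False).mc

    rho = w @ gamma / w.sum()
    group_weights = q.T @ rho  # W_l

    component_mcs = np.zeros(n_upper)
    for l in range(n_upper):
        w_l = w * upper_gamma[:, l]
        if not w_l.sum() > 0:
            continue  # degenerate upper component: MC := 0
        local = q[:, l] * gamma  # numerators of the local responsibilities
        denom = upper_gamma[:, l]
        ok = denom > 0
        local[ok] /= denom[ok, None]
        local[~ok] = 1.0 / k  # arbitrary valid row; weight is zero there
        component_mcs[l] = mixture_complexity(local, w_l, validate=False).mc

    return DecompositionResult(
        total=total,
        interaction=interaction,
        weights=group_weights,
        component_mcs=component_mcs,
    )
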