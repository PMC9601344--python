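"""Synthetic benchmark generators.

Two static two-component examples (varying overlap, varying weight
imbalance) and two 150-step streams (the "move" and "imbalance" Gaussian
streams) in which the generating mixture changes gradually over the
transaction period t = 51..100, plus a four-component hierarchy fixture.
Every generator is deterministic given its seed; stream steps draw from
per-step child seeds so any time subset is reproducible.
"""

from __future__ import annotations

import numpy as np

from .gmm import GMMParams

__all__ = [
    "overlap_example",
    "imbalance_example",
    "move_gaussian_stream",
    "imbalance_gaussian_stream",
    "hierarchy_fixture",
    "move_alpha",
    "imbalance_alpha",
]

#: stream length and per-step sample size of the benchmark streams
STREAM_T = 150
STREAM_N = 1000


def _stack_gaussians(rng, sizes, means, d):
    parts = [
        rng.normal(size=(s, d)) + np.asarray(m, dtype=float)
        for s, m in zip(sizes, means)
    ]
    return np.vstack(parts)


def overlap_example(alpha: float, seed: int = 0):
    """Two equal-weight unit Gaussians in 2-D at distance ``alpha``.

    300 points per component (N=600); returns ``(data, params)`` with the
    true two-component model (rho = (1/2, 1/2), identity covariances).
    The effective cluster count exp(MC) under the true posteriors grows
    from 1.0 at alpha=0 to about 2.0 at alpha=6.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = np.random.default_rng(seed)
    means = [[0.0, 0.0], [float(alpha), 0.0]]
    data = _stack_gaussians(rng, [300, 300], means, 2)
    params = GMMParams(
        proportions=np.array([0.5, 0.5]),
        means=np.array(means),
        covariances=np.stack([np.eye(2)] * 2),
    )
    return data, params


def imbalance_example(alpha: int, seed: int = 0):
    """Two unit Gaussians 6 apart with sizes 300+alpha and 300-alpha (N=600).

    True proportions ((300+alpha)/600, (300-alpha)/600); alpha in [0, 300].
    exp(MC) under the true posteriors shrinks from about 2.0 at alpha=0 to
    exactly 1.0 at alpha=300 (the second component has zero weight).
    """
    alpha = int(alpha)
    if not 0 <= alpha <= 300:
        raise ValueError("alpha must lie in [0, 300]")
    rng = np.random.default_rng(seed)
    means = [[0.0, 0.0], [6.0, 0.0]]
    data = _stack_gaussians(rng, [300 + alpha, 300 - alpha], means, 2)
    params = GMMParams(
        proportions=np.array([(300 + alpha) / 600, (300 - alpha) / 600]),
        means=np.array(means),
        covariances=np.stack([np.eye(2)] * 2),
    )
    return data, params


def move_alpha(t: int) -> float:
    """Mean-shift schedule of the move stream: 0, then 0.12(t-50), then 6."""
    if t <= 50:
        return 0.0
    if t <= 100:
        return 0.12 * (t - 50)
    return 6.0


def imbalance_alpha(t: int) -> int:
    """Size-shift schedule of the imbalance stream: 0, then 5(t-51), then 250."""
    if t <= 50:
        return 0
    if t <= 100:
        return 5 * (t - 51)
    return 250


def _spawn_step_rngs(seed: int, t_len: int):
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(t_len)]


def move_gaussian_stream(seed: int = 0) -> list[np.ndarray]:
    """150 steps of 1000 3-D points; the third component's mean moves from
    [10,0,0] to [16,0,0] during t=51..100 (components 333/333/334)."""
    out = []
    for t, rng in enumerate(_spawn_step_rngs(seed, STREAM_T), start=1):
        a = move_alpha(t)
        means = [[0, 0, 0], [10, 0, 0], [10 + a, 0, 0]]
        out.append(_stack_gaussians(rng, [333, 333, 334], means, 3))
    return out


def imbalance_gaussian_stream(seed: int = 0) -> list[np.ndarray]:
    """150 steps of 1000 3-D points on a line of four unit Gaussians; the
    fourth component's size shrinks 250 -> 0 during t=51..100."""
    out = []
    for t, rng in enumerate(_spawn_step_rngs(seed, STREAM_T), start=1):
        a = imbalance_alpha(t)
        means = [[0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0]]
        sizes = [250, 250, 250 + a, 250 - a]
        out.append(_stack_gaussians(rng, [s for s in sizes if s > 0],
                                    [m for s, m in zip(sizes, means) if s > 0], 3))
    return out


def hierarchy_fixture(seed: int = 0, n_per_component: int = 100):
    """Four unit Gaussians forming two distant pairs, plus a hard 2-group
    partition: within-pair mean distance 1, between-pair distance 20.

    Returns ``(data, params, q)`` where ``q`` is the 4x2 row-stochastic
    assignment of the lower components to their pairs.  Useful for
    exercising the decomposition: the pairs are far apart (large
    interaction term) while each pair overlaps heavily internally (small
    per-group MC).
    """
    rng = np.random.default_rng(seed)
    means = np.array(
        [[-0.5, 0.0], [0.5, 0.0], [19.5, 0.0], [20.5, 0.0]], dtype=float
    )
    data = _stack_gaussians(rng, [n_per_component] * 4, means, 2)
    params = GMMParams(
        proportions=np.full(4, 0.25),
        means=means,
        covariances=np.stack([np.eye(2)] * 4),
    )
    q = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    return data, params, q
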