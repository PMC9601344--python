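"""Tracking mixture complexity over a data stream.

:class:`MixtureTracker` is the model object: it holds a time-indexed
sequence of data matrices and a model-selection configuration.  ``fit()``
runs SDMS sequentially (each step's candidate sizes are the previous
selection's neighbours), computes MC from the selected model's
responsibilities at every step, and returns a :class:`TrackingResults`.

``fit(decomposition_size=L)`` additionally runs a stream-wide weighted
fuzzy c-means over all per-step component means (weighted by their mixture
proportions) to estimate L upper components that are common across time,
and decomposes each step's MC along the resulting soft partition.  This is
a two-pass (offline) procedure; plain tracking is single-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmm import CriterionConfig, FittingError, GMMParams, posterior, sdms_step
from .hierarchy import DecompositionResult, decompose
from .mc import mixture_complexity

__all__ = [
    "MixtureTracker",
    "TrackingResults",
    "FCMState",
    "weighted_fcm",
    "track_mc",
    "track_mc_decomposed",
]


# ---------------------------------------------------------------------------
# weighted fuzzy c-means
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FCMState:
    """Converged state of the weighted fuzzy c-means.

    ``centers`` are the L upper-component centers; ``memberships`` has one
    row per input point, rows summing to one; ``loss`` is the final value
    of sum_i w_i sum_l u_il^m ||x_i - c_l||^2, nonincreasing across the
    recorded ``loss_history``.
    """

    centers: np.ndarray
    memberships: np.ndarray
    fuzziness: float
    loss: float
    loss_history: np.ndarray


def _fcm_memberships(points: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 0.0
    u = np.empty_like(d2)
    with np.errstate(divide="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
    any_zero = zero.any(axis=1)
    # minimizer of the fuzzy loss: u ∝ dist^(-2/(m-1)); points coinciding
    # with one or more centers split their membership among those centers
    u[~any_zero] = inv[~any_zero] / inv[~any_zero].sum(axis=1, keepdims=True)
    u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    return u


def weighted_fcm(
    points: np.ndarray,
    weights: np.ndarray,
    n_clusters: int,
    m: float = 1.5,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 300,
) -> FCMState:
    """Fuzzy c-means over weighted points.

    Alternates membership updates (u ∝ ||x - c||^(-2/(m-1)), normalized
    over clusters) with center updates (the u^m- and weight-weighted mean)
    until the loss improves by less than ``tol`` or ``max_iter`` is hit.
    Centers are initialized as a seeded draw of distinct points.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    weights = np.asarray(weights, dtype=float)
    n = points.shape[0]
    if weights.shape != (n,):
        raise ValueError("weights must match the number of points")
    if m <= 1:
        raise ValueError("fuzziness m must be > 1")
    distinct = np.unique(points, axis=0)
    if len(distinct) < n_clusters:
        raise ValueError(
            f"need at least {n_clusters} distinct points, got {len(distinct)}"
        )
    rng = np.random.default_rng(seed)
    centers = distinct[rng.choice(len(distinct), size=n_clusters, replace=False)]

    losses = []
    u = _fcm_memberships(points, centers, m)
    for _ in range(max_iter):
        um = weights[:, None] * u**m
        centers = (um.T @ points) / um.sum(axis=0)[:, None]
        u = _fcm_memberships(points, centers, m)
        d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        loss = float((weights[:, None] * u**m * d2).sum())
        if losses and losses[-1] - loss < tol:
            losses.append(loss)
            break
        losses.append(loss)
    return FCMState(
        centers=centers,
        memberships=u,
        fuzziness=m,
        loss=losses[-1],
        loss_history=np.asarray(losses),
    )


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------

@dataclass
class TrackingResults:
    """Per-step selections, MC series, and (optionally) its decomposition.

    Attributes use trailing underscores for estimated quantities, indexed
    t = 1..T.  Failed steps (all candidates failed to fit) carry NaN in the
    numeric series and None in ``params_``; their indices are listed in
    ``failed_steps``.
    """

    config: CriterionConfig
    k_hat_: np.ndarray  # (T,) float, NaN at failed steps
    mc_: np.ndarray  # (T,) nats
    params_: list[GMMParams | None]
    #: per step: map of candidate K -> total SDMS cost (nats); None at gaps
    candidate_scores_: list[dict[int, float] | None] = field(default_factory=list)
    failed_steps: list[int] = field(default_factory=list)
    # decomposition (present when fitted with decomposition_size)
    fcm_: FCMState | None = None
    interaction_: np.ndarray | None = None
    weights_: np.ndarray | None = None  # (T, L)
    component_mcs_: np.ndarray | None = None  # (T, L)
    decompositions_: list[DecompositionResult | None] | None = None

    @property
    def n_steps(self) -> int:
        return len(self.mc_)

    @property
    def exp_mc_(self) -> np.ndarray:
        return np.exp(self.mc_)

    def to_frame(self) -> pd.DataFrame:
        """Per-step series as a DataFrame indexed by t = 1..T."""
        df = pd.DataFrame(
            {"k_hat": self.k_hat_, "mc": self.mc_, "exp_mc": self.exp_mc_},
            index=pd.RangeIndex(1, self.n_steps + 1, name="t"),
        )
        if self.interaction_ is not None:
            df["interaction"] = self.interaction_
            n_upper = self.weights_.shape[1]
            for l in range(n_upper):
                df[f"W_{l + 1}"] = self.weights_[:, l]
                df[f"mc_{l + 1}"] = self.component_mcs_[:, l]
                df[f"contribution_{l + 1}"] = (
                    self.weights_[:, l] * self.component_mcs_[:, l]
                )
        return df

    def detect_alerts(self, mode: str = "continuous", **kwargs):
        """Change alerts on the MC series (continuous) or on K (discrete)."""
        from .change import AlertConfig, detect_alerts

        series = self.mc_ if mode == "continuous" else self.k_hat_
        return detect_alerts(series, AlertConfig(mode=mode, **kwargs))

    def summary(self) -> str:
        ok = np.isfinite(self.mc_)
        lines = [
            "Mixture complexity tracking",
            f"  criterion: {self.config.criterion}   k_max: {self.config.k_max}"
            f"   steps: {self.n_steps}   failed: {len(self.failed_steps)}",
            f"  K_hat range: {int(np.nanmin(self.k_hat_))}..{int(np.nanmax(self.k_hat_))}",
            f"  exp(MC) range: {np.exp(np.nanmin(self.mc_)):.3f}.."
            f"{np.exp(np.nanmax(self.mc_)):.3f}",
            f"  mean MC: {self.mc_[ok].mean():.4f} nats",
        ]
        if self.interaction_ is not None:
            lines.append(
                f"  decomposition: L={self.weights_.shape[1]} upper components, "
                f"mean interaction {np.nanmean(self.interaction_):.4f} nats"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model object
# ---------------------------------------------------------------------------

class MixtureTracker:
    """Sequential MC tracking over a stream of data matrices.

    Parameters
    ----------
    stream : sequence of (N_t, d) arrays
        One data matrix per time step.
    config : CriterionConfig, optional
        Criterion, candidate bound ``k_max``, EM restarts and seed.
    """

    def __init__(self, stream, config: CriterionConfig | None = None):
        self.stream = [np.atleast_2d(np.asarray(x, dtype=float)) for x in stream]
        if not self.stream:
            raise ValueError("stream must contain at least one time step")
        d = self.stream[0].shape[1]
        for t, x in enumerate(self.stream, start=1):
            if x.shape[1] != d:
                raise ValueError(f"step {t} has {x.shape[1]} features, expected {d}")
        self.config = config if config is not None else CriterionConfig()

    def fit(
        self,
        decomposition_size: int | None = None,
        fuzziness: float = 1.5,
    ) -> TrackingResults:
        """Run SDMS + MC over the stream; optionally decompose per step.

        Deterministic given ``config.seed``: per-step fitting seeds are
        derived from it up front.
        """
        cfg = self.config
        t_len = len(self.stream)
        rng = np.random.default_rng(cfg.seed)
        step_seeds = rng.integers(0, 2**31 - 1, size=t_len)
        fcm_seed = int(rng.integers(0, 2**31 - 1))

        k_hat = np.full(t_len, np.nan)
        mc = np.full(t_len, np.nan)
        params: list[GMMParams | None] = []
        cand_scores: list[dict[int, float] | None] = []
        failed: list[int] = []
        k_prev: int | None = None
        for t, data in enumerate(self.stream):
            try:
                sel = sdms_step(data, k_prev, cfg, seed=int(step_seeds[t]))
            except FittingError:
                params.append(None)
                cand_scores.append(None)
                failed.append(t + 1)
                continue  # explicit gap; next step keeps the last good K
            gamma = posterior(sel.params, data)
            k_hat[t] = sel.k_hat
            mc[t] = mixture_complexity(gamma, validate=False).mc
            params.append(sel.params)
            cand_scores.append(sel.candidate_scores)
            k_prev = sel.k_hat

        results = TrackingResults(
            config=cfg, k_hat_=k_hat, mc_=mc, params_=params,
            candidate_scores_=cand_scores, failed_steps=failed,
        )
        if decomposition_size is not None:
            self._decompose(results, decomposition_size, fuzziness, fcm_seed)
        return results

    def _decompose(
        self, results: TrackingResults, n_upper: int, m: float, seed: int
    ) -> None:
        # stream-wide clustering of per-step component means, weighted by
        # their mixture proportions: the upper components are common to all t
        pts, wts, owner = [], [], []
        for t, p in enumerate(results.params_):
            if p is None:
                continue
            pts.append(p.means)
            wts.append(p.proportions)
            owner.extend([t] * p.n_components)
        fcm = weighted_fcm(
            np.vstack(pts), np.concatenate(wts), n_upper, m=m, seed=seed
        )
        owner = np.asarray(owner)

        t_len = results.n_steps
        interaction = np.full(t_len, np.nan)
        weights = np.full((t_len, n_upper), np.nan)
        comp_mcs = np.full((t_len, n_upper), np.nan)
        decs: list[DecompositionResult | None] = [None] * t_len
        for t, p in enumerate(results.params_):
            if p is None:
                continue
            q_t = fcm.memberships[owner == t]
            gamma = posterior(p, self.stream[t])
            dec = decompose(gamma, q_t)
            interaction[t] = dec.interaction
            weights[t] = dec.weights
            comp_mcs[t] = dec.component_mcs
            decs[t] = dec
        results.fcm_ = fcm
        results.interaction_ = interaction
        results.weights_ = weights
        results.component_mcs_ = comp_mcs
        results.decompositions_ = decs


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def track_mc(stream, config: CriterionConfig | None = None) -> TrackingResults:
    """Track K-hat and MC over a stream (single-pass)."""
    return MixtureTracker(stream, config).fit()


def track_mc_decomposed(
    stream,
    config: CriterionConfig | None = None,
    n_upper: int = 4,
    m: float = 1.5,
) -> TrackingResults:
    """Track MC and its decomposition along L stream-wide upper components."""
    return MixtureTracker(stream, config).fit(
        decomposition_size=n_upper, fuzziness=m
    )
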