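"""Change alerts on MC / K series and their Delay / FAR evaluation.

The detector slides two adjacent 5-step windows over the series: at step t
it compares median(y[t-9..t-5]) against median(y[t-4..t]).  A continuous
series (MC) alerts when the medians differ by more than a threshold
epsilon; a discrete series (K) alerts when they differ at all.  Alerts are
suppressed while fewer than 5 steps have passed since the last raised
alert.  Against a known transaction period starting at t=51, performance
is scored as Delay = min(t* - 51, 50) (t* the first alert in the
acceptable window, 50 if none) and FAR, the fraction of non-acceptable
time points at which an alert fired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gmm import CriterionConfig

__all__ = [
    "AlertConfig",
    "EvalMetrics",
    "detect_alerts",
    "evaluate",
    "run_benchmark",
]


@dataclass(frozen=True)
class AlertConfig:
    """Alert rule parameters.

    ``mode`` is ``continuous`` (threshold on the median difference, for MC)
    or ``discrete`` (any difference, for K).  With ``one_sided=True`` the
    continuous rule fires only when the early median exceeds the late one
    (a decrease); the default compares absolute differences so increases
    alert as well.
    """

    epsilon: float = 0.01
    mode: str = "continuous"
    one_sided: bool = False
    start: int = 10
    window: int = 5
    refractory: int = 5

    def __post_init__(self):
        if self.mode not in ("continuous", "discrete"):
            raise ValueError("mode must be 'continuous' or 'discrete'")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


def detect_alerts(series, config: AlertConfig = AlertConfig()) -> list[int]:
    """Alert times (1-based) for a series y_1..y_T.

    For t = start..T, compares the medians of y[t-9..t-5] and y[t-4..t]
    (5-step windows; exact middle order statistic).  Raised alerts start a
    refractory period: candidates with t - last_alert < 5 are dropped.
    """
    y = np.asarray(series, dtype=float)
    t_len = len(y)
    w = config.window
    if t_len < 2 * w:
        raise ValueError(f"series must have at least {2 * w} steps, got {t_len}")
    alerts: list[int] = []
    last = None
    for t in range(config.start, t_len + 1):  # 1-based
        early = np.median(y[t - 2 * w : t - w])
        late = np.median(y[t - w : t])
        if not (np.isfinite(early) and np.isfinite(late)):
            continue  # window overlaps a failed-step gap
        if config.mode == "discrete":
            fire = early != late
        elif config.one_sided:
            fire = early - late > config.epsilon
        else:
            fire = abs(early - late) > config.epsilon
        if fire and (last is None or t - last >= config.refractory):
            alerts.append(t)
            last = t
    return alerts


@dataclass(frozen=True)
class EvalMetrics:
    """Delay in [0, 50], false alarm rate in [0, 1], and the alert times."""

    delay: float
    far: float
    alerts: tuple[int, ...]


def evaluate(
    alerts,
    t_len: int = 150,
    accept: tuple[int, int] = (51, 109),
    transaction_start: int = 51,
    start: int = 10,
) -> EvalMetrics:
    """Score a set of alerts against a known change period.

    ``accept`` is the closed interval of times at which alerting is
    acceptable (the transaction period plus the detector's window reach).
    Delay counts from ``transaction_start`` to the first acceptable alert,
    capped at 50; FAR is |alerts outside accept| / |times outside accept|
    within [start, t_len].
    """
    alerts = sorted(int(a) for a in alerts)
    lo, hi = accept
    in_window = [a for a in alerts if lo <= a <= hi]
    cap = 50.0
    delay = min(in_window[0] - transaction_start, cap) if in_window else cap
    eligible = [t for t in range(start, t_len + 1) if not lo <= t <= hi]
    false_alarms = [a for a in alerts if start <= a <= t_len and not lo <= a <= hi]
    far = len(false_alarms) / len(eligible) if eligible else 0.0
    return EvalMetrics(delay=float(delay), far=float(far), alerts=tuple(alerts))


def run_benchmark(
    dataset: str,
    criterion: str = "BIC",
    directions=("forward", "reverse"),
    n_trials: int = 10,
    seed: int = 0,
    k_max: int = 10,
    n_init: int = 10,
    epsilon: float = 0.01,
) -> pd.DataFrame:
    """Delay/FAR of MC- versus K-based alerting on a benchmark stream.

    Regenerates the named stream (``move`` or ``imbalance``) ``n_trials``
    times, tracks it in each requested direction (reverse feeds the same
    stream backwards), detects alerts on the MC series (continuous rule,
    threshold ``epsilon``) and on the K series (discrete rule), and
    averages Delay and FAR over trials.  Returns one row per direction
    with the MC and K scores and their differences (MC - K).
    """
    from .datasets import imbalance_gaussian_stream, move_gaussian_stream
    from .tracking import track_mc

    generators = {"move": move_gaussian_stream, "imbalance": imbalance_gaussian_stream}
    if dataset not in generators:
        raise ValueError(f"dataset must be one of {sorted(generators)}")
    gen = generators[dataset]
    if isinstance(directions, str):
        directions = (directions,)

    rng = np.random.default_rng(seed)
    trial_seeds = rng.integers(0, 2**31 - 1, size=n_trials)
    rows = {dr: [] for dr in directions}
    for s in trial_seeds:
        stream = gen(int(s))
        for dr in directions:
            data = stream if dr == "forward" else stream[::-1]
            cfg = CriterionConfig(
                criterion=criterion, k_max=k_max, n_init=n_init, seed=int(s)
            )
            res = track_mc(data, cfg)
            m_mc = evaluate(
                detect_alerts(res.mc_, AlertConfig(epsilon=epsilon)), len(data)
            )
            m_k = evaluate(
                detect_alerts(res.k_hat_, AlertConfig(mode="discrete")), len(data)
            )
            rows[dr].append((m_mc.delay, m_mc.far, m_k.delay, m_k.far))

    records = []
    for dr in directions:
        arr = np.asarray(rows[dr])
        d_mc, f_mc, d_k, f_k = arr.mean(axis=0)
        records.append(
            {
                "dataset": dataset,
                "criterion": criterion,
                "direction": dr,
                "n_trials": n_trials,
                "delay_mc": d_mc,
                "far_mc": f_mc,
                "delay_k": d_k,
                "far_k": f_k,
                "delay_diff": d_mc - d_k,
                "far_diff": f_mc - f_k,
            }
        )
    return pd.DataFrame.from_records(records)
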