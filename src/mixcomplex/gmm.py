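"""Gaussian mixture fitting and sequential dynamic model selection (SDMS).

Per time step, SDMS restricts the candidate mixture sizes to the previous
selection's neighbours, fits each candidate by EM, and picks the size
minimizing a two-part cost

    L_SDMS = L_model(data; K) + L_change(K | K_prev),

where L_model is one of six code-length criteria (AIC/BIC with observed or
complete likelihood, NML, DNML) and L_change codes the transition of the
mixture size.  EM itself is delegated to scikit-learn; the restart that
minimizes the *configured criterion* (not merely the likelihood) is kept.
All code lengths are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

from .penalties import NMLHyperparams, log_gaussian_pc, log_mixture_pc, log_multinomial_pc

__all__ = [
    "GMMParams",
    "CriterionConfig",
    "SelectionResult",
    "FittingError",
    "CRITERIA",
    "fit_gmm",
    "posterior",
    "hard_assign",
    "log_likelihoods",
    "model_code_length",
    "candidates",
    "change_code_length",
    "sdms_step",
]

CRITERIA = ("AIC", "AIC+comp", "BIC", "BIC+comp", "NML", "DNML")


class FittingError(RuntimeError):
    """Raised when every EM restart (or every candidate) fails."""


@dataclass(frozen=True)
class GMMParams:
    """Parameters of a Gaussian mixture: proportions, means, full covariances."""

    proportions: np.ndarray  # (K,)
    means: np.ndarray  # (K, d)
    covariances: np.ndarray  # (K, d, d)

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        m = np.atleast_2d(np.asarray(self.means, dtype=float))
        c = np.asarray(self.covariances, dtype=float)
        if c.ndim == 2:
            c = c[None, :, :]
        object.__setattr__(self, "proportions", p)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "covariances", c)
        k, d = m.shape
        if p.shape != (k,) or c.shape != (k, d, d):
            raise ValueError("inconsistent shapes among proportions/means/covariances")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be nonnegative and sum to 1")

    @property
    def n_components(self) -> int:
        return self.means.shape[0]

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    @classmethod
    def from_sklearn(cls, gm: GaussianMixture) -> "GMMParams":
        return cls(
            proportions=gm.weights_.copy(),
            means=gm.means_.copy(),
            covariances=gm.covariances_.copy(),
        )


@dataclass(frozen=True)
class CriterionConfig:
    """Configuration of the per-step model selection.

    ``param_count_mode`` chooses the free-parameter count D of a
    K-component d-variate Gaussian mixture: ``standard`` uses
    (K-1) + K d(d+3)/2 (each component carries its own mean and full
    covariance); ``as_printed`` uses (K-1) + d(d+3)/2.
    """

    criterion: str = "BIC"
    k_max: int = 10
    n_init: int = 10
    seed: int = 0
    param_count_mode: str = "standard"
    nml_hyperparams: NMLHyperparams = field(default_factory=NMLHyperparams)
    reg_covar: float = 1e-6
    tol: float = 1e-4
    max_iter: int = 200

    def __post_init__(self):
        if self.criterion not in CRITERIA:
            raise ValueError(
                f"unknown criterion {self.criterion!r}; choose one of {CRITERIA}"
            )
        if self.param_count_mode not in ("standard", "as_printed"):
            raise ValueError("param_count_mode must be 'standard' or 'as_printed'")
        if self.k_max < 1 or self.n_init < 1:
            raise ValueError("k_max and n_init must be >= 1")

    @classmethod
    def from_file(cls, path) -> "CriterionConfig":
        """Load a config from a key/value text file.

        One ``key = value`` (or ``key: value``) pair per line; ``#`` starts
        a comment.  Keys match the constructor arguments, with ``nml_r``,
        ``nml_lambda_min`` and ``nml_lambda_max`` mapping onto
        :class:`~mixcomplex.penalties.NMLHyperparams`.
        """
        text = Path(path).read_text()
        raw: dict[str, str] = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            for sep in ("=", ":"):
                if sep in line:
                    key, _, val = line.partition(sep)
                    raw[key.strip()] = val.strip()
                    break
            else:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        kwargs: dict = {}
        nml: dict = {}
        casts = {
            "criterion": str, "k_max": int, "n_init": int, "seed": int,
            "param_count_mode": str, "reg_covar": float, "tol": float,
            "max_iter": int,
        }
        for key, val in raw.items():
            if key in casts:
                kwargs[key] = casts[key](val)
            elif key in ("nml_r", "nml_lambda_min", "nml_lambda_max"):
                nml[key.removeprefix("nml_")] = float(val)
            else:
                raise ValueError(f"{path}: unknown config key {key!r}")
        if nml:
            kwargs["nml_hyperparams"] = NMLHyperparams(**nml)
        return cls(**kwargs)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one SDMS step: selected size, parameters and scores (nats)."""

    k_hat: int
    params: GMMParams
    score: float
    candidate_scores: dict[int, float]


# ---------------------------------------------------------------------------
# densities and responsibilities
# ---------------------------------------------------------------------------

def _component_log_densities(params: GMMParams, data: np.ndarray) -> np.ndarray:
    """N x K matrix of log N(x_n | mu_k, Sigma_k), Cholesky-based."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n, d = data.shape
    if d != params.n_features:
        raise ValueError(
            f"data has {d} features but the model has {params.n_features}"
        )
    out = np.empty((n, params.n_components))
    for k in range(params.n_components):
        try:
            chol = np.linalg.cholesky(params.covariances[k])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"covariance of component {k + 1} is not positive definite"
            ) from exc
        dev = solve_triangular(chol, (data - params.means[k]).T, lower=True)
        log_det = 2.0 * np.log(np.diag(chol)).sum()
        out[:, k] = -0.5 * (
            d * np.log(2 * np.pi) + log_det + np.einsum("ij,ij->j", dev, dev)
        )
    return out


def posterior(params: GMMParams, data: np.ndarray) -> np.ndarray:
    """Posterior responsibilities gamma_nk = P(Z=k | X=x_n), log-space stable.

    A component with zero proportion yields an identically-zero column.
    """
    log_dens = _component_log_densities(params, data)
    with np.errstate(divide="ignore"):
        log_w = np.log(params.proportions)
    joint = log_dens + log_w  # -inf columns where rho_k == 0
    norm = logsumexp(joint, axis=1, keepdims=True)
    gamma = np.exp(joint - norm)
    return gamma


def hard_assign(gamma: np.ndarray) -> np.ndarray:
    """Row-wise MAP component labels, 1-based; ties go to the lowest index."""
    gamma = np.asarray(gamma, dtype=float)
    return np.argmax(gamma, axis=1) + 1


def log_likelihoods(params: GMMParams, data: np.ndarray) -> tuple[float, float]:
    """(observed, complete) log-likelihoods of ``data`` under ``params``.

    The complete likelihood pairs each point with its MAP label
    z_n = argmax_k gamma_nk.
    """
    log_dens = _component_log_densities(params, data)
    with np.errstate(divide="ignore"):
        joint = log_dens + np.log(params.proportions)
    per_point = logsumexp(joint, axis=1)
    l_obs = float(per_point.sum())
    z = np.argmax(joint - per_point[:, None], axis=1)  # == argmax gamma
    l_comp = float(joint[np.arange(len(z)), z].sum())
    return l_obs, l_comp


# ---------------------------------------------------------------------------
# code lengths
# ---------------------------------------------------------------------------

def _free_params(k: int, d: int, mode: str) -> float:
    if mode == "as_printed":
        return (k - 1) + d * (d + 3) / 2
    return (k - 1) + k * d * (d + 3) / 2


def model_code_length(
    data: np.ndarray, params: GMMParams, config: CriterionConfig
) -> float:
    """Model part of the SDMS cost (nats) under the configured criterion."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n, d = data.shape
    k = params.n_components
    l_obs, l_comp = log_likelihoods(params, data)
    dd = _free_params(k, d, config.param_count_mode)
    crit = config.criterion
    if crit == "AIC":
        return -l_obs + dd
    if crit == "AIC+comp":
        return -l_comp + dd
    if crit == "BIC":
        return -l_obs + dd / 2 * np.log(n)
    if crit == "BIC+comp":
        return -l_comp + dd / 2 * np.log(n)
    hp = config.nml_hyperparams
    if crit == "NML":
        return -l_comp + log_mixture_pc(n, k, d, hp)
    # DNML: multinomial part over the hard assignment + per-cluster Gaussians
    z = hard_assign(posterior(params, data))
    counts = np.bincount(z - 1, minlength=k)
    pc = log_multinomial_pc(n, k) + sum(
        log_gaussian_pc(int(c), d, hp) for c in counts if c > 0
    )
    return -l_comp + pc


def candidates(k_prev: int | None, k_max: int) -> list[int]:
    """Candidate mixture sizes: all of 1..k_max initially, else the
    previous size and its neighbours clipped to [1, k_max]."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_prev is None:
        return list(range(1, k_max + 1))
    return [k for k in (k_prev - 1, k_prev, k_prev + 1) if 1 <= k <= k_max]


def change_code_length(k_t: int, k_prev: int, k_max: int) -> float:
    """Code length (nats) of moving from ``k_prev`` to ``k_t``.

    Probability 1/2 of staying, the remaining 1/2 split uniformly over the
    other admissible candidates; 0 when only one candidate exists.
    """
    cands = candidates(k_prev, k_max)
    if k_t not in cands:
        raise ValueError(f"k_t={k_t} is not an admissible candidate {cands}")
    if len(cands) == 1:
        return 0.0
    if k_t == k_prev:
        return float(np.log(2.0))
    return float(np.log(2.0) + np.log(len(cands) - 1))


# ---------------------------------------------------------------------------
# fitting and the SDMS step
# ---------------------------------------------------------------------------

def fit_gmm(
    data: np.ndarray,
    k: int,
    config: CriterionConfig,
    seed: int | None = None,
) -> GMMParams:
    """Fit a K-component Gaussian mixture by EM with criterion-scored restarts.

    Runs ``config.n_init`` seeded k-means++ initialized EM fits and returns
    the restart minimizing the configured criterion score (which, for the
    complete-likelihood criteria, can differ from the maximum-likelihood
    restart).  Deterministic given ``seed`` (defaults to ``config.seed``).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]
    if n <= k:
        raise FittingError(f"need more than k={k} points, got {n}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=config.n_init)
    best: tuple[float, GMMParams] | None = None
    errors: list[Exception] = []
    for s in restart_seeds:
        try:
            gm = GaussianMixture(
                n_components=k,
                covariance_type="full",
                reg_covar=config.reg_covar,
                tol=config.tol,
                max_iter=config.max_iter,
                n_init=1,
                init_params="k-means++",
                random_state=int(s),
            ).fit(data)
            params = GMMParams.from_sklearn(gm)
            score = model_code_length(data, params, config)
        except (np.linalg.LinAlgError, ValueError) as exc:
            errors.append(exc)
            continue
        if np.isfinite(score) and (best is None or score < best[0]):
            best = (score, params)
    if best is None:
        raise FittingError(
            f"all {config.n_init} EM restarts failed for k={k}: {errors[-1] if errors else 'non-finite scores'}"
        )
    return best[1]


def sdms_step(
    data: np.ndarray,
    k_prev: int | None,
    config: CriterionConfig,
    seed: int | None = None,
) -> SelectionResult:
    """One SDMS step: fit every candidate size and return the cost minimizer.

    Ties in the total cost break toward the smallest candidate.  Candidate
    fitting errors are tolerated as long as at least one candidate fits.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    rng = np.random.default_rng(config.seed if seed is None else seed)
    scores: dict[int, float] = {}
    fits: dict[int, GMMParams] = {}
    errors: list[Exception] = []
    for k in candidates(k_prev, config.k_max):
        child = int(rng.integers(0, 2**31 - 1))
        try:
            params = fit_gmm(data, k, config, seed=child)
        except FittingError as exc:
            errors.append(exc)
            continue
        cost = model_code_length(data, params, config)
        if k_prev is not None:
            cost += change_code_length(k, k_prev, config.k_max)
        scores[k] = float(cost)
        fits[k] = params
    if not scores:
        raise FittingError(f"every candidate failed: {errors[-1]}")
    k_hat = min(sorted(scores), key=lambda k: scores[k])
    return SelectionResult(
        k_hat=k_hat, params=fits[k_hat], score=scores[k_hat], candidate_scores=scores
    )
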