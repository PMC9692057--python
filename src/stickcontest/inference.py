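"""Bayesian fitting and predictive model comparison.

Posteriors are sampled with random-walk Metropolis (four chains, long
burn-in, heavy thinning), matching the lightweight-MCMC style the
variants were designed for; no gradients are required.  Point estimates
come from multi-start bounded optimisation of the log posterior (MAP)
or the log likelihood (ML).  Out-of-sample predictive performance is
scored by WAIC and PSIS-LOO on the pointwise log-likelihood matrix, and
by k-fold cross-validated parameter fits.

Priors (all parameters are bounded):

* ``beta``      ~ Uniform(0, 10)       perceived persuasive bias
* ``offset``    ~ Uniform(-0.5, 0.5)   slider offset, probability scale
* ``noise_sd``  ~ HalfNormal(0.3)      response noise, probability scale
* mixture weights ~ Uniform(0, 1)
* ``anchor``    ~ Uniform(-1, 1)       MAS reference point
* ``eta``       ~ Uniform(0, 1)        anchor-and-adjust weight
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import arviz as az
import numpy as np
import pandas as pd
from scipy import optimize, special

from .response import DatasetEvaluator, ParticipantRecord, VARIANTS

__all__ = [
    "PRIORS",
    "MCMCConfig",
    "PosteriorDraws",
    "ComparisonRow",
    "sample_posterior",
    "run_mcmc",
    "map_estimate",
    "waic",
    "psis_loo",
    "kfold_cv",
    "compare_models",
]

logger = logging.getLogger(__name__)

# prior family and hyperparameters per parameter name; every mixture
# weight w_* gets Uniform(0, 1)
PRIORS: Dict[str, tuple] = {
    "beta": ("uniform", 0.0, 10.0),
    "offset": ("uniform", -0.5, 0.5),
    "noise_sd": ("halfnormal", 0.3),
    "anchor": ("uniform", -1.0, 1.0),
    "eta": ("uniform", 0.0, 1.0),
}

_NOISE_SD_MAX = 2.0  # practical optimisation bound; prior mass beyond is negligible


def _prior_spec(name: str) -> tuple:
    if name in PRIORS:
        return PRIORS[name]
    if name.startswith("w_"):
        return ("uniform", 0.0, 1.0)
    raise KeyError(f"no prior defined for parameter {name!r}")


def param_bounds(names: Sequence[str]) -> List[Tuple[float, float]]:
    """Support of each parameter's prior (used as optimisation bounds)."""
    out = []
    for name in names:
        spec = _prior_spec(name)
        if spec[0] == "uniform":
            out.append((spec[1], spec[2]))
        else:  # halfnormal
            out.append((1e-4, _NOISE_SD_MAX))
    return out


def log_prior(theta: np.ndarray, names: Sequence[str]) -> float:
    """Joint log prior density; -inf outside the support."""
    lp = 0.0
    for value, name in zip(theta, names):
        spec = _prior_spec(name)
        if spec[0] == "uniform":
            lo, hi = spec[1], spec[2]
            if not (lo <= value <= hi):
                return -math.inf
            lp += -math.log(hi - lo)
        else:
            scale = spec[1]
            if value <= 0:
                return -math.inf
            # half-normal density: sqrt(2/pi)/scale * exp(-v^2 / (2 scale^2))
            lp += 0.5 * math.log(2.0 / math.pi) - math.log(scale) - 0.5 * (value / scale) ** 2
    return lp


def sample_prior(names: Sequence[str], rng: np.random.Generator) -> np.ndarray:
    draw = []
    for name in names:
        spec = _prior_spec(name)
        if spec[0] == "uniform":
            draw.append(rng.uniform(spec[1], spec[2]))
        else:
            draw.append(abs(rng.normal(0.0, spec[1])))
    return np.array(draw)


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler configuration.

    Defaults keep 1,000 posterior draws split across four chains, after
    a burn-in of 7,500 steps and with a thinning lag of 100 steps per
    chain.  Proposal scales adapt toward a 0.2-0.5 acceptance rate
    during burn-in only, so the kept chain is a valid Markov chain.
    """

    n_draws: int = 1000
    n_chains: int = 4
    burn_in: int = 7500
    thin: int = 100
    seed: int = 1
    init_scale: float = 0.1

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if self.n_draws % self.n_chains:
            raise ValueError("n_draws must be divisible by n_chains")


@dataclass
class PosteriorDraws:
    """Kept posterior draws plus the pointwise log-likelihood matrix."""

    draws: np.ndarray  # (n_draws, n_params)
    param_names: Tuple[str, ...]
    pointwise_loglik: np.ndarray  # (n_draws, n_participants)
    chain_ids: np.ndarray  # (n_draws,)
    accept_rates: np.ndarray  # (n_chains,)
    rhat: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.draws.shape[0] != self.pointwise_loglik.shape[0]:
            raise ValueError("draws and pointwise_loglik must have matching row counts")
        if len(np.unique(self.chain_ids)) < 2:
            raise ValueError("at least 2 chains are required for diagnostics")

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws: columns draw, chain, param, value."""
        rows = []
        for j, name in enumerate(self.param_names):
            rows.append(
                pd.DataFrame(
                    {
                        "draw": np.arange(len(self.draws)),
                        "chain": self.chain_ids,
                        "param": name,
                        "value": self.draws[:, j],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd and central 95% interval per parameter."""
        q = np.percentile(self.draws, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "param": self.param_names,
                "mean": self.draws.mean(axis=0),
                "sd": self.draws.std(axis=0, ddof=1),
                "q2.5": q[0],
                "q97.5": q[1],
                "rhat": [self.rhat.get(p, np.nan) for p in self.param_names],
            }
        )


@dataclass(frozen=True)
class ComparisonRow:
    """One row of the model-comparison table."""

    model: str
    variant: str
    max_loglik: float
    waic: float
    waic_se: float
    psis_loo: float
    psis_loo_se: float

    def __post_init__(self):
        if self.waic_se < 0 or self.psis_loo_se < 0:
            raise ValueError("standard errors must be nonnegative")


# ---------------------------------------------------------------------------
# Random-walk Metropolis
# ---------------------------------------------------------------------------

def _metropolis_chain(
    log_post: Callable[[np.ndarray], float],
    x0: np.ndarray,
    n_keep: int,
    burn_in: int,
    thin: int,
    rng: np.random.Generator,
    init_scale: float,
):
    """One adaptive random-walk Metropolis chain (unconstrained space).

    During burn-in the multivariate-normal proposal adapts continuously
    (Robbins-Monro): a global log step size is nudged toward a ~0.3
    acceptance probability while the proposal covariance tracks the
    recursive empirical covariance of the chain, which handles
    parameters whose posterior scales differ by orders of magnitude.
    The proposal is frozen after burn-in, so kept draws come from a
    valid Markov chain.  Returns (kept draws, post-burn-in acceptance
    rate).
    """
    dim = len(x0)
    cov = np.diag(np.full(dim, init_scale**2))
    floor = 1e-12 * np.eye(dim)
    chol = np.linalg.cholesky(cov + floor)
    log_lam = 0.0
    target_accept = 0.3
    mu = x0.astype(float).copy()
    x = x0.astype(float).copy()
    lp = log_post(x)
    if not np.isfinite(lp):
        raise ValueError("non-finite log posterior at initialization")
    kept = np.empty((n_keep, dim))
    n_accept_sampling = 0
    total = burn_in + n_keep * thin
    k = 0
    for step in range(total):
        prop = x + math.exp(log_lam) * (chol @ rng.normal(size=dim))
        lp_prop = log_post(prop)
        log_ratio = lp_prop - lp
        if math.log(rng.uniform()) < log_ratio:
            x, lp = prop, lp_prop
            if step >= burn_in:
                n_accept_sampling += 1
        if step < burn_in:
            alpha = min(1.0, math.exp(min(0.0, log_ratio)))
            gamma = (step + 1) ** -0.6
            log_lam += gamma * (alpha - target_accept)
            diff = x - mu
            mu += gamma * diff
            cov += gamma * (np.outer(diff, diff) - cov)
            if (step + 1) % 50 == 0 and step + 1 >= 10 * dim:
                try:
                    chol = np.linalg.cholesky((2.38**2 / dim) * cov + floor)
                except np.linalg.LinAlgError:  # pragma: no cover
                    pass
        elif (step - burn_in + 1) % thin == 0:
            kept[k] = x
            k += 1
    accept_rate = n_accept_sampling / max(1, n_keep * thin)
    return kept, accept_rate


class _Transform:
    """Bijection between the bounded parameter space and R^d.

    Uniform-prior parameters get a logit transform of their support;
    half-normal parameters a log transform.  Sampling happens in the
    unconstrained space (with the log-Jacobian added to the target), so
    the random-walk proposal never fights the bounds -- important for
    mixture weights whose posteriors hug 0 or 1.
    """

    def __init__(self, names: Sequence[str]):
        self.names = tuple(names)
        specs = [_prior_spec(n) for n in self.names]
        self.is_uniform = np.array([s[0] == "uniform" for s in specs])
        self.lo = np.array([s[1] if s[0] == "uniform" else 0.0 for s in specs])
        self.width = np.array([s[2] - s[1] if s[0] == "uniform" else 1.0 for s in specs])
        self.log_width = np.log(self.width)

    def to_unconstrained(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        p = np.clip((v - self.lo) / self.width, 1e-12, 1.0 - 1e-12)
        return np.where(self.is_uniform, special.logit(p), np.log(np.maximum(v, 1e-12)))

    def to_constrained(self, z: np.ndarray):
        """Returns (v, log |dv/dz|)."""
        s = special.expit(z)
        v_uniform = self.lo + self.width * s
        with np.errstate(over="ignore"):
            v_log = np.exp(z)
        v = np.where(self.is_uniform, v_uniform, v_log)
        with np.errstate(divide="ignore"):
            jac = np.where(
                self.is_uniform,
                self.log_width + np.log(np.maximum(s * (1.0 - s), 1e-300)),
                z,
            )
        return v, float(jac.sum())


def sample_posterior(
    log_lik: Callable[[np.ndarray], float],
    param_names: Sequence[str],
    config: MCMCConfig,
    init: Optional[np.ndarray] = None,
):
    """Sample any log-likelihood over the registered priors.

    Returns (draws, chain_ids, accept_rates, rhat) with draws stacked
    across ``config.n_chains`` chains, on the natural parameter scale.
    Fully reproducible from ``config.seed``.
    """
    names = tuple(param_names)
    transform = _Transform(names)

    def log_post_z(z: np.ndarray) -> float:
        v, log_jac = transform.to_constrained(z)
        lp = log_prior(v, names)
        if not np.isfinite(lp):
            return -math.inf
        ll = log_lik(v)
        if not np.isfinite(ll):
            return -math.inf
        return lp + ll + log_jac

    per_chain = config.n_draws // config.n_chains
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_draws, chain_ids, accept_rates = [], [], []
    for c in range(config.n_chains):
        rng = np.random.default_rng(seeds[c])
        z0 = None
        for _ in range(200):
            v0 = init.copy() if init is not None and z0 is None else sample_prior(names, rng)
            z0 = transform.to_unconstrained(v0)
            if np.isfinite(log_post_z(z0)):
                break
        else:  # pragma: no cover - degenerate likelihood
            raise ValueError("non-finite likelihood at initialization for every prior draw")
        kept_z, rate = _metropolis_chain(
            log_post_z, z0, per_chain, config.burn_in, config.thin, rng, config.init_scale
        )
        kept = np.stack([transform.to_constrained(z)[0] for z in kept_z])
        all_draws.append(kept)
        chain_ids.append(np.full(per_chain, c))
        accept_rates.append(rate)
    draws = np.concatenate(all_draws)
    chain_ids = np.concatenate(chain_ids)
    rhat = _rhat(draws, chain_ids, names)
    return draws, chain_ids, np.array(accept_rates), rhat


def _rhat(draws: np.ndarray, chain_ids: np.ndarray, names: Sequence[str]) -> Dict[str, float]:
    chains = sorted(np.unique(chain_ids))
    stacked = np.stack([draws[chain_ids == c] for c in chains])  # (chain, draw, param)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, name in enumerate(names):
            out[name] = float(az.rhat(az.convert_to_dataset(stacked[:, :, j]))["x"].values)
    return out


def run_mcmc(
    records: Sequence[ParticipantRecord],
    variant: str,
    config: MCMCConfig = MCMCConfig(),
) -> PosteriorDraws:
    """Posterior sampling for one model variant on a participant table.

    Records the pointwise log-likelihood at every kept draw (the input
    to WAIC/PSIS-LOO).  An R-hat above 1.1 is reported as a warning,
    not an error.
    """
    names = VARIANTS[variant] if variant in VARIANTS else None
    if names is None:
        raise ValueError(f"unknown variant {variant!r}")
    ev = DatasetEvaluator(records, variant)

    def log_lik(theta: np.ndarray) -> float:
        return ev.total(dict(zip(names, theta)))

    draws, chain_ids, accept_rates, rhat = sample_posterior(log_lik, names, config)
    pointwise = np.stack([ev.pointwise(dict(zip(names, row))) for row in draws])
    bad = {k: v for k, v in rhat.items() if v > 1.1}
    if bad:
        logger.warning("variant %s: R-hat > 1.1 for %s", variant, bad)
    return PosteriorDraws(
        draws=draws,
        param_names=names,
        pointwise_loglik=pointwise,
        chain_ids=chain_ids,
        accept_rates=accept_rates,
        rhat=rhat,
    )


# ---------------------------------------------------------------------------
# Point estimation
# ---------------------------------------------------------------------------

def map_estimate(
    records: Sequence[ParticipantRecord],
    variant: str,
    seed: int = 1,
    n_starts: int = 8,
    include_prior: bool = True,
    extra_starts: Optional[Sequence[Mapping[str, float]]] = None,
) -> Dict[str, float]:
    """Multi-start MAP (or, with ``include_prior=False``, ML) estimate.

    Runs bounded L-BFGS-B from ``n_starts`` prior draws (plus any
    ``extra_starts``, e.g. a nested variant's optimum) and returns the
    best optimum as a name->value dict, with the achieved objective
    under ``"log_posterior"`` and the log-likelihood at the optimum
    under ``"log_lik"``.  Deterministic given the seed.
    """
    names = VARIANTS[variant] if variant in VARIANTS else None
    if names is None:
        raise ValueError(f"unknown variant {variant!r}")
    ev = DatasetEvaluator(records, variant)
    bounds = param_bounds(names)
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = [np.clip(sample_prior(names, rng), lo, hi) for _ in range(n_starts)]
    starts += [
        np.clip(np.array([s[name] for name in names]), lo, hi) for s in (extra_starts or [])
    ]

    def objective(theta: np.ndarray) -> float:
        ll = ev.total(dict(zip(names, theta)))
        if include_prior:
            ll += log_prior(theta, names)
        return -ll

    best = None
    n_converged = 0
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
        n_converged += bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if n_converged == 0:
        logger.warning("map_estimate(%s): no start converged; returning best iterate", variant)
    out = dict(zip(names, best.x))
    out["log_posterior"] = -best.fun
    out["log_lik"] = float(ev.total(dict(zip(names, best.x))))
    return out


# ---------------------------------------------------------------------------
# Predictive information criteria
# ---------------------------------------------------------------------------

def waic(pointwise_loglik: np.ndarray) -> Tuple[float, float]:
    """Widely applicable information criterion on the deviance scale.

    ``-2 * (lppd - p_waic)`` where ``p_waic`` sums the per-observation
    posterior variance of the log-likelihood.  The standard error comes
    from the spread of the per-observation contributions.  Warns when
    any per-observation variance exceeds 0.4 (the estimate is then
    unreliable).
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("pointwise_loglik must be (n_draws >= 2, n_obs)")
    n_draws, n_obs = ll.shape
    lppd_i = special.logsumexp(ll, axis=0) - math.log(n_draws)
    p_i = ll.var(axis=0, ddof=1)
    if (p_i > 0.4).any():
        warnings.warn(
            f"{int((p_i > 0.4).sum())} observation(s) with p_waic > 0.4; "
            "WAIC may be unreliable",
            stacklevel=2,
        )
    elpd_i = lppd_i - p_i
    value = -2.0 * elpd_i.sum()
    se = 2.0 * math.sqrt(n_obs * elpd_i.var(ddof=1)) if n_obs > 1 else 0.0
    return float(value), float(se)


def psis_loo(pointwise_loglik: np.ndarray) -> Tuple[float, float, np.ndarray]:
    """Pareto-smoothed importance-sampling LOO on the deviance scale.

    Importance ratios ``1/p(y_i | theta_s)`` are stabilised per
    observation by fitting a generalised Pareto distribution to the
    upper tail of the weights.  Returns ``(value, se, pareto_k)``;
    observations with a shape diagnostic k-hat above 0.7 are flagged
    with a warning.  With constant draws this equals the zero-variance
    WAIC value, ``-2 * sum(log p(y_i))``.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise ValueError("pointwise_loglik must be (n_draws >= 2, n_obs)")
    n_draws, n_obs = ll.shape
    spread = ll.max(axis=0) - ll.min(axis=0)
    if np.all(spread < 1e-12):
        # degenerate posterior: uniform weights, exact lppd
        elpd_i = ll[0]
        k_hat = np.full(n_obs, -np.inf)
    else:
        # arviz expects the draws on the last axis
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            log_w, k_hat = az.psislw(-ll.T)
        log_w = np.asarray(log_w).reshape(n_obs, n_draws).T
        k_hat = np.asarray(k_hat).reshape(n_obs)
        elpd_i = special.logsumexp(log_w + ll, axis=0)
    n_bad = int((k_hat > 0.7).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} observation(s) with Pareto k-hat > 0.7; PSIS-LOO may be unreliable",
            stacklevel=2,
        )
    value = -2.0 * elpd_i.sum()
    se = 2.0 * math.sqrt(n_obs * elpd_i.var(ddof=1)) if n_obs > 1 else 0.0
    return float(value), float(se), k_hat


# ---------------------------------------------------------------------------
# Cross-validation and the comparison table
# ---------------------------------------------------------------------------

def kfold_cv(
    records: Sequence[ParticipantRecord],
    variant: str,
    k: int = 10,
    seed: int = 1,
) -> pd.DataFrame:
    """Per-fold MAP fits on k seeded training partitions.

    Participants are partitioned into ``k`` folds; each fold's
    parameters are fit on the complementary training set.  Returns one
    row per fold with the fitted parameters (fold means are the
    cross-validated estimates, e.g. the averaged beta and offset behind
    a fitted belief curve).  ``k = n`` gives the leave-one-out
    partition.
    """
    n = len(records)
    names = VARIANTS[variant] if variant in VARIANTS else None
    if names is None:
        raise ValueError(f"unknown variant {variant!r}")
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, n={n}], got {k}")
    if n - math.ceil(n / k) < len(names):
        raise ValueError("training folds are smaller than the parameter count")
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(np.arange(n) % k)
    rows = []
    for fold in range(k):
        train = [r for r, a in zip(records, assignment) if a != fold]
        fit = map_estimate(train, variant, seed=seed)
        rows.append({"fold": fold, "n_train": len(train), **{p: fit[p] for p in names}})
    return pd.DataFrame(rows)


_TABLE_LABELS = {
    "aa-hom": ("A&A", "homogeneous"),
    "mas-hom": ("MAS", "homogeneous"),
    "mas-het": ("MAS", "heterogeneous"),
    "rsa-hom": ("RSA", "homogeneous"),
    "rsa-het": ("RSA", "heterogeneous"),
    "rsa-speaker": ("RSA", "speaker-dependent"),
}


def compare_models(
    records: Sequence[ParticipantRecord],
    config: MCMCConfig = MCMCConfig(),
    variants: Sequence[str] = tuple(_TABLE_LABELS),
    seed: int = 1,
) -> pd.DataFrame:
    """Fit every variant and tabulate max log-likelihood, WAIC and PSIS-LOO.

    All variants share the same participant table and sampler settings;
    lower WAIC / PSIS-LOO is better.  Columns: ``model, variant,
    likelihood, waic, waic_se, psis_loo, psis_loo_se``.  Deterministic
    given the seeds.
    """
    rows = []
    for variant in variants:
        logger.info("compare_models: fitting %s (n=%d)", variant, len(records))
        ml = map_estimate(records, variant, seed=seed, include_prior=False)
        post = run_mcmc(records, variant, config)
        w, w_se = waic(post.pointwise_loglik)
        loo, loo_se, _ = psis_loo(post.pointwise_loglik)
        model, label = _TABLE_LABELS[variant]
        row = ComparisonRow(
            model=model,
            variant=label,
            max_loglik=ml["log_lik"],
            waic=w,
            waic_se=w_se,
            psis_loo=loo,
            psis_loo_se=loo_se,
        )
        rows.append(
            {
                "model": row.model,
                "variant": row.variant,
                "likelihood": row.max_loglik,
                "waic": row.waic,
                "waic_se": row.waic_se,
                "psis_loo": row.psis_loo,
                "psis_loo_se": row.psis_loo_se,
            }
        )
    return pd.DataFrame(rows)
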