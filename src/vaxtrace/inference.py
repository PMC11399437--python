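"""Posterior sampling and diagnostics for the decision model.

The sampler is a multinomial no-U-turn sampler (NUTS) over the model's
unconstrained parameterization, with Stan-style warm-up: dual-averaging
step-size adaptation toward a target acceptance statistic and expanding
memoryless windows for a diagonal mass matrix.  Any gradient-based HMC
variant targeting ``ptmodel.unconstrained_log_density_and_grad`` would be an
acceptable backend; this one is validated against closed-form posteriors
and finite-difference gradient checks in the test suite.

Convergence is judged by the split-chain rank-normalized potential scale
reduction statistic (R-hat), with the conventional 1.01 threshold.
Posterior intervals are highest density intervals (HDI).  Predictive
performance is summarized as balanced accuracy (mean of the accept-class
and refuse-class accuracies), either in-sample or leave-one-out via
Pareto-smoothed importance sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp, ndtr, ndtri

from . import ptmodel
from .ptmodel import ModelDataset

__all__ = [
    "SamplerConfig",
    "PT_SAMPLER_DEFAULTS",
    "ASSOCIATION_SAMPLER_DEFAULTS",
    "PosteriorSamples",
    "nuts_sample",
    "fit_pt_model",
    "compute_rhat",
    "hdi",
    "posterior_predictive_accuracy",
    "recovery_report",
    "RHAT_THRESHOLD",
]

RHAT_THRESHOLD = 1.01

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC configuration.  ``n_sampling`` post-warm-up iterations are
    recorded every ``thin``-th iteration, so each chain contributes
    ``n_sampling // thin`` draws."""

    n_chains: int = 4
    n_warmup: int = 2000
    n_sampling: int = 3000
    thin: int = 2
    seed: int = 0
    max_treedepth: int = 10
    target_accept: float = 0.8

    def __post_init__(self) -> None:
        for name in ("n_chains", "n_warmup", "n_sampling", "thin"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def n_recorded(self) -> int:
        return self.n_chains * (self.n_sampling // self.thin)


#: decision-model default (4 x (2000 warm-up + 3000), thin 2 -> 6000 draws)
PT_SAMPLER_DEFAULTS = SamplerConfig()
#: regression default (4 x 4000 iterations, first half burn-in, every
#: second of the rest recorded -> 4000 draws)
ASSOCIATION_SAMPLER_DEFAULTS = SamplerConfig(n_warmup=2000, n_sampling=2000, thin=2)


# ---------------------------------------------------------------------------
# NUTS core
# ---------------------------------------------------------------------------

_DELTA_MAX = 1000.0  # divergence threshold on the joint log-density drop


class _Tree:
    __slots__ = (
        "theta_minus", "r_minus", "grad_minus",
        "theta_plus", "r_plus", "grad_plus",
        "theta_prop", "logp_prop", "grad_prop", "log_sum_w",
        "sum_metro", "n_leapfrog", "divergent", "turning",
    )


def _kinetic(r: np.ndarray, inv_mass: np.ndarray) -> float:
    return 0.5 * float(np.dot(r, inv_mass * r))


def _uturn(theta_plus, r_plus, theta_minus, r_minus, inv_mass) -> bool:
    d = theta_plus - theta_minus
    return (
        float(np.dot(d, inv_mass * r_plus)) <= 0.0
        or float(np.dot(d, inv_mass * r_minus)) <= 0.0
    )


def _leapfrog(logp_grad, theta, r, grad, eps, inv_mass):
    r1 = r + 0.5 * eps * grad
    theta1 = theta + eps * inv_mass * r1
    logp1, grad1 = logp_grad(theta1)
    r1 = r1 + 0.5 * eps * grad1
    return theta1, r1, logp1, grad1


def _build_tree(logp_grad, depth, theta, r, grad, direction, eps, inv_mass, h0, rng):
    """Recursively double a trajectory; returns a _Tree."""
    t = _Tree()
    if depth == 0:
        try:
            theta1, r1, logp1, grad1 = _leapfrog(
                logp_grad, theta, r, grad, direction * eps, inv_mass
            )
            h1 = logp1 - _kinetic(r1, inv_mass)
        except FloatingPointError:
            theta1, r1, logp1, grad1, h1 = theta, r, -np.inf, grad, -np.inf
        if not np.isfinite(h1):
            h1 = -np.inf
        t.theta_minus = t.theta_plus = t.theta_prop = theta1
        t.r_minus = t.r_plus = r1
        t.grad_minus = t.grad_plus = t.grad_prop = grad1
        t.logp_prop = logp1
        t.log_sum_w = h1 - h0
        t.divergent = (h0 - h1) > _DELTA_MAX
        t.turning = False
        t.sum_metro = min(1.0, math.exp(min(0.0, h1 - h0)))
        t.n_leapfrog = 1
        return t

    inner = _build_tree(
        logp_grad, depth - 1, theta, r, grad, direction, eps, inv_mass, h0, rng
    )
    if inner.divergent or inner.turning:
        return inner
    if direction == 1:
        outer = _build_tree(
            logp_grad, depth - 1, inner.theta_plus, inner.r_plus, inner.grad_plus,
            direction, eps, inv_mass, h0, rng,
        )
        inner.theta_plus = outer.theta_plus
        inner.r_plus = outer.r_plus
        inner.grad_plus = outer.grad_plus
    else:
        outer = _build_tree(
            logp_grad, depth - 1, inner.theta_minus, inner.r_minus, inner.grad_minus,
            direction, eps, inv_mass, h0, rng,
        )
        inner.theta_minus = outer.theta_minus
        inner.r_minus = outer.r_minus
        inner.grad_minus = outer.grad_minus
    inner.sum_metro += outer.sum_metro
    inner.n_leapfrog += outer.n_leapfrog
    inner.divergent = outer.divergent
    inner.turning = outer.turning or _uturn(
        inner.theta_plus, inner.r_plus, inner.theta_minus, inner.r_minus, inv_mass
    )
    total = np.logaddexp(inner.log_sum_w, outer.log_sum_w)
    if (
        not (inner.divergent or inner.turning)
        and math.log(rng.random()) < outer.log_sum_w - total
    ):
        inner.theta_prop = outer.theta_prop
        inner.logp_prop = outer.logp_prop
        inner.grad_prop = outer.grad_prop
    inner.log_sum_w = total
    return inner


def _nuts_transition(logp_grad, theta, logp, grad, eps, inv_mass, max_depth, rng):
    """One NUTS draw; returns (theta, logp, grad, accept_stat, divergent, depth)."""
    r = rng.standard_normal(theta.shape) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(r, inv_mass)
    theta_minus = theta_plus = theta
    r_minus = r_plus = r
    grad_minus = grad_plus = grad
    theta_prop, logp_prop, grad_prop = theta, logp, grad
    log_sum_w = 0.0
    sum_metro, n_leapfrog = 0.0, 0
    divergent = False
    depth = 0
    for depth in range(1, max_depth + 1):
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            tree = _build_tree(
                logp_grad, depth - 1, theta_plus, r_plus, grad_plus,
                1, eps, inv_mass, h0, rng,
            )
            theta_plus, r_plus, grad_plus = tree.theta_plus, tree.r_plus, tree.grad_plus
        else:
            tree = _build_tree(
                logp_grad, depth - 1, theta_minus, r_minus, grad_minus,
                -1, eps, inv_mass, h0, rng,
            )
            theta_minus, r_minus, grad_minus = (
                tree.theta_minus, tree.r_minus, tree.grad_minus,
            )
        sum_metro += tree.sum_metro
        n_leapfrog += tree.n_leapfrog
        if tree.divergent:
            divergent = True
            break
        if tree.turning:
            break
        # biased progressive sampling: favor the fresh subtree
        if rng.random() < min(1.0, math.exp(tree.log_sum_w - log_sum_w)):
            theta_prop, logp_prop, grad_prop = (
                tree.theta_prop, tree.logp_prop, tree.grad_prop,
            )
        log_sum_w = float(np.logaddexp(log_sum_w, tree.log_sum_w))
        if _uturn(theta_plus, r_plus, theta_minus, r_minus, inv_mass):
            break
    accept_stat = sum_metro / max(n_leapfrog, 1)
    return theta_prop, logp_prop, grad_prop, accept_stat, divergent, depth


def _find_initial_step(logp_grad, theta, logp, grad, inv_mass, rng) -> float:
    """Coarse initial step size: double/halve until the one-step acceptance
    probability crosses 0.5."""
    eps = 1.0
    r = rng.standard_normal(theta.shape) / np.sqrt(inv_mass)
    h0 = logp - _kinetic(r, inv_mass)

    def joint(e):
        try:
            _, r1, logp1, _ = _leapfrog(logp_grad, theta, r, grad, e, inv_mass)
            h = logp1 - _kinetic(r1, inv_mass)
            return h if np.isfinite(h) else -np.inf
        except FloatingPointError:
            return -np.inf

    direction = 1 if (joint(eps) - h0) > math.log(0.5) else -1
    for _ in range(50):
        if direction == 1 and (joint(eps * 2) - h0) > math.log(0.5):
            eps *= 2
        elif direction == -1 and (joint(eps) - h0) < math.log(0.5):
            eps /= 2
        else:
            break
    return eps


@dataclass
class _Welford:
    n: int = 0
    mean: np.ndarray | None = None
    m2: np.ndarray | None = None

    def add(self, x: np.ndarray) -> None:
        if self.mean is None:
            self.mean = np.zeros_like(x)
            self.m2 = np.zeros_like(x)
        self.n += 1
        delta = x - self.mean
        self.mean += delta / self.n
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        return self.m2 / max(self.n - 1, 1)


def _adaptation_schedule(n_warmup: int, init_buffer=75, term_buffer=50, base=25):
    """Iteration indices (ends, exclusive) of the slow mass-adaptation
    windows; empty when the warm-up phase is too short for windowing."""
    if n_warmup < init_buffer + term_buffer + base:
        return []
    ends = []
    start = init_buffer
    size = base
    while True:
        end = start + size
        if end + term_buffer >= n_warmup or start + 2 * size + term_buffer > n_warmup:
            ends.append(n_warmup - term_buffer)
            break
        ends.append(end)
        start = end
        size *= 2
    return ends


def _run_chain(
    logp_grad: LogpGrad,
    theta0: np.ndarray,
    config: SamplerConfig,
    rng: np.random.Generator,
):
    theta = np.asarray(theta0, dtype=float).copy()
    logp, grad = logp_grad(theta)
    inv_mass = np.ones_like(theta)

    eps = _find_initial_step(logp_grad, theta, logp, grad, inv_mass, rng)
    mu = math.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    windows = _adaptation_schedule(config.n_warmup)
    welford = _Welford()
    window_ix = 0

    n_kept = config.n_sampling // config.thin
    dim = theta.size
    draws = np.empty((n_kept, dim))
    divergences = 0
    depths = []

    for it in range(config.n_warmup + config.n_sampling):
        warming = it < config.n_warmup
        theta, logp, grad, accept, div, depth = _nuts_transition(
            logp_grad, theta, logp, grad, eps,
            inv_mass, config.max_treedepth, rng,
        )
        if warming:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (config.target_accept - accept)
            log_eps = mu - math.sqrt(adapt_count) / gamma * h_bar
            weight = adapt_count ** -kappa
            log_eps_bar = weight * log_eps + (1 - weight) * log_eps_bar
            eps = math.exp(log_eps)
            if windows and window_ix < len(windows):
                if it >= 75:
                    welford.add(theta)
                if it + 1 == windows[window_ix]:
                    n = welford.n
                    var = welford.variance()
                    inv_mass = var * (n / (n + 5.0)) + 1e-3 * (5.0 / (n + 5.0))
                    welford = _Welford()
                    window_ix += 1
                    eps = _find_initial_step(logp_grad, theta, logp, grad, inv_mass, rng)
                    mu = math.log(10.0 * eps)
                    log_eps_bar, h_bar, adapt_count = 0.0, 0.0, 0
            if it + 1 == config.n_warmup:
                eps = math.exp(log_eps_bar)
        else:
            post_it = it - config.n_warmup
            if div:
                divergences += 1
            depths.append(depth)
            if (post_it + 1) % config.thin == 0:
                draws[(post_it + 1) // config.thin - 1] = theta
    stats = {
        "step_size": eps,
        "divergences": divergences,
        "mean_treedepth": float(np.mean(depths)) if depths else 0.0,
    }
    return draws, stats


def nuts_sample(
    logp_grad: LogpGrad,
    theta0s: Sequence[np.ndarray],
    config: SamplerConfig,
) -> tuple[np.ndarray, list[dict]]:
    """Run ``config.n_chains`` NUTS chains (sequentially) from the given
    starting points.  Returns draws [n_chains, n_kept, dim] and per-chain
    statistics."""
    if len(theta0s) != config.n_chains:
        raise ValueError("need one starting point per chain")
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_draws, all_stats = [], []
    for theta0, ss in zip(theta0s, seeds):
        draws, stats = _run_chain(logp_grad, theta0, config, np.random.default_rng(ss))
        all_draws.append(draws)
        all_stats.append(stats)
    return np.stack(all_draws), all_stats


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def _split_chains(draws: np.ndarray) -> np.ndarray:
    """(n_chains, n_draws) -> (2*n_chains, n_draws//2)."""
    n_chains, n_draws = draws.shape
    half = n_draws // 2
    return np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata

    ranks = rankdata(x.ravel()).reshape(x.shape)
    return ndtri((ranks - 0.375) / (x.size + 0.25))


def _psrf(x: np.ndarray) -> float:
    """Classic potential scale reduction on (m, n) chains."""
    m, n = x.shape
    chain_means = x.mean(axis=1)
    b = n * chain_means.var(ddof=1)
    w = x.var(axis=1, ddof=1).mean()
    var_plus = (n - 1) / n * w + b / n
    if w == 0:
        return 1.0
    return math.sqrt(var_plus / w)


def compute_rhat(draws: np.ndarray) -> float:
    """Split-chain rank-normalized R-hat (max of the bulk statistic and the
    folded statistic on absolute deviations from the median).

    ``draws`` has shape (n_chains, n_draws) with at least 2 chains and 4
    draws per chain.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("R-hat requires at least two chains of draws")
    if draws.shape[1] < 4:
        raise ValueError("R-hat requires at least 4 draws per chain")
    split = _split_chains(draws)
    bulk = _psrf(_rank_normalize(split))
    folded = _psrf(_rank_normalize(np.abs(split - np.median(split))))
    return max(bulk, folded)


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``mass`` of the draws."""
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 50:
        raise ValueError("HDI needs at least 50 draws")
    m = int(math.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


# ---------------------------------------------------------------------------
# fitted-model container
# ---------------------------------------------------------------------------

_GROUP_NAMES = [
    "beta",
    "beta_j[0]", "beta_j[1]", "beta_j[2]", "beta_j[3]",
    "lambda_probit", "gamma_probit", "phi_probit", "alpha_raw",
    "log_sigma_beta", "logit_sigma_lambda", "logit_sigma_gamma",
    "cpc[0]", "cpc[1]", "cpc[2]",
]


@dataclass
class PosteriorSamples:
    """Chain-indexed posterior draws on the unconstrained scale plus
    diagnostics.  ``group_posterior`` exposes the natural-scale group
    parameters per draw."""

    draws: np.ndarray  # [n_chains, n_kept, dim]
    names: list[str]
    n_participants: int
    config: SamplerConfig
    chain_stats: list[dict] = field(default_factory=list)
    rhat: dict[str, float] = field(default_factory=dict)

    @property
    def n_recorded(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        """Draws of a named unconstrained coordinate, shape (chains, kept)."""
        return self.draws[:, :, self.names.index(name)]

    def group_posterior(self) -> dict[str, np.ndarray]:
        """Natural-scale group-level posteriors, each flattened over chains."""
        g = self.draws[:, :, : len(_GROUP_NAMES)].reshape(-1, len(_GROUP_NAMES))
        c = np.tanh(g[:, 12:15])
        r23 = c[:, 0] * c[:, 1] + c[:, 2] * np.sqrt(
            (1 - c[:, 0] ** 2) * (1 - c[:, 1] ** 2)
        )
        out = {
            "beta": g[:, 0],
            "beta_j[0]": g[:, 1],
            "beta_j[1]": g[:, 2],
            "beta_j[2]": g[:, 3],
            "beta_j[3]": g[:, 4],
            "lambda_probit": g[:, 5],
            "gamma_probit": g[:, 6],
            "phi_probit": g[:, 7],
            "alpha_raw": g[:, 8],
            "lambda": ndtr(g[:, 5]),
            "gamma": ndtr(g[:, 6]),
            "phi": ndtr(g[:, 7]),
            "alpha": np.exp(g[:, 8]),
            "Lambda": ndtr(g[:, 5]) / (1.0 - ndtr(g[:, 5])),
            "sigma_beta": np.exp(g[:, 9]),
            "sigma_lambda": expit(g[:, 10]),
            "sigma_gamma": expit(g[:, 11]),
            "r12": c[:, 0],
            "r13": c[:, 1],
            "r23": r23,
        }
        return out

    def max_rhat(self) -> float:
        return max(self.rhat.values())


def _initial_points(dataset: ModelDataset, config: SamplerConfig):
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11CE]))
    dim = ptmodel.n_unconstrained(dataset.n_participants)
    points = []
    for _ in range(config.n_chains):
        theta = 0.1 * rng.standard_normal(dim)
        theta[10] = -0.5 + 0.1 * rng.standard_normal()  # logit sigma_lambda
        theta[11] = -0.5 + 0.1 * rng.standard_normal()  # logit sigma_gamma
        points.append(theta)
    return points


def fit_pt_model(
    dataset: ModelDataset, config: SamplerConfig = PT_SAMPLER_DEFAULTS
) -> PosteriorSamples:
    """Sample the hierarchical prospect-theory posterior for one attitude
    group.  Per-coordinate split rank-normalized R-hat is recorded for every
    parameter (group-level coordinates by name, displacement coordinates
    under ``z[...]``)."""
    logp_grad = lambda th: ptmodel.unconstrained_log_density_and_grad(th, dataset)
    draws, stats = nuts_sample(logp_grad, _initial_points(dataset, config), config)
    names = list(_GROUP_NAMES) + [
        f"z[{i},{k}]" for i in range(dataset.n_participants) for k in range(3)
    ]
    rhat = {name: compute_rhat(draws[:, :, j]) for j, name in enumerate(names)}
    return PosteriorSamples(
        draws=draws,
        names=names,
        n_participants=dataset.n_participants,
        config=config,
        chain_stats=stats,
        rhat=rhat,
    )


# ---------------------------------------------------------------------------
# posterior predictive evaluation
# ---------------------------------------------------------------------------

def _acceptance_prob_per_draw(samples: PosteriorSamples, dataset: ModelDataset):
    """Yields (draw_index, P(accept) [N, 8]) over all recorded draws."""
    flat = samples.draws.reshape(-1, samples.draws.shape[-1])
    for s in range(flat.shape[0]):
        group, zetas = ptmodel.unpack_parameters(flat[s], dataset.n_participants)
        beta_i = group.beta + zetas[:, 0]
        lam_i = ndtr(group.lambda_probit + zetas[:, 1])
        gam_i = ndtr(group.gamma_probit + zetas[:, 2])
        eta, _, _ = ptmodel._linear_predictor(
            dataset, beta_i, lam_i, gam_i, group.alpha, group.phi, group.beta_j
        )
        yield s, expit(eta)


def _balanced_accuracy(y: np.ndarray, p_hat: np.ndarray) -> float:
    pred = p_hat > 0.5
    accs = []
    for cls, want in ((1.0, True), (0.0, False)):
        mask = y == cls
        if mask.any():
            accs.append(float((pred[mask] == want).mean()))
    return float(np.mean(accs))


def posterior_predictive_accuracy(
    samples: PosteriorSamples, dataset: ModelDataset, method: str = "in_sample"
) -> float:
    """Balanced predictive accuracy of the fitted model.

    ``in_sample``: trials classified at 0.5 from the posterior-mean
    acceptance probability.  ``loo``: the per-trial probability is reweighted
    by Pareto-smoothed importance sampling so each trial is predicted as if
    left out of the fit.
    """
    if samples.n_participants != dataset.n_participants:
        raise ValueError("samples were fitted to a different dataset")
    if method not in ("in_sample", "loo"):
        raise ValueError(f"unknown method {method!r}")
    n_draws = samples.draws.shape[0] * samples.draws.shape[1]
    probs = np.empty((n_draws, *dataset.y.shape))
    for s, p in _acceptance_prob_per_draw(samples, dataset):
        probs[s] = p
    y = dataset.y
    if method == "in_sample":
        return _balanced_accuracy(y, probs.mean(axis=0))
    import arviz as az

    eps = 1e-12
    log_lik = y[None] * np.log(probs + eps) + (1 - y[None]) * np.log(1 - probs + eps)
    flat_ll = log_lik.reshape(n_draws, -1)
    lw, _ = az.psislw(-flat_ll.T)  # (n_obs, n_draws) smoothed log-weights
    lw = np.asarray(lw)
    w = np.exp(lw - logsumexp(lw, axis=1, keepdims=True))
    p_loo = (w * probs.reshape(n_draws, -1).T).sum(axis=1).reshape(y.shape)
    return _balanced_accuracy(y, p_loo)


def recovery_report(truth: dict[str, float], samples: PosteriorSamples) -> pd.DataFrame:
    """Coverage/bias table of the group-level posterior against stored
    ground truth.  ``truth`` maps parameter names (as in
    ``group_posterior``) to their generating values."""
    post = samples.group_posterior()
    rows = []
    for name, true_val in truth.items():
        if name not in post:
            raise KeyError(f"no posterior for truth entry {name!r}")
        d = post[name]
        lo, hi = hdi(d, 0.95)
        sd = float(d.std())
        med = float(np.median(d))
        rows.append(
            {
                "parameter": name,
                "truth": float(true_val),
                "median": med,
                "hdi_low": lo,
                "hdi_high": hi,
                "covered": bool(lo <= true_val <= hi),
                "bias_sd": (med - true_val) / sd if sd > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)
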