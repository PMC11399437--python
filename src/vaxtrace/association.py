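"""Supporting Bayesian hierarchical regressions.

Binary outcomes (vaccine acceptance, a neglect flag) are modelled with
hierarchical logistic regressions; ordinal outcomes (ignorance level,
affect ratings) with hierarchical cumulative ordered-logit regressions.
Both share the structure used throughout the analysis: categorical
predictors with sum-to-zero contrasts, a random intercept per participant,
and weakly informative zero-centered Student-t(3, 0, 2.5) priors on the
regression coefficients (half-t(3, 0, 2.5) on the random-intercept SD).

Predicted outcome values per factor level set all other predictors to
zero — with sum-to-zero coding this is the grand mean plus that level's
effect, pushed through the inverse link.  Pairwise comparisons subtract
linear-scale predicted values draw by draw; a difference whose 95% HDI
excludes zero is flagged as evidence.

The regressions are fitted with the package's own NUTS sampler so the whole
pipeline is testable against planted ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .inference import (
    ASSOCIATION_SAMPLER_DEFAULTS,
    SamplerConfig,
    compute_rhat,
    hdi,
    nuts_sample,
)

__all__ = [
    "RegressionSpec",
    "RegressionPosterior",
    "sum_to_zero_columns",
    "build_design",
    "fit_hierarchical_logistic",
    "fit_ordered_logit",
    "predicted_levels",
    "pairwise_difference",
    "odds_ratios",
    "LOG_OR_RELEVANCE",
]

#: |log(OR)| at or above this value is conventionally practically relevant
LOG_OR_RELEVANCE = 0.2

_T_DF = 3.0
_T_SCALE = 2.5


@dataclass(frozen=True)
class RegressionSpec:
    """Outcome, family, categorical predictors and the random-intercept
    grouping column."""

    outcome: str
    family: str  # "bernoulli" | "ordered"
    predictors: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    random_intercept: str = "participant_id"
    prior_df: float = _T_DF
    prior_scale: float = _T_SCALE

    def __post_init__(self) -> None:
        if self.family not in ("bernoulli", "ordered"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.predictors:
            raise ValueError("at least one predictor is required")


def sum_to_zero_columns(values: pd.Series) -> tuple[np.ndarray, list]:
    """Sum-to-zero (deviation) coding of a categorical column: K levels map
    to K-1 columns; the last level is coded -1 in every column."""
    levels = list(pd.unique(values))
    k = len(levels)
    if k < 2:
        raise ValueError(f"factor {values.name!r} needs at least 2 levels")
    ix = values.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    D = np.zeros((len(values), k - 1))
    for j in range(k - 1):
        D[ix == j, j] = 1.0
    D[ix == k - 1, :] = -1.0
    return D, levels


@dataclass
class _Design:
    matrix: np.ndarray  # [n_obs, P]
    column_names: list[str]
    factor_levels: dict[str, list]
    factor_columns: dict[str, list[int]]
    group_index: np.ndarray  # random-intercept group per observation
    n_groups: int


def build_design(data: pd.DataFrame, spec: RegressionSpec) -> _Design:
    blocks, names = [], []
    factor_levels: dict[str, list] = {}
    factor_columns: dict[str, list[int]] = {}
    col = 0
    for factor in spec.predictors:
        D, levels = sum_to_zero_columns(data[factor])
        blocks.append(D)
        factor_levels[factor] = levels
        factor_columns[factor] = list(range(col, col + D.shape[1]))
        names += [f"{factor}[{lv}]" for lv in levels[:-1]]
        col += D.shape[1]
    for fa, fb in spec.interactions:
        Da = blocks[spec.predictors.index(fa)]
        Db = blocks[spec.predictors.index(fb)]
        inter = np.einsum("ni,nj->nij", Da, Db).reshape(len(data), -1)
        blocks.append(inter)
        key = f"{fa}:{fb}"
        factor_columns[key] = list(range(col, col + inter.shape[1]))
        names += [
            f"{key}[{la}x{lb}]"
            for la in factor_levels[fa][:-1]
            for lb in factor_levels[fb][:-1]
        ]
        col += inter.shape[1]
    groups = data[spec.random_intercept].astype(str)
    group_levels = list(pd.unique(groups))
    gix = groups.map({g: i for i, g in enumerate(group_levels)}).to_numpy()
    return _Design(
        matrix=np.concatenate(blocks, axis=1),
        column_names=names,
        factor_levels=factor_levels,
        factor_columns=factor_columns,
        group_index=gix,
        n_groups=len(group_levels),
    )


@dataclass
class RegressionPosterior:
    """Posterior draws for one regression: named coordinates on the scale
    they were sampled on (coefficients and cutpoints untransformed)."""

    draws: np.ndarray  # [chains, kept, dim]
    names: list[str]
    spec: RegressionSpec
    design: _Design
    config: SamplerConfig
    rhat: dict[str, float] = field(default_factory=dict)
    n_cutpoints: int = 0

    def parameter(self, name: str) -> np.ndarray:
        """Flattened draws of one named coordinate."""
        return self.draws[:, :, self.names.index(name)].ravel()

    def coefficient_draws(self) -> dict[str, np.ndarray]:
        return {
            name: self.parameter(name) for name in self.design.column_names
        }

    def max_rhat(self) -> float:
        return max(self.rhat.values())


# ---------------------------------------------------------------------------
# log-densities with analytic gradients
# ---------------------------------------------------------------------------

def _t_logpdf_grad(x: np.ndarray, df: float, scale: float):
    """Unnormalized Student-t log-density and gradient."""
    denom = df * scale**2 + x**2
    lp = float(np.sum(-0.5 * (df + 1.0) * np.log1p(x**2 / (df * scale**2))))
    grad = -(df + 1.0) * x / denom
    return lp, grad


def _logistic_logp_grad(theta, y, D, gix, n_groups, spec):
    P = D.shape[1]
    intercept = theta[0]
    coefs = theta[1 : 1 + P]
    log_sd = theta[1 + P]
    u_raw = theta[2 + P :]
    sd = math.exp(log_sd)
    u = sd * u_raw
    eta = intercept + D @ coefs + u[gix]
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    resid = y - expit(eta)

    grad = np.zeros_like(theta)
    grad[0] = resid.sum()
    grad[1 : 1 + P] = D.T @ resid
    d_u = np.bincount(gix, weights=resid, minlength=n_groups)
    grad[2 + P :] = d_u * sd - u_raw
    grad[1 + P] = float(np.sum(d_u * u)) + 1.0
    lp = ll - 0.5 * float(np.sum(u_raw**2))
    # half-t prior on sd (+ log-Jacobian of the log transform)
    t_lp, t_grad = _t_logpdf_grad(np.array([sd]), spec.prior_df, spec.prior_scale)
    lp += t_lp + log_sd
    grad[1 + P] += float(t_grad[0]) * sd
    # t priors on intercept and coefficients
    block = np.concatenate([[intercept], coefs])
    t_lp, t_grad = _t_logpdf_grad(block, spec.prior_df, spec.prior_scale)
    lp += t_lp
    grad[0] += t_grad[0]
    grad[1 : 1 + P] += t_grad[1:]
    if not np.isfinite(lp):
        raise FloatingPointError("non-finite regression log-density")
    return lp, grad


def _ordered_logp_grad(theta, y, K, D, gix, n_groups, spec):
    """Cumulative logit with ordered cutpoints (c1 free, positive
    increments); y is 0-based in 0..K-1."""
    P = D.shape[1]
    c_raw = theta[:K - 1]
    coefs = theta[K - 1 : K - 1 + P]
    log_sd = theta[K - 1 + P]
    u_raw = theta[K + P :]
    sd = math.exp(log_sd)
    u = sd * u_raw
    incr = np.exp(c_raw[1:])
    cuts = np.concatenate([[c_raw[0]], c_raw[0] + np.cumsum(incr)])
    eta = D @ coefs + u[gix]

    z = cuts[None, :] - eta[:, None]  # [n, K-1]
    F = expit(z)
    f = F * (1.0 - F)
    F_hi = np.concatenate([F, np.ones((len(eta), 1))], axis=1)
    F_lo = np.concatenate([np.zeros((len(eta), 1)), F], axis=1)
    f_hi = np.concatenate([f, np.zeros((len(eta), 1))], axis=1)
    f_lo = np.concatenate([np.zeros((len(eta), 1)), f], axis=1)
    rows = np.arange(len(eta))
    pk = F_hi[rows, y] - F_lo[rows, y]
    pk = np.maximum(pk, 1e-300)
    ll = float(np.sum(np.log(pk)))

    d_eta = (f_lo[rows, y] - f_hi[rows, y]) / pk
    d_cuts = np.zeros(K - 1)
    # d ll / d c_k: + f_k/pk where y == k, - f_k/pk where y == k+1
    fk_over_p = f / pk[:, None]
    for k in range(K - 1):
        d_cuts[k] = float(np.sum(fk_over_p[y == k, k])) - float(
            np.sum(fk_over_p[y == k + 1, k])
        )

    grad = np.zeros_like(theta)
    grad[K - 1 : K - 1 + P] = D.T @ d_eta
    d_u = np.bincount(gix, weights=d_eta, minlength=n_groups)
    grad[K + P :] = d_u * sd - u_raw
    grad[K - 1 + P] = float(np.sum(d_u * u)) + 1.0
    lp = ll - 0.5 * float(np.sum(u_raw**2))
    # priors: t on each cutpoint and coefficient, half-t on sd
    t_lp_c, t_grad_c = _t_logpdf_grad(cuts, spec.prior_df, spec.prior_scale)
    t_lp_b, t_grad_b = _t_logpdf_grad(coefs, spec.prior_df, spec.prior_scale)
    lp += t_lp_c + t_lp_b
    grad[K - 1 : K - 1 + P] += t_grad_b
    d_cuts += t_grad_c
    # chain cutpoints back to (c1, log-increments) + Jacobian sum(log incr)
    grad[0] = float(np.sum(d_cuts))
    csum = np.cumsum(d_cuts[::-1])[::-1]  # sum_{k >= j} d_cuts[k]
    grad[1 : K - 1] = incr * csum[1:] + 1.0  # +1 from the log-Jacobian
    lp += float(np.sum(c_raw[1:]))
    t_lp_s, t_grad_s = _t_logpdf_grad(np.array([sd]), spec.prior_df, spec.prior_scale)
    lp += t_lp_s + log_sd
    grad[K - 1 + P] += float(t_grad_s[0]) * sd
    if not np.isfinite(lp):
        raise FloatingPointError("non-finite regression log-density")
    return lp, grad


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _fit(logp_grad, dim, names, spec, design, config, n_cutpoints=0):
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    theta0s = []
    for _ in range(config.n_chains):
        t0 = 0.1 * rng.standard_normal(dim)
        if n_cutpoints > 1:
            t0[1:n_cutpoints] = math.log(0.5) + 0.1 * rng.standard_normal(
                n_cutpoints - 1
            )
        theta0s.append(t0)
    draws, _stats = nuts_sample(logp_grad, theta0s, config)
    rhat = {name: compute_rhat(draws[:, :, j]) for j, name in enumerate(names)}
    return RegressionPosterior(
        draws=draws,
        names=names,
        spec=spec,
        design=design,
        config=config,
        rhat=rhat,
        n_cutpoints=n_cutpoints,
    )


def fit_hierarchical_logistic(
    data: pd.DataFrame,
    spec: RegressionSpec,
    config: SamplerConfig = ASSOCIATION_SAMPLER_DEFAULTS,
) -> RegressionPosterior:
    """Hierarchical logistic regression with a participant random intercept."""
    if spec.family != "bernoulli":
        raise ValueError("spec.family must be 'bernoulli' for a logistic fit")
    y_col = data[spec.outcome]
    uniq = set(pd.unique(y_col.astype(int))) if y_col.dtype != bool else {0, 1}
    if y_col.dtype == bool:
        y = y_col.to_numpy().astype(float)
    elif uniq <= {0, 1}:
        y = y_col.astype(int).to_numpy().astype(float)
    else:
        raise ValueError(f"outcome {spec.outcome!r} is not binary (values {uniq})")
    design = build_design(data, spec)
    P = design.matrix.shape[1]
    dim = 2 + P + design.n_groups
    names = (
        ["intercept"]
        + design.column_names
        + ["log_sd_participant"]
        + [f"u[{i}]" for i in range(design.n_groups)]
    )
    logp_grad = lambda th: _logistic_logp_grad(
        th, y, design.matrix, design.group_index, design.n_groups, spec
    )
    return _fit(logp_grad, dim, names, spec, design, config)


def fit_ordered_logit(
    data: pd.DataFrame,
    spec: RegressionSpec,
    config: SamplerConfig = ASSOCIATION_SAMPLER_DEFAULTS,
) -> RegressionPosterior:
    """Hierarchical cumulative ordered-logit regression (>= 3 ordered
    levels) with a participant random intercept."""
    if spec.family != "ordered":
        raise ValueError("spec.family must be 'ordered' for an ordinal fit")
    y_col = data[spec.outcome]
    if isinstance(y_col.dtype, pd.CategoricalDtype):
        if not y_col.cat.ordered:
            raise ValueError(f"outcome {spec.outcome!r} must be an ordered categorical")
        y = y_col.cat.codes.to_numpy()
        K = len(y_col.cat.categories)
    else:
        levels = np.sort(pd.unique(y_col))
        K = len(levels)
        y = y_col.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    if K < 3:
        raise ValueError(
            f"ordinal outcome needs at least 3 levels, got {K}; use the logistic model"
        )
    design = build_design(data, spec)
    P = design.matrix.shape[1]
    dim = K + P + design.n_groups
    names = (
        [f"cut_raw[{k}]" for k in range(K - 1)]
        + design.column_names
        + ["log_sd_participant"]
        + [f"u[{i}]" for i in range(design.n_groups)]
    )
    logp_grad = lambda th: _ordered_logp_grad(
        th, y, K, design.matrix, design.group_index, design.n_groups, spec
    )
    return _fit(logp_grad, dim, names, spec, design, config, n_cutpoints=K - 1)


# ---------------------------------------------------------------------------
# predicted values and comparisons
# ---------------------------------------------------------------------------

def _cutpoint_draws(fit: RegressionPosterior) -> np.ndarray:
    K1 = fit.n_cutpoints
    raw = np.stack([fit.parameter(f"cut_raw[{k}]") for k in range(K1)], axis=1)
    cuts = raw.copy()
    cuts[:, 1:] = np.exp(raw[:, 1:])
    return np.concatenate(
        [raw[:, :1], raw[:, :1] + np.cumsum(cuts[:, 1:], axis=1)], axis=1
    )


def _linear_level_draws(fit: RegressionPosterior, factor: str, level) -> np.ndarray:
    """Draws of the linear-scale predicted value for one factor level with
    all other predictors at zero."""
    design = fit.design
    if factor not in design.factor_levels:
        raise KeyError(f"unknown factor {factor!r}")
    levels = design.factor_levels[factor]
    if level not in levels:
        raise KeyError(f"unknown level {level!r} of factor {factor!r}")
    k = levels.index(level)
    cols = design.factor_columns[factor]
    contrast = np.zeros(len(cols))
    if k < len(cols):
        contrast[k] = 1.0
    else:
        contrast[:] = -1.0
    coef_draws = np.stack(
        [fit.parameter(design.column_names[c]) for c in cols], axis=1
    )
    value = coef_draws @ contrast
    if fit.spec.family == "bernoulli":
        value = value + fit.parameter("intercept")
    return value


def predicted_levels(
    fit: RegressionPosterior, factor: str, mass: float = 0.95
) -> pd.DataFrame:
    """Per-level posterior predicted outcome values (median + HDI on the
    response scale): acceptance probability for logistic models, expected
    ordinal level for ordered models."""
    if factor not in fit.design.factor_levels:
        raise KeyError(f"unknown factor {factor!r}")
    rows = []
    for level in fit.design.factor_levels[factor]:
        lin = _linear_level_draws(fit, factor, level)
        if fit.spec.family == "bernoulli":
            resp = expit(lin)
        else:
            cuts = _cutpoint_draws(fit)
            F = expit(cuts - lin[:, None])
            probs = np.diff(
                np.concatenate(
                    [np.zeros((len(lin), 1)), F, np.ones((len(lin), 1))], axis=1
                ),
                axis=1,
            )
            resp = probs @ np.arange(1, probs.shape[1] + 1)
        lo, hi = hdi(resp, mass)
        rows.append(
            {
                "factor": factor,
                "level": level,
                "median": float(np.median(resp)),
                "hdi_low": lo,
                "hdi_high": hi,
            }
        )
    return pd.DataFrame(rows)


def pairwise_difference(
    fit: RegressionPosterior, factor: str, level_a, level_b, mass: float = 0.95
) -> dict:
    """Posterior of the linear-scale difference between two factor levels;
    ``excludes_zero`` flags evidence for a difference at the given mass."""
    if level_a == level_b:
        return {
            "difference_median": 0.0,
            "hdi_low": 0.0,
            "hdi_high": 0.0,
            "excludes_zero": False,
        }
    diff = _linear_level_draws(fit, factor, level_a) - _linear_level_draws(
        fit, factor, level_b
    )
    lo, hi = hdi(diff, mass)
    return {
        "difference_median": float(np.median(diff)),
        "hdi_low": lo,
        "hdi_high": hi,
        "excludes_zero": bool(lo > 0.0 or hi < 0.0),
    }


def odds_ratios(fit: RegressionPosterior, mass: float = 0.95) -> pd.DataFrame:
    """Coefficient odds ratios with HDIs; ``relevant`` marks
    |log(OR)| >= 0.2 at the posterior median."""
    if fit.spec.family != "bernoulli":
        raise ValueError("odds ratios apply to logistic models")
    rows = []
    for name in fit.design.column_names:
        d = fit.parameter(name)
        lo, hi = hdi(np.exp(d), mass)
        med = float(np.median(d))
        rows.append(
            {
                "coefficient": name,
                "odds_ratio": float(np.exp(med)),
                "hdi_low": lo,
                "hdi_high": hi,
                "relevant": bool(abs(med) >= LOG_OR_RELEVANCE),
            }
        )
    return pd.DataFrame(rows)
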