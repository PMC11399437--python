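"""Hierarchical prospect-theory model of accept/refuse vaccination decisions.

The probability that individual ``i`` accepts vaccine ``v`` is

    P(accept) = logistic(beta_i + X_v . beta_j + phi * V_iv)

where ``beta_i`` is an individual decision bias, ``X_v`` a row of sum-to-zero
contrasts coding country of origin and technology, and ``V_iv`` the
prospect-theory valuation of the inspected vaccine evidence:

    V_iv = sum_se v(a_se) w(p_se) + sum_b v(a_b) w(p_b)

with the three-case value function over signed affect ratings ``a``

    v(a) = -lambda_i |a|^alpha   (side effect)
         = (1-lambda_i) a^alpha  (benefit)
         = 0                     (outcome not inspected)

and the two-case decision-weight function over probabilities

    w(p) = exp(-(-ln p)^gamma_i)  (probability inspected; one-parameter
                                   Prelec weighting)
         = 0.5                    (outcome inspected, probability not)

Individual parameters are hierarchical: beta_i = beta + zeta_b,
lambda_i = Phi(lambda^probit + zeta_l), gamma_i = Phi(gamma^probit + zeta_g),
with (zeta_b, zeta_l, zeta_g) ~ MVN(0, Sigma), Sigma = diag(sigma) R
diag(sigma).  Phi is the standard normal CDF, so lambda_i, gamma_i in (0,1);
loss aversion is reported as Lambda = lambda/(1-lambda) (Lambda > 1 means
losses loom larger).  alpha = exp(alpha_raw) > 0 allows a nonlinear use of
the rating scale; phi = Phi(phi^probit) in (0,1) scales the valuation.

Priors: standard normal on beta, beta_j, lambda^probit, gamma^probit,
phi^probit; N(0, 0.5) on alpha_raw; gamma(2, 1) on sigma_beta; N(0.5, 0.13)
truncated to (0, 1) on sigma_lambda and sigma_gamma; LKJ(eta=5) on R.

``model_log_density`` evaluates the joint density in the centered
parameterization the model is specified in.  The sampler targets an
unconstrained reparameterization (non-centered displacements, log /
logit-transformed scales, partial-correlation coding of R) whose density
equals the centered one after the change of variables; ``unconstrained_
log_density_and_grad`` returns it together with its analytic gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import expit, ndtr

from .evidence import MISSING, EvidenceTable

__all__ = [
    "W_NEGLECT",
    "P_CLAMP",
    "LKJ_ETA",
    "GroupParameters",
    "IndividualParameters",
    "TrialOutcome",
    "TrialInput",
    "ModelDataset",
    "value_function",
    "weight_probability",
    "subjective_valuation",
    "acceptance_probability",
    "transform_individual_parameters",
    "loss_aversion_Lambda",
    "contrast_matrix",
    "build_model_dataset",
    "model_log_density",
    "n_unconstrained",
    "pack_parameters",
    "unpack_parameters",
    "unconstrained_log_density_and_grad",
]

#: decision weight assigned to a neglected probability
W_NEGLECT = 0.5
#: probabilities are clamped to this open interval before Prelec weighting
P_CLAMP = (1e-8, 1.0 - 1e-8)
#: LKJ shape for the displacement correlation matrix
LKJ_ETA = 5.0

_SLOTS = ("se1", "se2", "se3", "b1", "b2", "b3")
_IS_SE = np.array([True, True, True, False, False, False])

_SD_TRUNC_MU = 0.5
_SD_TRUNC_SD = 0.13


# ---------------------------------------------------------------------------
# parameter containers and elementary model functions
# ---------------------------------------------------------------------------

@dataclass
class GroupParameters:
    """Group-level parameters of one attitude group's model."""

    beta: float
    beta_j: np.ndarray  # 4 sum-to-zero coefficients (2 country + 2 technology)
    lambda_probit: float
    gamma_probit: float
    alpha_raw: float
    phi_probit: float
    sigma: np.ndarray  # SDs of (zeta_beta, zeta_lambda, zeta_gamma)
    correlation: np.ndarray  # 3x3 correlation matrix of the displacements

    def __post_init__(self) -> None:
        self.beta_j = np.asarray(self.beta_j, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        if self.beta_j.shape != (4,):
            raise ValueError("beta_j must have exactly 4 entries")
        if self.sigma.shape != (3,) or np.any(self.sigma <= 0):
            raise ValueError("sigma must be 3 positive SDs")
        R = self.correlation
        if R.shape != (3, 3) or not np.allclose(R, R.T) or not np.allclose(
            np.diag(R), 1.0
        ):
            raise ValueError("correlation must be symmetric with unit diagonal")
        if np.any(np.linalg.eigvalsh(R) <= 0):
            raise ValueError("correlation matrix is not positive-definite")

    @property
    def alpha(self) -> float:
        return math.exp(self.alpha_raw)

    @property
    def phi(self) -> float:
        return float(ndtr(self.phi_probit))

    @property
    def covariance(self) -> np.ndarray:
        return np.outer(self.sigma, self.sigma) * self.correlation


@dataclass(frozen=True)
class IndividualParameters:
    """One participant's decision bias, loss aversion and probability
    sensitivity."""

    beta_i: float
    lambda_i: float
    gamma_i: float

    def __post_init__(self) -> None:
        if not 0.0 < self.lambda_i < 1.0:
            raise ValueError("lambda_i must lie in (0, 1)")
        if not 0.0 < self.gamma_i < 1.0:
            raise ValueError("gamma_i must lie in (0, 1)")

    @property
    def Lambda(self) -> float:
        return loss_aversion_Lambda(self.lambda_i)


def loss_aversion_Lambda(lambda_i: float) -> float:
    """Conventional loss-aversion multiplier Lambda = lambda/(1-lambda)."""
    return lambda_i / (1.0 - lambda_i)


def transform_individual_parameters(
    group: GroupParameters, zeta: Sequence[float]
) -> IndividualParameters:
    """Map a participant's displacement vector (zeta_b, zeta_l, zeta_g) to
    individual parameters via the hierarchy's probit links."""
    zb, zl, zg = (float(z) for z in zeta)
    return IndividualParameters(
        beta_i=group.beta + zb,
        lambda_i=float(ndtr(group.lambda_probit + zl)),
        gamma_i=float(ndtr(group.gamma_probit + zg)),
    )


def value_function(
    rating: float, lambda_i: float, alpha: float, kind: str, ignored: bool
) -> float:
    """Three-case prospect-theory value of a signed affect rating."""
    if ignored:
        return 0.0
    if rating == 0:
        raise ValueError("affect ratings exclude 0 (scale is -5..-1, 1..5)")
    if kind == "side_effect":
        if rating > 0:
            raise ValueError("side-effect ratings must be negative")
        return -lambda_i * abs(rating) ** alpha
    if kind == "benefit":
        if rating < 0:
            raise ValueError("benefit ratings must be positive")
        return (1.0 - lambda_i) * rating**alpha
    raise ValueError(f"unknown outcome kind {kind!r}")


def weight_probability(
    p: float | None, gamma_i: float, neglected: bool
) -> float:
    """Two-case decision weight: Prelec weighting of an inspected
    probability, a fixed 0.5 for a neglected (or never-presented) one."""
    if neglected or p is MISSING:
        return W_NEGLECT
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p!r} outside [0, 1]")
    if not 0.0 <= gamma_i <= 1.0:
        raise ValueError(f"gamma_i {gamma_i!r} outside [0, 1]")
    p = min(max(p, P_CLAMP[0]), P_CLAMP[1])
    return math.exp(-((-math.log(p)) ** gamma_i))


@dataclass(frozen=True)
class TrialOutcome:
    """One outcome of one trial as the model sees it."""

    rating: int
    probability: float | None
    kind: str
    outcome_ignored: bool
    probability_neglected: bool

    def __post_init__(self) -> None:
        if self.probability_neglected and self.outcome_ignored:
            raise ValueError(
                "probability_neglected requires the outcome to be inspected"
            )


@dataclass(frozen=True)
class TrialInput:
    """Model inputs for one participant x vaccine trial."""

    outcomes: tuple[TrialOutcome, ...]
    x_row: np.ndarray  # 4 sum-to-zero contrast entries


def subjective_valuation(
    trial: TrialInput, ind: IndividualParameters, alpha: float
) -> float:
    """Prospect-theory valuation V_iv: sum of value x weight over the
    trial's side effects and benefits."""
    total = 0.0
    for o in trial.outcomes:
        v = value_function(o.rating, ind.lambda_i, alpha, o.kind, o.outcome_ignored)
        if o.outcome_ignored:
            continue
        w = weight_probability(o.probability, ind.gamma_i, o.probability_neglected)
        total += v * w
    return total


def acceptance_probability(
    ind: IndividualParameters,
    x_row: np.ndarray,
    beta_j: np.ndarray,
    phi: float,
    V: float,
) -> float:
    """P(accept) = logistic(beta_i + X_v . beta_j + phi V)."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    return float(expit(ind.beta_i + float(np.dot(x_row, beta_j)) + phi * V))


def contrast_matrix(table: EvidenceTable) -> np.ndarray:
    """8x4 sum-to-zero design: columns 1-2 code country (US, China, other),
    columns 3-4 technology (mRNA, vector, other)."""
    X = np.zeros((len(table.vaccines), 4))
    specs = [
        ("country_category", ("US", "China", "other"), 0),
        ("technology_category", ("mRNA", "vector", "other"), 2),
    ]
    for attr, levels, col0 in specs:
        values = [getattr(v, attr) for v in table.vaccines]
        for level in levels:
            if level not in values:
                raise ValueError(f"category level {level!r} of {attr} has no vaccines")
        for r, val in enumerate(values):
            k = levels.index(val)
            if k < 2:
                X[r, col0 + k] = 1.0
            else:  # reference level: minus the sum of the others
                X[r, col0] = X[r, col0 + 1] = -1.0
    return X


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class ModelDataset:
    """Vectorized inputs for one attitude group: N participants x 8 vaccines
    x 6 outcome slots (3 side effects then 3 benefits)."""

    participant_ids: list[str]
    brands: list[str]
    y: np.ndarray  # [N, 8] 0/1 decisions (1 = accept)
    rating_mag: np.ndarray  # [N, 8, 6] |affect rating|, 1..5
    p: np.ndarray  # [8, 6] probabilities (NaN where never presented)
    m_prelec: np.ndarray  # [N, 8, 6] outcome and probability inspected
    m_half: np.ndarray  # [N, 8, 6] outcome inspected, probability not
    X: np.ndarray  # [8, 4] vaccine contrasts

    @property
    def n_participants(self) -> int:
        return self.y.shape[0]

    @property
    def n_trials(self) -> int:
        return int(self.y.size)

    def __post_init__(self) -> None:
        if np.any(self.m_prelec & self.m_half):
            raise ValueError("an outcome cannot be both weighted and neglected")
        missing = np.isnan(self.p)
        if np.any(self.m_prelec & missing[None, :, :]):
            raise ValueError("Prelec weighting requires a presented probability")


def build_model_dataset(
    table: EvidenceTable,
    ratings: pd.DataFrame,
    summaries: pd.DataFrame,
    decisions: pd.DataFrame,
) -> ModelDataset:
    """Assemble model arrays from the pipeline's tabular outputs.

    ``ratings``: columns (participant_id, outcome_label, rating).
    ``summaries``: one row per participant x trial with per-slot
    ``{slot}_insp`` / ``{slot}_prob_insp`` flags (see inspection module).
    ``decisions``: columns (participant_id, vaccine, decision).
    """
    from .evidence import normalize_label

    brands = table.brands
    pids = sorted(decisions["participant_id"].astype(str).unique())
    n = len(pids)
    pid_ix = {p: i for i, p in enumerate(pids)}
    brand_ix = {b: j for j, b in enumerate(brands)}

    p = np.full((8, 6), np.nan)
    labels = np.empty((8, 6), dtype=object)
    for j, v in enumerate(table.vaccines):
        for k, o in enumerate(v.outcomes):
            labels[j, k] = normalize_label(o.label)
            if o.probability is not MISSING:
                p[j, k] = o.probability

    rmap: dict[tuple[str, str], float] = {}
    for row in ratings.itertuples(index=False):
        rmap[(str(row.participant_id), normalize_label(row.outcome_label))] = float(
            row.rating
        )
    rating_mag = np.zeros((n, 8, 6))
    for pid, i in pid_ix.items():
        for j in range(8):
            for k in range(6):
                try:
                    rating_mag[i, j, k] = abs(rmap[(pid, labels[j, k])])
                except KeyError:
                    raise ValueError(
                        f"participant {pid!r} lacks a rating for {labels[j, k]!r}"
                    ) from None

    y = np.zeros((n, 8))
    seen = np.zeros((n, 8), dtype=bool)
    for row in decisions.itertuples(index=False):
        i, j = pid_ix[str(row.participant_id)], brand_ix[row.vaccine]
        y[i, j] = 1.0 if str(row.decision) == "accept" else 0.0
        seen[i, j] = True
    if not seen.all():
        raise ValueError("every participant needs a decision for all 8 vaccines")

    m_prelec = np.zeros((n, 8, 6), dtype=bool)
    m_half = np.zeros((n, 8, 6), dtype=bool)
    for row in summaries.itertuples(index=False):
        pid = str(row.participant_id)
        if pid not in pid_ix:
            continue
        i, j = pid_ix[pid], brand_ix[row.vaccine]
        for k, slot in enumerate(_SLOTS):
            insp = bool(getattr(row, f"{slot}_insp"))
            prob_insp = bool(getattr(row, f"{slot}_prob_insp"))
            if insp and prob_insp and not np.isnan(p[j, k]):
                m_prelec[i, j, k] = True
            elif insp:
                m_half[i, j, k] = True
    return ModelDataset(
        participant_ids=pids,
        brands=list(brands),
        y=y,
        rating_mag=rating_mag,
        p=p,
        m_prelec=m_prelec,
        m_half=m_half,
        X=contrast_matrix(table),
    )


# ---------------------------------------------------------------------------
# vectorized likelihood core (shared by the centered density and the sampler)
# ---------------------------------------------------------------------------

def _prepared(ds: ModelDataset) -> tuple[np.ndarray, np.ndarray]:
    """(log rating magnitude, log(-log p_clamped)) with the clamp applied;
    memoized on the dataset object (its arrays are treated as immutable)."""
    cached = getattr(ds, "_prepared_arrays", None)
    if cached is None:
        ln_a = np.log(ds.rating_mag)
        pc = np.clip(np.nan_to_num(ds.p, nan=0.5), P_CLAMP[0], P_CLAMP[1])
        cached = (ln_a, np.log(-np.log(pc)))
        ds._prepared_arrays = cached
    return cached


def _linear_predictor(
    ds: ModelDataset,
    beta_i: np.ndarray,
    lam_i: np.ndarray,
    gam_i: np.ndarray,
    alpha: float,
    phi: float,
    beta_j: np.ndarray,
):
    """Returns (eta, V, intermediates) for all N x 8 trials."""
    ln_a, q = _prepared(ds)
    A = np.exp(alpha * ln_a)  # |a|^alpha
    E = np.exp(gam_i[:, None, None] * q[None])  # (-ln p)^gamma_i
    w_pre = np.exp(-E)
    W = ds.m_prelec * w_pre + W_NEGLECT * ds.m_half
    AW = A * W
    S_se = (AW * _IS_SE).sum(axis=2)
    S_b = (AW * ~_IS_SE).sum(axis=2)
    V = -lam_i[:, None] * S_se + (1.0 - lam_i)[:, None] * S_b
    eta = beta_i[:, None] + (ds.X @ beta_j)[None, :] + phi * V
    return eta, V, (ln_a, q, A, E, w_pre, W, S_se, S_b)


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # overflowing linear predictors surface as a non-finite total, which the
    # sampler treats as a divergent proposal
    with np.errstate(invalid="ignore", over="ignore"):
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


# ---------------------------------------------------------------------------
# centered joint log-density (the model's specification)
# ---------------------------------------------------------------------------

def _norm_logpdf(x: float | np.ndarray, mu: float = 0.0, sd: float = 1.0):
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)


def model_log_density(
    dataset: ModelDataset,
    group: GroupParameters,
    zetas: np.ndarray,
    lkj_eta: float = LKJ_ETA,
) -> float:
    """Joint log-density (Bernoulli likelihood + priors) in the centered
    parameterization.

    The LKJ term is the unnormalized (eta-1) log det R; all other prior
    terms carry their full normalizing constants (the truncated-normal SD
    priors include the fixed truncation mass on (0, 1)).  Raises if any
    term is non-finite.
    """
    zetas = np.asarray(zetas, dtype=float)
    n = dataset.n_participants
    if zetas.shape != (n, 3):
        raise ValueError(f"zetas must have shape ({n}, 3)")

    beta_i = group.beta + zetas[:, 0]
    lam_i = ndtr(group.lambda_probit + zetas[:, 1])
    gam_i = ndtr(group.gamma_probit + zetas[:, 2])
    eta, _, _ = _linear_predictor(
        dataset, beta_i, lam_i, gam_i, group.alpha, group.phi, group.beta_j
    )
    ll = _bernoulli_loglik(dataset.y, eta)

    lp = 0.0
    lp += _norm_logpdf(group.beta)
    lp += float(np.sum(_norm_logpdf(group.beta_j)))
    lp += _norm_logpdf(group.lambda_probit)
    lp += _norm_logpdf(group.gamma_probit)
    lp += _norm_logpdf(group.phi_probit)
    lp += _norm_logpdf(group.alpha_raw, 0.0, 0.5)
    # sigma_beta ~ gamma(shape=2, rate=1): log x - x  (Gamma(2) = 1)
    lp += math.log(group.sigma[0]) - group.sigma[0]
    # sigma_lambda, sigma_gamma ~ N(0.5, 0.13) truncated to (0, 1)
    trunc_mass = float(
        ndtr((1.0 - _SD_TRUNC_MU) / _SD_TRUNC_SD)
        - ndtr((0.0 - _SD_TRUNC_MU) / _SD_TRUNC_SD)
    )
    for s in group.sigma[1:]:
        if not 0.0 < s < 1.0:
            raise ValueError("sigma_lambda and sigma_gamma must lie in (0, 1)")
        lp += float(_norm_logpdf(s, _SD_TRUNC_MU, _SD_TRUNC_SD)) - math.log(trunc_mass)
    sign, logdet_R = np.linalg.slogdet(group.correlation)
    lp += (lkj_eta - 1.0) * logdet_R
    # zetas ~ MVN(0, Sigma)
    Sigma = group.covariance
    L = np.linalg.cholesky(Sigma)
    zw = solve_triangular(L, zetas.T, lower=True)
    lp += float(
        -0.5 * np.sum(zw**2)
        - n * (np.sum(np.log(np.diag(L))) + 1.5 * math.log(2 * math.pi))
    )
    total = ll + lp
    if not np.isfinite(total):
        raise FloatingPointError("non-finite joint log-density")
    return total


# ---------------------------------------------------------------------------
# unconstrained parameterization for HMC/NUTS
# ---------------------------------------------------------------------------
#
# theta = [beta, beta_j (4), lambda_probit, gamma_probit, phi_probit,
#          alpha_raw, log sigma_beta, logit sigma_lambda, logit sigma_gamma,
#          y_cpc (3), z (N*3 non-centered displacements)]
#
# The correlation matrix is coded by canonical partial correlations
# c = tanh(y_cpc); under LKJ(eta) these are independent shifted Betas
# (C-vine construction), so the prior-plus-Jacobian term in y is
# sum_k a_k log(1 - c_k^2) with a = (eta + 1/2, eta + 1/2, eta).

_N_GROUP = 15


def n_unconstrained(n_participants: int) -> int:
    return _N_GROUP + 3 * n_participants


def _logit(x: float) -> float:
    return math.log(x / (1.0 - x))


def pack_parameters(group: GroupParameters, z: np.ndarray) -> np.ndarray:
    """Pack group parameters and non-centered displacements z [N, 3] into an
    unconstrained vector (inverse of :func:`unpack_parameters`)."""
    R = group.correlation
    c12, c13 = R[1, 0], R[2, 0]
    # invert the partial-correlation Cholesky coding
    c23p = (R[2, 1] - c12 * c13) / math.sqrt((1 - c12**2) * (1 - c13**2))
    theta = np.concatenate(
        [
            [group.beta],
            group.beta_j,
            [
                group.lambda_probit,
                group.gamma_probit,
                group.phi_probit,
                group.alpha_raw,
                math.log(group.sigma[0]),
                _logit(group.sigma[1]),
                _logit(group.sigma[2]),
                math.atanh(c12),
                math.atanh(c13),
                math.atanh(c23p),
            ],
            np.asarray(z, dtype=float).ravel(),
        ]
    )
    return theta


def _cpc_to_chol(c: np.ndarray) -> np.ndarray:
    """Cholesky factor of the correlation matrix from its three canonical
    partial correlations (c12, c13, c23|1)."""
    c1, c2, c3 = c
    L = np.zeros((3, 3))
    L[0, 0] = 1.0
    L[1, 0] = c1
    L[1, 1] = math.sqrt(1.0 - c1**2)
    L[2, 0] = c2
    s2 = math.sqrt(1.0 - c2**2)
    L[2, 1] = c3 * s2
    L[2, 2] = s2 * math.sqrt(1.0 - c3**2)
    return L


def unpack_parameters(
    theta: np.ndarray, n_participants: int
) -> tuple[GroupParameters, np.ndarray]:
    """Unpack an unconstrained vector into (GroupParameters, zetas [N, 3]),
    with zetas on the centered scale."""
    g = theta[:_N_GROUP]
    sigma = np.array([math.exp(g[9]), expit(g[10]), expit(g[11])])
    c = np.tanh(g[12:15])
    L = _cpc_to_chol(c)
    R = L @ L.T
    R[np.diag_indices(3)] = 1.0
    group = GroupParameters(
        beta=float(g[0]),
        beta_j=g[1:5].copy(),
        lambda_probit=float(g[5]),
        gamma_probit=float(g[6]),
        phi_probit=float(g[7]),
        alpha_raw=float(g[8]),
        sigma=sigma,
        correlation=R,
    )
    z = theta[_N_GROUP:].reshape(n_participants, 3)
    zetas = (z @ L.T) * sigma[None, :]
    return group, zetas


def _likelihood_core_numpy(dataset, beta_i, lam_i, gam_i, alpha, phi, beta_j):
    """Forward + backward pass of the Bernoulli likelihood.

    Returns (ll, resid_col_sum[8], d_beta_i, d_lam_i, d_gam_i, d_alpha,
    d_phi); the reference implementation, vectorized in numpy."""
    eta, V, inter = _linear_predictor(
        dataset, beta_i, lam_i, gam_i, alpha, phi, beta_j
    )
    ln_a, q, A, E, w_pre, W, S_se, S_b = inter
    ll = _bernoulli_loglik(dataset.y, eta)
    resid = dataset.y - expit(eta)
    d_beta_i = resid.sum(axis=1)
    d_phi = float(np.sum(resid * V))
    dV = phi * resid
    d_lam_i = -(dV * (S_se + S_b)).sum(axis=1)
    coef = np.where(_IS_SE, -lam_i[:, None, None], (1.0 - lam_i)[:, None, None])
    dAW = dV[:, :, None] * coef
    d_alpha = float(np.sum(dAW * W * A * ln_a))
    dw_pre = dAW * A * dataset.m_prelec
    d_gam_i = -(dw_pre * w_pre * E * q[None]).sum(axis=(1, 2))
    return ll, resid.sum(axis=0), d_beta_i, d_lam_i, d_gam_i, d_alpha, d_phi


try:  # optional compiled fast path; numerically identical to the numpy core
    from numba import njit

    @njit(cache=False)
    def _likelihood_kernel(y, ln_a, q, mpre, mhalf, xb, alpha, phi,
                           beta_i, lam, gam):
        n, nv, nk = ln_a.shape
        ll = 0.0
        d_alpha = 0.0
        d_phi = 0.0
        resid_sum = np.zeros(nv)
        d_beta_i = np.zeros(n)
        d_lam = np.zeros(n)
        d_gam = np.zeros(n)
        a_pow = np.zeros(nk)
        w_arr = np.zeros(nk)
        e_arr = np.zeros(nk)
        for i in range(n):
            li = lam[i]
            gi = gam[i]
            dbi = 0.0
            dli = 0.0
            dgi = 0.0
            for v in range(nv):
                s_se = 0.0
                s_b = 0.0
                for k in range(nk):
                    if mpre[i, v, k]:
                        a_pow[k] = math.exp(alpha * ln_a[i, v, k])
                        e_arr[k] = math.exp(gi * q[v, k])
                        w_arr[k] = math.exp(-e_arr[k])
                    elif mhalf[i, v, k]:
                        a_pow[k] = math.exp(alpha * ln_a[i, v, k])
                        w_arr[k] = 0.5
                        e_arr[k] = 0.0
                    else:
                        a_pow[k] = 0.0
                        w_arr[k] = 0.0
                        e_arr[k] = 0.0
                    if k < 3:
                        s_se += a_pow[k] * w_arr[k]
                    else:
                        s_b += a_pow[k] * w_arr[k]
                V = -li * s_se + (1.0 - li) * s_b
                eta = beta_i[i] + xb[v] + phi * V
                if eta > 0.0:
                    ll += y[i, v] * eta - (eta + math.log1p(math.exp(-eta)))
                    p = 1.0 / (1.0 + math.exp(-eta))
                else:
                    ll += y[i, v] * eta - math.log1p(math.exp(eta))
                    p = math.exp(eta) / (1.0 + math.exp(eta))
                resid = y[i, v] - p
                resid_sum[v] += resid
                dbi += resid
                d_phi += resid * V
                dV = phi * resid
                dli -= dV * (s_se + s_b)
                for k in range(nk):
                    if a_pow[k] == 0.0:
                        continue
                    coef = -li if k < 3 else (1.0 - li)
                    dAW = dV * coef
                    d_alpha += dAW * w_arr[k] * a_pow[k] * ln_a[i, v, k]
                    if mpre[i, v, k]:
                        dgi -= dAW * a_pow[k] * w_arr[k] * e_arr[k] * q[v, k]
            d_beta_i[i] = dbi
            d_lam[i] = dli
            d_gam[i] = dgi
        return ll, resid_sum, d_beta_i, d_lam, d_gam, d_alpha, d_phi

    def _likelihood_core_numba(dataset, beta_i, lam_i, gam_i, alpha, phi, beta_j):
        cached = getattr(dataset, "_numba_arrays", None)
        if cached is None:
            ln_a, q = _prepared(dataset)
            cached = (
                np.ascontiguousarray(dataset.y),
                np.ascontiguousarray(ln_a),
                np.ascontiguousarray(q),
                np.ascontiguousarray(dataset.m_prelec.astype(np.uint8)),
                np.ascontiguousarray(dataset.m_half.astype(np.uint8)),
            )
            dataset._numba_arrays = cached
        y, ln_a, q, mpre, mhalf = cached
        xb = dataset.X @ beta_j
        return _likelihood_kernel(
            y, ln_a, q, mpre, mhalf, xb, alpha, phi,
            np.ascontiguousarray(beta_i),
            np.ascontiguousarray(lam_i),
            np.ascontiguousarray(gam_i),
        )

    _likelihood_core = _likelihood_core_numba
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _likelihood_core = _likelihood_core_numpy


def unconstrained_log_density_and_grad(
    theta: np.ndarray, dataset: ModelDataset
) -> tuple[float, np.ndarray]:
    """Log-density of the unconstrained reparameterization and its analytic
    gradient.

    Equals the centered joint density plus the change-of-variables terms
    (log-Jacobians of the log / logit / tanh transforms; the non-centered
    displacements carry a standard-normal density).  Constant offsets are
    dropped.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        n = dataset.n_participants
        g = theta[:_N_GROUP]
        beta = g[0]
        beta_j = g[1:5]
        lam_p, gam_p, phi_p, alpha_raw = g[5], g[6], g[7], g[8]
        s_beta, t_lam, t_gam = g[9], g[10], g[11]
        y_cpc = g[12:15]
        z = theta[_N_GROUP:].reshape(n, 3)

        sigma_b = math.exp(s_beta)
        sigma_l = float(expit(t_lam))
        sigma_g = float(expit(t_gam))
        c = np.tanh(np.clip(y_cpc, -18.0, 18.0))
        L = _cpc_to_chol(c)

        u = z @ L.T  # correlated standard displacements
        beta_i = beta + sigma_b * u[:, 0]
        lam_arg = lam_p + sigma_l * u[:, 1]
        gam_arg = gam_p + sigma_g * u[:, 2]
        lam_i = ndtr(lam_arg)
        gam_i = ndtr(gam_arg)
        alpha = math.exp(alpha_raw)
        phi = float(ndtr(phi_p))

        ll, resid_col, d_beta_i, d_lam_i, d_gam_i, d_alpha, d_phi = (
            _likelihood_core(dataset, beta_i, lam_i, gam_i, alpha, phi, beta_j)
        )
        d_beta = float(d_beta_i.sum())
        d_beta_j = dataset.X.T @ resid_col

        pdf_lam = np.exp(-0.5 * lam_arg**2) / math.sqrt(2 * math.pi)
        pdf_gam = np.exp(-0.5 * gam_arg**2) / math.sqrt(2 * math.pi)
        d_lam_arg = d_lam_i * pdf_lam
        d_gam_arg = d_gam_i * pdf_gam

        du = np.empty((n, 3))
        du[:, 0] = d_beta_i * sigma_b
        du[:, 1] = d_lam_arg * sigma_l
        du[:, 2] = d_gam_arg * sigma_g
        d_sigma_b = float(np.sum(d_beta_i * u[:, 0]))
        d_sigma_l = float(np.sum(d_lam_arg * u[:, 1]))
        d_sigma_g = float(np.sum(d_gam_arg * u[:, 2]))
        dz = du @ L
        dL = du.T @ z  # [3, 3]; entries outside the lower triangle are unused

        # ---- priors (and transform Jacobians) on the unconstrained scale
        lp = ll
        grad = np.zeros_like(theta)

        lp += -0.5 * (beta**2 + float(np.sum(beta_j**2)) + lam_p**2 + gam_p**2 + phi_p**2)
        lp += -2.0 * alpha_raw**2  # N(0, 0.5)
        lp += 2.0 * s_beta - sigma_b  # gamma(2,1) on sigma_b + log Jacobian
        for sig in (sigma_l, sigma_g):
            lp += (
                -0.5 * ((sig - _SD_TRUNC_MU) / _SD_TRUNC_SD) ** 2
                + math.log(sig)
                + math.log1p(-sig)
            )
        a_cpc = np.array([LKJ_ETA + 0.5, LKJ_ETA + 0.5, LKJ_ETA])
        lp += float(np.sum(a_cpc * np.log1p(-(c**2))))
        lp += -0.5 * float(np.sum(z**2))

        pdf_phi = math.exp(-0.5 * phi_p**2) / math.sqrt(2 * math.pi)
        grad[0] = d_beta - beta
        grad[1:5] = d_beta_j - beta_j
        grad[5] = float(d_lam_arg.sum()) - lam_p
        grad[6] = float(d_gam_arg.sum()) - gam_p
        grad[7] = d_phi * pdf_phi - phi_p
        grad[8] = d_alpha * alpha - 4.0 * alpha_raw
        grad[9] = d_sigma_b * sigma_b + 2.0 - sigma_b
        for ix, (sig, d_sig) in ((10, (sigma_l, d_sigma_l)), (11, (sigma_g, d_sigma_g))):
            dprior = -(sig - _SD_TRUNC_MU) / _SD_TRUNC_SD**2
            grad[ix] = (d_sig + dprior) * sig * (1.0 - sig) + (1.0 - 2.0 * sig)

        c1, c2, c3 = c
        s1 = math.sqrt(1.0 - c1**2)
        s2 = math.sqrt(1.0 - c2**2)
        s3 = math.sqrt(1.0 - c3**2)
        dc = np.zeros(3)
        dc[0] = dL[1, 0] - dL[1, 1] * c1 / s1
        dc[1] = dL[2, 0] - (dL[2, 1] * c3 + dL[2, 2] * s3) * c2 / s2
        dc[2] = dL[2, 1] * s2 - dL[2, 2] * s2 * c3 / s3
        grad[12:15] = dc * (1.0 - c**2) - 2.0 * a_cpc * c
        grad[_N_GROUP:] = (dz - z).ravel()

        if not np.isfinite(lp):
            raise FloatingPointError("non-finite log-density at the evaluated point")
        return float(lp), grad
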