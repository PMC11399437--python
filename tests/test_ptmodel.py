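"""Value function, probability weighting, valuation, contrasts, and the
joint log-density (checked against an independent brute-force oracle)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.special import ndtr, ndtri

from conftest import make_toy_dataset
from vaxtrace import ptmodel
from vaxtrace.ptmodel import (
    GroupParameters,
    IndividualParameters,
    TrialInput,
    TrialOutcome,
    acceptance_probability,
    contrast_matrix,
    loss_aversion_Lambda,
    model_log_density,
    subjective_valuation,
    transform_individual_parameters,
    unconstrained_log_density_and_grad,
    value_function,
    weight_probability,
)


class TestValueFunction:
    def test_ignored_outcome_is_zero(self):
        assert value_function(-4, 0.7, 1.2, "side_effect", ignored=True) == 0.0

    def test_cubic_exponent_magnitude(self):
        lam = 0.8
        assert value_function(-5, lam, 3.0, "side_effect", False) == pytest.approx(
            -lam * 125.0
        )
        assert value_function(5, lam, 3.0, "benefit", False) == pytest.approx(
            (1 - lam) * 125.0
        )

    def test_loss_neutral_symmetry(self):
        for a in (1, 2, 3, 4, 5):
            neg = value_function(-a, 0.5, 1.0, "side_effect", False)
            pos = value_function(a, 0.5, 1.0, "benefit", False)
            assert abs(neg) == pytest.approx(pos)

    def test_zero_rating_rejected(self):
        with pytest.raises(ValueError, match="exclude 0"):
            value_function(0, 0.5, 1.0, "side_effect", False)

    def test_sign_consistency_enforced(self):
        with pytest.raises(ValueError):
            value_function(3, 0.5, 1.0, "side_effect", False)
        with pytest.raises(ValueError):
            value_function(-3, 0.5, 1.0, "benefit", False)

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.integers(min_value=1, max_value=5),
        lam=st.floats(min_value=0.01, max_value=0.99),
        alpha=st.floats(min_value=0.1, max_value=4.0),
    )
    def test_sign_and_loss_aversion_properties(self, a, lam, alpha):
        neg = value_function(-a, lam, alpha, "side_effect", False)
        pos = value_function(a, lam, alpha, "benefit", False)
        assert neg <= 0.0 <= pos
        if lam > 0.5:
            assert abs(neg) > pos  # losses loom larger


class TestWeighting:
    def test_gamma_zero_constant_037(self):
        for p in (0.00002, 0.1, 0.5, 0.95):
            assert weight_probability(p, 0.0, False) == pytest.approx(0.37, abs=0.005)

    def test_gamma_one_identity(self):
        assert weight_probability(0.95, 1.0, False) == pytest.approx(0.95)

    def test_neglected_is_half(self):
        assert weight_probability(0.95, 0.7, True) == 0.5
        assert weight_probability(None, 0.7, False) == 0.5

    def test_rare_probability_oracle(self):
        # independent high-precision evaluation of exp(-(-ln p)^0.5)
        p = 0.00002
        expected = math.exp(-math.sqrt(-math.log(p)))
        assert weight_probability(p, 0.5, False) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0373, abs=5e-4)

    def test_fixed_point_at_inverse_e(self):
        for gamma in (0.2, 0.5, 0.8, 1.0):
            assert weight_probability(math.exp(-1), gamma, False) == pytest.approx(
                math.exp(-1), rel=1e-9
            )

    @settings(max_examples=100, deadline=None)
    @given(
        gamma=st.floats(min_value=0.05, max_value=1.0),
        p1=st.floats(min_value=1e-6, max_value=1 - 1e-6),
        p2=st.floats(min_value=1e-6, max_value=1 - 1e-6),
    )
    def test_strictly_increasing_in_p(self, gamma, p1, p2):
        if p1 > p2:
            p1, p2 = p2, p1
        w1 = weight_probability(p1, gamma, False)
        w2 = weight_probability(p2, gamma, False)
        assert (w1 < w2) or (p1 == p2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            weight_probability(1.5, 0.5, False)


class TestValuation:
    def test_full_ignorance_gives_zero(self):
        trial = TrialInput(
            outcomes=tuple(
                TrialOutcome(-3 if k < 3 else 3, 0.5, "side_effect" if k < 3 else "benefit", True, False)
                for k in range(6)
            ),
            x_row=np.zeros(4),
        )
        ind = IndividualParameters(0.0, 0.6, 0.4)
        assert subjective_valuation(trial, ind, 1.0) == 0.0

    def test_single_side_effect_hand_value(self):
        # one inspected side effect: a=-2, gamma=1, alpha=1, lambda=0.5
        p = 0.3
        trial = TrialInput(
            outcomes=(
                TrialOutcome(-2, p, "side_effect", False, False),
                TrialOutcome(-1, 0.5, "side_effect", True, False),
                TrialOutcome(-1, 0.5, "side_effect", True, False),
                TrialOutcome(1, 0.9, "benefit", True, False),
                TrialOutcome(1, 0.9, "benefit", True, False),
                TrialOutcome(1, 0.9, "benefit", True, False),
            ),
            x_row=np.zeros(4),
        )
        ind = IndividualParameters(0.0, 0.5, 1.0 - 1e-12)
        assert subjective_valuation(trial, ind, 1.0) == pytest.approx(
            -0.5 * 2 * p, rel=1e-6
        )

    def test_only_benefits_inspected_positive(self):
        trial = TrialInput(
            outcomes=(
                TrialOutcome(-5, 0.1, "side_effect", True, False),
                TrialOutcome(-5, 0.1, "side_effect", True, False),
                TrialOutcome(-5, 0.1, "side_effect", True, False),
                TrialOutcome(4, 0.9, "benefit", False, False),
                TrialOutcome(3, 0.9, "benefit", False, False),
                TrialOutcome(5, None, "benefit", False, False),
            ),
            x_row=np.zeros(4),
        )
        ind = IndividualParameters(0.0, 0.9, 0.5)
        assert subjective_valuation(trial, ind, 1.0) > 0.0


class TestAcceptance:
    def test_neutral_point(self):
        ind = IndividualParameters(0.0, 0.5, 0.5)
        assert acceptance_probability(ind, np.zeros(4), np.zeros(4), 0.5, 0.0) == 0.5

    def test_direct_logistic_value(self):
        # beta_i = 1, X.beta_j = -0.5, phi*V = 0.5 -> logistic(1.0)
        ind = IndividualParameters(1.0, 0.5, 0.5)
        x = np.array([1.0, 0, 0, 0])
        bj = np.array([-0.5, 0, 0, 0])
        p = acceptance_probability(ind, x, bj, 0.5, 1.0)
        assert p == pytest.approx(1 / (1 + math.exp(-1.0)), rel=1e-12)

    def test_saturation(self):
        lo = acceptance_probability(
            IndividualParameters(-40.0, 0.5, 0.5), np.zeros(4), np.zeros(4), 0.5, 0.0
        )
        assert lo == pytest.approx(0.0, abs=1e-12)


class TestTransforms:
    def test_zero_displacement_at_probit_zero(self):
        gp = GroupParameters(
            beta=0.3, beta_j=np.zeros(4), lambda_probit=0.0, gamma_probit=0.0,
            alpha_raw=0.0, phi_probit=0.0, sigma=np.ones(3), correlation=np.eye(3),
        )
        ind = transform_individual_parameters(gp, (0.0, 0.0, 0.0))
        assert ind.beta_i == pytest.approx(0.3)
        assert ind.lambda_i == pytest.approx(0.5)
        assert ind.Lambda == pytest.approx(1.0)  # loss neutrality

    def test_probit_095_quantile(self):
        gp = GroupParameters(
            beta=0.0, beta_j=np.zeros(4), lambda_probit=0.0, gamma_probit=0.0,
            alpha_raw=0.0, phi_probit=0.0, sigma=np.ones(3), correlation=np.eye(3),
        )
        ind = transform_individual_parameters(gp, (0.0, 1.6449, 0.0))
        assert ind.lambda_i == pytest.approx(0.95, abs=1e-4)

    def test_lambda_interpretation(self):
        assert loss_aversion_Lambda(0.8) == pytest.approx(4.0)


class TestContrasts:
    def test_shape_and_column_sums(self, table):
        X = contrast_matrix(table)
        assert X.shape == (8, 4)
        # summing each contrast column over the three category levels gives 0
        for attr, col0 in (("country_category", 0), ("technology_category", 2)):
            levels = {}
            for row, v in zip(X, table.vaccines):
                levels.setdefault(getattr(v, attr), row[col0 : col0 + 2])
            assert np.allclose(sum(levels.values()), 0.0)

    def test_same_cell_identical_rows(self, table):
        X = contrast_matrix(table)
        cells = {}
        for row, v in zip(X, table.vaccines):
            key = (v.country_category, v.technology_category)
            if key in cells:
                assert np.allclose(row, cells[key])
            cells[key] = row


# ---------------------------------------------------------------------------
# joint density against a brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_log_density(ds, group, zetas, lkj_eta=5.0):
    """Independent term-by-term evaluation with scipy.stats and plain loops."""
    total = 0.0
    alpha = math.exp(group.alpha_raw)
    phi = ndtr(group.phi_probit)
    for i in range(ds.n_participants):
        beta_i = group.beta + zetas[i, 0]
        lam = ndtr(group.lambda_probit + zetas[i, 1])
        gam = ndtr(group.gamma_probit + zetas[i, 2])
        for v in range(len(ds.brands)):
            V = 0.0
            for k in range(6):
                if not (ds.m_prelec[i, v, k] or ds.m_half[i, v, k]):
                    continue
                a = ds.rating_mag[i, v, k]
                value = -lam * a**alpha if k < 3 else (1 - lam) * a**alpha
                if ds.m_half[i, v, k]:
                    w = 0.5
                else:
                    p = min(max(ds.p[v, k], 1e-8), 1 - 1e-8)
                    w = math.exp(-((-math.log(p)) ** gam))
                V += value * w
            eta = beta_i + float(ds.X[v] @ group.beta_j) + phi * V
            p_acc = 1.0 / (1.0 + math.exp(-eta))
            total += math.log(p_acc) if ds.y[i, v] == 1 else math.log(1 - p_acc)
    # priors
    total += stats.norm.logpdf(group.beta)
    total += stats.norm.logpdf(group.beta_j).sum()
    total += stats.norm.logpdf(group.lambda_probit)
    total += stats.norm.logpdf(group.gamma_probit)
    total += stats.norm.logpdf(group.phi_probit)
    total += stats.norm.logpdf(group.alpha_raw, scale=0.5)
    total += stats.gamma.logpdf(group.sigma[0], a=2, scale=1.0)
    a_t, b_t = (0 - 0.5) / 0.13, (1 - 0.5) / 0.13
    total += stats.truncnorm.logpdf(group.sigma[1], a_t, b_t, loc=0.5, scale=0.13)
    total += stats.truncnorm.logpdf(group.sigma[2], a_t, b_t, loc=0.5, scale=0.13)
    total += (lkj_eta - 1.0) * np.linalg.slogdet(group.correlation)[1]
    total += stats.multivariate_normal.logpdf(
        zetas, mean=np.zeros(3), cov=group.covariance
    ).sum()
    return float(total)


def example_group():
    return GroupParameters(
        beta=-0.4,
        beta_j=np.array([0.2, -0.1, 0.05, 0.3]),
        lambda_probit=0.6,
        gamma_probit=-0.2,
        alpha_raw=0.1,
        phi_probit=-0.3,
        sigma=np.array([1.2, 0.45, 0.38]),
        correlation=np.array(
            [[1.0, 0.2, -0.1], [0.2, 1.0, 0.15], [-0.1, 0.15, 1.0]]
        ),
    )


class TestJointDensity:
    def test_matches_brute_force_oracle(self, toy_dataset):
        rng = np.random.default_rng(9)
        group = example_group()
        zetas = 0.5 * rng.standard_normal((3, 3))
        ours = model_log_density(toy_dataset, group, zetas)
        oracle = brute_force_log_density(toy_dataset, group, zetas)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_empty_dataset_is_prior_only(self):
        ds = make_toy_dataset(n_participants=1, n_vaccines=1, seed=2)
        # with one trial forced to an uninformative state: all ignored
        ds.m_prelec[:] = False
        ds.m_half[:] = False
        group = example_group()
        zetas = np.zeros((1, 3))
        full = model_log_density(ds, group, zetas)
        # likelihood of the single trial is log(0.5 +/- logistic offset);
        # isolate it by subtracting the brute-force prior-only value
        oracle = brute_force_log_density(ds, group, zetas)
        assert full == pytest.approx(oracle, abs=1e-8)

    def test_half_probability_everywhere(self):
        # all trials at P(accept) = 0.5: likelihood = n * ln(1/2), so the
        # density is invariant to flipping every decision
        ds = make_toy_dataset(n_participants=4, n_vaccines=3, seed=3)
        ds.m_prelec[:] = False
        ds.m_half[:] = False
        ds.X[:] = 0.0
        group = example_group()
        group.beta = 0.0
        zetas = np.zeros((4, 3))
        with_data = model_log_density(ds, group, zetas)
        flipped = make_toy_dataset(n_participants=4, n_vaccines=3, seed=3)
        flipped.m_prelec[:] = False
        flipped.m_half[:] = False
        flipped.X[:] = 0.0
        flipped.y = 1.0 - ds.y
        assert model_log_density(flipped, group, zetas) == pytest.approx(
            with_data, abs=1e-10
        )
        prior_only = brute_force_log_density(ds, group, zetas) - ds.y.size * math.log(0.5)
        assert with_data - prior_only == pytest.approx(
            ds.y.size * math.log(0.5), abs=1e-8
        )

    def test_zeta_shape_validated(self, toy_dataset):
        with pytest.raises(ValueError, match="shape"):
            model_log_density(toy_dataset, example_group(), np.zeros((2, 3)))


class TestUnconstrainedDensity:
    def test_gradient_matches_finite_differences(self, toy_dataset):
        rng = np.random.default_rng(12)
        theta = 0.4 * rng.standard_normal(ptmodel.n_unconstrained(3))
        _, grad = unconstrained_log_density_and_grad(theta, toy_dataset)
        eps = 1e-6
        for i in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (
                unconstrained_log_density_and_grad(tp, toy_dataset)[0]
                - unconstrained_log_density_and_grad(tm, toy_dataset)[0]
            ) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_pack_unpack_roundtrip(self):
        group = example_group()
        rng = np.random.default_rng(4)
        z = rng.standard_normal((5, 3))
        theta = ptmodel.pack_parameters(group, z)
        group2, zetas = ptmodel.unpack_parameters(theta, 5)
        assert group2.beta == pytest.approx(group.beta)
        assert np.allclose(group2.correlation, group.correlation)
        assert np.allclose(group2.sigma, group.sigma)
        # zetas are the centered displacements implied by (sigma, R, z)
        L = np.linalg.cholesky(group.correlation)
        expected = (z @ L.T) * group.sigma[None, :]
        assert np.allclose(zetas, expected)

    def test_compiled_and_reference_likelihood_cores_agree(self, toy_dataset):
        """The accelerated likelihood kernel reproduces the reference
        numpy implementation exactly (to floating-point roundoff)."""
        if ptmodel._likelihood_core is ptmodel._likelihood_core_numpy:
            pytest.skip("compiled kernel unavailable")
        rng = np.random.default_rng(30)
        for _ in range(5):
            beta_i = rng.standard_normal(3)
            lam = rng.uniform(0.05, 0.95, 3)
            gam = rng.uniform(0.05, 0.95, 3)
            bj = rng.standard_normal(4)
            alpha = float(rng.uniform(0.3, 2.5))
            phi = float(rng.uniform(0.05, 0.95))
            ref = ptmodel._likelihood_core_numpy(
                toy_dataset, beta_i, lam, gam, alpha, phi, bj
            )
            fast = ptmodel._likelihood_core_numba(
                toy_dataset, beta_i, lam, gam, alpha, phi, bj
            )
            for r, f in zip(ref, fast):
                assert np.allclose(r, f, rtol=1e-10, atol=1e-10)

    def test_density_differences_match_centered_specification(self, toy_dataset):
        """For two points sharing the same (sigma, R), the sampler's target
        and the centered density differ only by a constant: the quadratic
        form of the MVN zeta prior equals the standard-normal z prior under
        the non-centered map zeta = diag(sigma) L z."""
        group = example_group()
        rng = np.random.default_rng(8)
        z1 = rng.standard_normal((3, 3))
        z2 = rng.standard_normal((3, 3))
        th1 = ptmodel.pack_parameters(group, z1)
        th2 = ptmodel.pack_parameters(group, z2)
        lp1, _ = unconstrained_log_density_and_grad(th1, toy_dataset)
        lp2, _ = unconstrained_log_density_and_grad(th2, toy_dataset)
        _, zeta1 = ptmodel.unpack_parameters(th1, 3)
        _, zeta2 = ptmodel.unpack_parameters(th2, 3)
        c1 = model_log_density(toy_dataset, group, zeta1)
        c2 = model_log_density(toy_dataset, group, zeta2)
        assert (lp1 - lp2) == pytest.approx(c1 - c2, abs=1e-8)
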