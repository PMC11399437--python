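"""Hierarchical logistic and ordered-logit regressions: gradients, null and
planted-effect behavior, predicted values and pairwise comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from vaxtrace import association
from vaxtrace.association import (
    RegressionSpec,
    build_design,
    fit_hierarchical_logistic,
    fit_ordered_logit,
    odds_ratios,
    pairwise_difference,
    predicted_levels,
    sum_to_zero_columns,
)
from vaxtrace.inference import SamplerConfig

FAST = SamplerConfig(n_chains=2, n_warmup=300, n_sampling=300, thin=1, seed=3)


def logistic_data(n_participants=40, n_trials=6, effect=0.0, seed=0, sd_u=0.5):
    """Simulate from the hierarchical logistic truth: sum-to-zero coded
    two-level factor with a planted log-odds gap of 2*effect."""
    rng = np.random.default_rng(seed)
    rows = []
    u = sd_u * rng.standard_normal(n_participants)
    for i in range(n_participants):
        for t in range(n_trials):
            grp = "A" if (i + t) % 2 == 0 else "B"
            x = 1.0 if grp == "A" else -1.0
            eta = effect * x + u[i]
            rows.append(
                {
                    "participant_id": f"p{i}",
                    "grp": grp,
                    "y": int(rng.random() < expit(eta)),
                }
            )
    return pd.DataFrame(rows)


def ordinal_data(n_participants=40, n_trials=6, shift=0.0, seed=0):
    """Cumulative-logit truth with 4 levels and a latent group shift."""
    rng = np.random.default_rng(seed)
    cuts = np.array([-1.5, 0.0, 1.5])
    rows = []
    u = 0.5 * rng.standard_normal(n_participants)
    for i in range(n_participants):
        for t in range(n_trials):
            grp = "A" if i % 2 == 0 else "B"
            x = 1.0 if grp == "A" else -1.0
            eta = shift * x + u[i]
            pr = np.diff(np.concatenate([[0.0], expit(cuts - eta), [1.0]]))
            rows.append(
                {
                    "participant_id": f"p{i}",
                    "grp": grp,
                    "level": int(rng.choice(4, p=pr)) + 1,
                }
            )
    return pd.DataFrame(rows)


class TestDesign:
    def test_sum_to_zero_coding(self):
        s = pd.Series(["a", "b", "c", "a", "c"], name="f")
        D, levels = sum_to_zero_columns(s)
        assert D.shape == (5, 2)
        # each level's contrast row; the K rows sum to zero per column
        rows = {lv: D[list(s).index(lv)] for lv in levels}
        assert np.allclose(sum(rows.values()), 0.0)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="at least 2 levels"):
            sum_to_zero_columns(pd.Series(["a", "a"], name="f"))

    def test_interaction_columns(self):
        df = logistic_data(n_participants=8)
        df["other"] = np.where(df.index % 3 == 0, "x", "y")
        spec = RegressionSpec(
            outcome="y", family="bernoulli", predictors=("grp", "other"),
            interactions=(("grp", "other"),),
        )
        design = build_design(df, spec)
        assert "grp:other" in design.factor_columns
        assert design.matrix.shape[1] == 1 + 1 + 1


class TestGradients:
    def test_logistic_gradient_finite_differences(self):
        df = logistic_data(n_participants=6, n_trials=3, effect=0.4, seed=2)
        spec = RegressionSpec(outcome="y", family="bernoulli", predictors=("grp",))
        design = build_design(df, spec)
        y = df["y"].to_numpy().astype(float)
        rng = np.random.default_rng(4)
        theta = 0.3 * rng.standard_normal(2 + design.matrix.shape[1] + design.n_groups)
        _, grad = association._logistic_logp_grad(
            theta, y, design.matrix, design.group_index, design.n_groups, spec
        )
        eps = 1e-6
        for i in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (
                association._logistic_logp_grad(
                    tp, y, design.matrix, design.group_index, design.n_groups, spec
                )[0]
                - association._logistic_logp_grad(
                    tm, y, design.matrix, design.group_index, design.n_groups, spec
                )[0]
            ) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_ordered_gradient_finite_differences(self):
        df = ordinal_data(n_participants=6, n_trials=3, shift=0.5, seed=2)
        spec = RegressionSpec(outcome="level", family="ordered", predictors=("grp",))
        design = build_design(df, spec)
        y = (df["level"] - 1).to_numpy()
        K = 4
        rng = np.random.default_rng(5)
        theta = 0.3 * rng.standard_normal(K + design.matrix.shape[1] + design.n_groups)
        _, grad = association._ordered_logp_grad(
            theta, y, K, design.matrix, design.group_index, design.n_groups, spec
        )
        eps = 1e-6
        for i in range(theta.size):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (
                association._ordered_logp_grad(
                    tp, y, K, design.matrix, design.group_index, design.n_groups, spec
                )[0]
                - association._ordered_logp_grad(
                    tm, y, K, design.matrix, design.group_index, design.n_groups, spec
                )[0]
            ) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestLogistic:
    def test_non_binary_outcome_rejected(self):
        df = logistic_data(n_participants=6)
        df["y"] = df["y"] + 5
        spec = RegressionSpec(outcome="y", family="bernoulli", predictors=("grp",))
        with pytest.raises(ValueError, match="not binary"):
            fit_hierarchical_logistic(df, spec, FAST)

    def test_null_data_tracks_empirical_gap_and_predicts_half(self):
        from scipy.special import logit

        df = logistic_data(n_participants=40, effect=0.0, seed=7, sd_u=0.3)
        spec = RegressionSpec(outcome="y", family="bernoulli", predictors=("grp",))
        fit = fit_hierarchical_logistic(df, spec, FAST)
        diff = pairwise_difference(fit, "grp", "A", "B")
        means = df.groupby("grp")["y"].mean()
        empirical = float(logit(means["A"]) - logit(means["B"]))
        assert diff["hdi_low"] <= empirical <= diff["hdi_high"]
        levels = predicted_levels(fit, "grp")
        assert levels["median"].between(0.3, 0.7).all()

    def test_planted_effect_recovered(self):
        df = logistic_data(n_participants=120, n_trials=8, effect=0.5, seed=8)
        spec = RegressionSpec(outcome="y", family="bernoulli", predictors=("grp",))
        fit = fit_hierarchical_logistic(df, spec, FAST)
        coef = fit.parameter("grp[A]")
        from vaxtrace.inference import hdi

        lo, hi = hdi(coef, 0.95)
        assert lo <= 0.5 <= hi  # truth covered
        diff = pairwise_difference(fit, "grp", "A", "B")
        assert diff["excludes_zero"] and diff["difference_median"] > 0

    def test_odds_ratio_table(self):
        df = logistic_data(n_participants=60, n_trials=8, effect=0.6, seed=9)
        spec = RegressionSpec(outcome="y", family="bernoulli", predictors=("grp",))
        fit = fit_hierarchical_logistic(df, spec, FAST)
        table = odds_ratios(fit)
        row = table[table.coefficient == "grp[A]"].iloc[0]
        assert row.odds_ratio > 1.0 and row.relevant


class TestOrdered:
    def test_two_level_outcome_rejected(self):
        df = ordinal_data(n_participants=6)
        df["level"] = (df["level"] > 2).astype(int)
        spec = RegressionSpec(outcome="level", family="ordered", predictors=("grp",))
        with pytest.raises(ValueError, match="at least 3 levels"):
            fit_ordered_logit(df, spec, FAST)

    def test_planted_shift_sign_recovered(self):
        df = ordinal_data(n_participants=80, n_trials=8, shift=0.8, seed=10)
        spec = RegressionSpec(outcome="level", family="ordered", predictors=("grp",))
        fit = fit_ordered_logit(df, spec, FAST)
        # positive shift lowers observed levels under the cumulative-logit
        # parameterization eta = x*coef, P(y<=k) = logistic(c_k - eta):
        # group A (x=+1) has higher latent eta -> higher levels
        diff = pairwise_difference(fit, "grp", "A", "B")
        assert diff["difference_median"] > 0 and diff["excludes_zero"]

    def test_cutpoints_strictly_increasing_every_draw(self):
        df = ordinal_data(n_participants=30, n_trials=4, shift=0.3, seed=11)
        spec = RegressionSpec(outcome="level", family="ordered", predictors=("grp",))
        fit = fit_ordered_logit(df, spec, FAST)
        cuts = association._cutpoint_draws(fit)
        assert np.all(np.diff(cuts, axis=1) > 0)

    def test_level_probabilities_sum_to_one(self):
        df = ordinal_data(n_participants=30, n_trials=4, seed=12)
        spec = RegressionSpec(outcome="level", family="ordered", predictors=("grp",))
        fit = fit_ordered_logit(df, spec, FAST)
        lin = association._linear_level_draws(fit, "grp", "A")
        cuts = association._cutpoint_draws(fit)
        F = expit(cuts - lin[:, None])
        probs = np.diff(
            np.concatenate(
                [np.zeros((len(lin), 1)), F, np.ones((len(lin), 1))], axis=1
            ),
            axis=1,
        )
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert np.all(probs >= 0)


class TestPredictedLevels:
    @pytest.fixture(scope="class")
    def fit(self):
        df = logistic_data(n_participants=50, n_trials=6, effect=0.4, seed=13)
        spec = RegressionSpec(outcome="y", family="bernoulli", predictors=("grp",))
        return fit_hierarchical_logistic(df, spec, FAST)

    def test_agreement_with_explicit_per_draw_loop(self, fit):
        levels = predicted_levels(fit, "grp")
        intercept = fit.parameter("intercept")
        coef = fit.parameter("grp[A]")
        manual = np.array([expit(b0 + c) for b0, c in zip(intercept, coef)])
        row = levels[levels.level == "A"].iloc[0]
        assert row["median"] == pytest.approx(float(np.median(manual)), abs=1e-12)

    def test_probabilities_within_unit_interval(self, fit):
        levels = predicted_levels(fit, "grp")
        assert levels["median"].between(0, 1).all()
        assert levels["hdi_low"].ge(0).all() and levels["hdi_high"].le(1).all()

    def test_sum_to_zero_identity_on_linear_scale(self, fit):
        a = association._linear_level_draws(fit, "grp", "A")
        b = association._linear_level_draws(fit, "grp", "B")
        intercept = fit.parameter("intercept")
        assert np.allclose((a + b) / 2, intercept)

    def test_unknown_factor_rejected(self, fit):
        with pytest.raises(KeyError, match="unknown factor"):
            predicted_levels(fit, "nope")

    def test_pairwise_antisymmetry_and_identity(self, fit):
        ab = pairwise_difference(fit, "grp", "A", "B")
        ba = pairwise_difference(fit, "grp", "B", "A")
        assert ab["difference_median"] == pytest.approx(-ba["difference_median"])
        same = pairwise_difference(fit, "grp", "A", "A")
        assert same["difference_median"] == 0.0 and not same["excludes_zero"]


class TestTypeIBehavior:
    def test_null_flag_rate_is_small(self):
        """Across replicated null simulations the excludes-zero flag fires
        rarely (loose small-sample bound)."""
        flags = 0
        reps = 6
        for rep in range(reps):
            df = logistic_data(n_participants=30, n_trials=4, effect=0.0, seed=100 + rep)
            spec = RegressionSpec(outcome="y", family="bernoulli", predictors=("grp",))
            config = SamplerConfig(
                n_chains=2, n_warmup=200, n_sampling=200, thin=1, seed=rep
            )
            fit = fit_hierarchical_logistic(df, spec, config)
            if pairwise_difference(fit, "grp", "A", "B")["excludes_zero"]:
                flags += 1
        assert flags <= 2
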