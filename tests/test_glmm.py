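import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from mrprev import design, glmm, synthetic
from mrprev.design import ModelSpec, TimeBasisSpec, default_model_specs
from mrprev.glmm import FittedModel, fit, predict_cells, rescale_weights, select_model

CELLS = ["sex", "age_group", "race_eth", "ses"]


def irls_weighted_logistic(X, y, w, max_iter=100, tol=1e-12):
    """Independent oracle: plain weighted IRLS logistic regression."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        s = w * mu * (1 - mu)
        z = eta + (y - mu) / (mu * (1 - mu))
        beta_new = np.linalg.solve((X.T * s) @ X, (X.T * s) @ z)
        if np.max(np.abs(beta_new - beta)) < tol:
            return beta_new
        beta = beta_new
    return beta


class TestRescaleWeights:
    def test_equal_weights_become_one(self):
        df = pd.DataFrame(
            {"domain": [0] * 4, "wave": [0] * 4, "weight": [2.5] * 4}
        )
        assert np.allclose(rescale_weights(df)["weight"], 1.0)

    def test_hand_case(self):
        df = pd.DataFrame({"domain": [0, 0], "wave": [0, 0], "weight": [2.0, 6.0]})
        assert np.allclose(rescale_weights(df)["weight"], [0.5, 1.5])

    def test_sum_equals_stratum_size(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "domain": rng.integers(0, 3, 200),
                "wave": rng.integers(0, 2, 200),
                "weight": rng.lognormal(0, 1, 200),
            }
        )
        out = rescale_weights(df)
        sums = out.groupby(["domain", "wave"])["weight"].agg(["sum", "size"])
        assert np.allclose(sums["sum"], sums["size"])

    def test_nonpositive_weight_named(self):
        df = pd.DataFrame({"domain": [0, 0], "wave": [0, 0], "weight": [1.0, 0.0]})
        with pytest.raises(ValueError, match="record 1"):
            rescale_weights(df)


class TestFitOracle:
    def test_pinned_zero_variance_matches_irls(self, outcome_survey):
        # with all variance components at 0 the mixed fit must reproduce
        # weighted fixed-effects logistic regression
        spec = default_model_specs(4)[0]
        fitted = fit(outcome_survey, spec, fix_variances={"domain": 0.0})
        X, names, _ = design.design_matrix(outcome_survey, spec)
        beta_oracle = irls_weighted_logistic(
            X, outcome_survey["outcome"].to_numpy(float),
            outcome_survey["weight"].to_numpy(float),
        )
        assert np.max(np.abs(fitted.beta.to_numpy() - beta_oracle)) < 1e-4

    def test_balanced_intercept_near_zero(self):
        cfg = synthetic.TruthConfig(
            2, 2, {"intercept": 0.0}, 0.0, {}, seed=1,
            sample_sizes=synthetic.SampleSizes(outcome=2000),
        )
        truth = synthetic.build_truth(cfg)
        df = synthetic.generate_outcome_survey(cfg, truth)
        lf = design.center_labor_force(truth.labor_force)
        df = df.merge(lf[["domain", "wave", "lf_partic_c"]], on=["domain", "wave"])
        df = rescale_weights(df)
        fitted = fit(df, ModelSpec("m", TimeBasisSpec("linear", 2)))
        b0 = fitted.beta["intercept"]
        se0 = fitted.beta_se["intercept"]
        assert abs(b0) < 3 * se0

    def test_zero_domain_variance_recovered(self):
        cfg = synthetic.default_truth_config(
            3, 2, seed=2, sigma_domain=0.0,
            sample_sizes=synthetic.SampleSizes(outcome=4000),
        )
        truth = synthetic.build_truth(cfg)
        df = synthetic.generate_outcome_survey(cfg, truth)
        lf = design.center_labor_force(truth.labor_force)
        df = df.merge(lf[["domain", "wave", "lf_partic_c"]], on=["domain", "wave"])
        df = rescale_weights(df)
        fitted = fit(df, ModelSpec("m", TimeBasisSpec("linear", 2)))
        assert fitted.variance_components["domain"] < 0.01


class TestFitStatistics:
    def test_information_criteria_identity(self, model1_fit, outcome_survey):
        p = design.count_parameters(model1_fit.spec)
        n = len(outcome_survey)
        assert model1_fit.aic == pytest.approx(-2 * model1_fit.loglik + 2 * p)
        assert model1_fit.bic == pytest.approx(
            -2 * model1_fit.loglik + p * np.log(n)
        )

    def test_variance_components_nonnegative(self, model1_fit):
        assert all(v >= 0 for v in model1_fit.variance_components.values())

    def test_coefficient_count_matches_design(self, model1_fit, outcome_survey):
        X, names, _ = design.design_matrix(outcome_survey, model1_fit.spec)
        assert len(model1_fit.beta) == X.shape[1]
        assert list(model1_fit.beta.index) == names


class TestFitErrors:
    def test_single_domain_rejected(self, outcome_survey):
        single = outcome_survey[outcome_survey["domain"] == 0]
        with pytest.raises(ValueError, match="2 domains"):
            fit(single, default_model_specs(4)[0])

    def test_rank_deficiency_lists_columns(self, outcome_survey):
        # removing every young respondent aliases the age columns
        df = outcome_survey[outcome_survey["age_group"] != "18-29"]
        with pytest.raises(ValueError, match="age_group\\[18-29\\]"):
            fit(df, default_model_specs(4)[0])


class TestCalibration:
    def test_beta_within_3se_most_of_the_time(self):
        # simulation-based check over 20 replicates at ~5,000 records
        spec = ModelSpec("m", TimeBasisSpec("linear", 2))
        hits, total = 0, 0
        for rep in range(20):
            cfg = synthetic.default_truth_config(
                3, 2, seed=1000 + rep, sigma_domain=0.2,
                sample_sizes=synthetic.SampleSizes(outcome=850),
            )
            truth = synthetic.build_truth(cfg)
            df = synthetic.generate_outcome_survey(cfg, truth)
            lf = design.center_labor_force(truth.labor_force)
            df = df.merge(
                lf[["domain", "wave", "lf_partic_c"]], on=["domain", "wave"]
            )
            df = rescale_weights(df)
            fitted = fit(df, spec)
            assert fitted.converged
            for name in fitted.beta.index:
                b_true = cfg.fixed_effects.get(name, 0.0)
                se = fitted.beta_se[name]
                total += 1
                hits += abs(fitted.beta[name] - b_true) <= 3 * se
        assert hits / total >= 0.95


class TestShrinkage:
    def test_domain_modes_shrunk_vs_empirical_offsets(self):
        # flat fixed effects so domain intercepts are the only signal
        cfg = synthetic.TruthConfig(
            5, 2, {"intercept": 0.0}, 0.5, {}, seed=8,
            sample_sizes=synthetic.SampleSizes(outcome=150),
        )
        truth = synthetic.build_truth(cfg)
        df = synthetic.generate_outcome_survey(cfg, truth)
        lf = design.center_labor_force(truth.labor_force)
        df = df.merge(lf[["domain", "wave", "lf_partic_c"]], on=["domain", "wave"])
        df = rescale_weights(df)
        fitted = fit(df, ModelSpec("m", TimeBasisSpec("linear", 2)))
        modes = fitted.random_effects["domain"]
        emp = logit(
            df.groupby("domain")["outcome"].mean().clip(1e-6, 1 - 1e-6)
        )
        emp_offsets = emp - emp.mean()
        assert modes.std() < emp_offsets.std()


def _constant_model(spec, domains, waves, intercept=0.0):
    grid = pd.DataFrame(
        {"domain": [domains[0]], "wave": [waves[0]], "sex": ["male"],
         "age_group": ["50+"], "race_eth": ["nh_white"], "ses": ["high"],
         "lf_partic_c": [0.0]}
    )
    _, names, _ = design.design_matrix(grid, spec)
    beta = pd.Series(0.0, index=names)
    beta["intercept"] = intercept
    return FittedModel(
        spec=spec,
        beta=beta,
        beta_se=pd.Series(np.nan, index=names),
        variance_components={t: 0.0 for t in spec.random_intercepts},
        random_effects={
            t: pd.Series(dtype=float) for t in spec.random_intercepts
        },
        loglik=0.0, aic=0.0, bic=0.0, converged=True, n_obs=0,
    )


def _lf_table(domains, waves):
    return pd.DataFrame(
        [
            {"domain": d, "wave": t, "lf_partic_c": 0.0}
            for d in domains
            for t in waves
        ]
    )


class TestPredictCells:
    def test_full_grid_size(self, model1_fit, labor_force):
        pred = predict_cells(model1_fit, labor_force)
        assert len(pred) == 72 * 3 * 4
        assert not pred.duplicated(["domain", "wave", *CELLS]).any()

    def test_zero_model_predicts_half(self):
        spec = ModelSpec("m", TimeBasisSpec("linear", 3))
        model = _constant_model(spec, [0, 1], [0, 1, 2])
        pred = predict_cells(model, _lf_table([0, 1], [0, 1, 2]))
        assert np.allclose(pred["pi_hat"], 0.5)

    def test_intercept_only_prediction(self):
        spec = ModelSpec("m", TimeBasisSpec("linear", 2))
        model = _constant_model(spec, [0, 1], [0, 1], intercept=float(logit(0.3)))
        pred = predict_cells(model, _lf_table([0, 1], [0, 1]))
        assert np.allclose(pred["pi_hat"], 0.3)

    def test_monotone_in_intercept(self):
        spec = ModelSpec("m", TimeBasisSpec("linear", 2))
        lf = _lf_table([0, 1], [0, 1])
        lo = predict_cells(_constant_model(spec, [0, 1], [0, 1], -0.5), lf)
        hi = predict_cells(_constant_model(spec, [0, 1], [0, 1], 0.5), lf)
        assert (hi["pi_hat"].to_numpy() > lo["pi_hat"].to_numpy()).all()

    def test_bounds_strict(self, predictions):
        assert (predictions["pi_hat"] > 0).all()
        assert (predictions["pi_hat"] < 1).all()

    def test_missing_labor_force_raises(self, model1_fit, labor_force):
        clipped = labor_force[
            ~((labor_force["domain"] == 0) & (labor_force["wave"] == 0))
        ]
        with pytest.raises(ValueError, match="domain=0 wave=0"):
            predict_cells(model1_fit, clipped, domains=[0, 1, 2], waves=[0, 1, 2, 3])


def _dummy_fit(aic, bic, converged=True, n_ri=1):
    spec = ModelSpec("m", TimeBasisSpec("linear", 2),
                     tuple(["domain", "wave"][:n_ri]))
    return FittedModel(
        spec=spec, beta=pd.Series(dtype=float), beta_se=pd.Series(dtype=float),
        variance_components={}, random_effects={}, loglik=0.0,
        aic=aic, bic=bic, converged=converged, n_obs=0,
    )


class TestSelectModel:
    def test_argmin_aic(self):
        fits = [_dummy_fit(100, 1), _dummy_fit(90, 2), _dummy_fit(95, 3)]
        assert select_model(fits) is fits[1]

    def test_bic_tiebreak(self):
        fits = [_dummy_fit(90, 50), _dummy_fit(90, 40)]
        assert select_model(fits) is fits[1]

    def test_single_fit(self):
        fits = [_dummy_fit(123, 5)]
        assert select_model(fits) is fits[0]

    def test_skips_nonconverged(self):
        fits = [_dummy_fit(10, 1, converged=False), _dummy_fit(90, 2)]
        assert select_model(fits) is fits[1]

    def test_no_converged_raises(self):
        with pytest.raises(RuntimeError, match="no converged"):
            select_model([_dummy_fit(1, 1, converged=False)])
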