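import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrprev import frame_builder, synthetic
from mrprev.frame_builder import (
    IPF_ORDER,
    apply_fallback,
    build_frame,
    composite,
    direct_estimates,
    model_estimates,
    rake,
    smoker_totals,
    survey_margins,
)

CELLS = ["sex", "age_group", "race_eth", "ses"]


def _survey(rows):
    base = {"domain": 0, "wave": 0, "sex": "male", "age_group": "50+",
            "race_eth": "nh_white", "ses": "high", "weight": 1.0, "smoker": 0}
    return pd.DataFrame([{**base, **r} for r in rows])


class TestDirectEstimates:
    def test_hand_case_equal_weights(self):
        df = _survey([{"smoker": int(i < 3)} for i in range(10)])
        de = direct_estimates(df)
        row = de[de["n_direct"] == 10].iloc[0]
        assert row["p_direct"] == pytest.approx(0.3)
        assert row["v_direct"] == pytest.approx(0.3 * 0.7 / 10)  # = 0.021

    def test_kish_limit_concentrated_weights(self):
        # nearly all weight on one respondent drives n_eff toward 1
        df = _survey(
            [{"smoker": 1, "weight": 1.0}]
            + [{"smoker": 0, "weight": 1e-9} for _ in range(9)]
        )
        de = direct_estimates(df)
        row = de[de["n_direct"] == 10].iloc[0]
        p = row["p_direct"]
        assert row["v_direct"] == pytest.approx(p * (1 - p) / 1.0, rel=1e-6)

    def test_empty_cell_marked(self):
        df = _survey([{"smoker": 1}])
        de = direct_estimates(df)
        empty = de[de["n_direct"] == 0]
        assert len(empty) == 71
        assert empty["p_direct"].isna().all()


class TestModelEstimates:
    def test_constant_probability_recovered(self):
        cfg = synthetic.TruthConfig(
            2, 2, {"intercept": 0.0}, 0.0,
            {"intercept": float(np.log(0.3 / 0.7))}, seed=4,
            sample_sizes=synthetic.SampleSizes(smoking=6000),
        )
        truth = synthetic.build_truth(cfg)
        sm = synthetic.generate_smoking_survey(cfg, truth)
        me = model_estimates(sm)
        assert me["p_model"].mean() == pytest.approx(0.3, abs=0.01)
        assert np.abs(me["p_model"] - 0.3).max() < 0.08  # saturated-model noise

    def test_consistency_at_large_n(self):
        cfg = synthetic.default_truth_config(
            2, 2, seed=6,
            sample_sizes=synthetic.SampleSizes(smoking=30000),
        )
        truth = synthetic.build_truth(cfg)
        sm = synthetic.generate_smoking_survey(cfg, truth)
        me = model_estimates(sm)
        merged = me.merge(truth.table, on=["domain", "wave", *CELLS])
        err = np.abs(merged["p_model"] - merged["p_smoke"])
        assert err.mean() < 0.01
        assert err.quantile(0.95) < 0.02

    def test_variances_positive(self, smoking_survey):
        me = model_estimates(smoking_survey)
        assert (me["v_model"] > 0).all()


class TestComposite:
    def test_equal_variances_average(self):
        a, theta = composite(0.2, 0.004, 0.4, 0.004)
        assert a == pytest.approx(0.5)
        assert theta == pytest.approx(0.3)

    def test_zero_direct_variance_gives_direct(self):
        a, theta = composite(0.2, 0.0, 0.4, 0.001)
        assert a == 1.0
        assert theta == pytest.approx(0.2)

    def test_hand_arithmetic(self):
        a, theta = composite(0.2, 0.003, 0.4, 0.001)
        assert a == pytest.approx(0.25, abs=1e-15)
        assert theta == pytest.approx(0.35, abs=1e-15)

    def test_both_zero_variances_error(self):
        with pytest.raises(ValueError, match="undefined"):
            composite(0.2, 0.0, 0.4, 0.0)

    @given(
        st.floats(0, 1), st.floats(1e-8, 1), st.floats(0.001, 0.999),
        st.floats(1e-8, 1),
    )
    @settings(max_examples=100, deadline=None)
    def test_blend_bounds(self, p_d, v_d, p_m, v_m):
        a, theta = composite(p_d, v_d, p_m, v_m)
        assert 0.0 <= a <= 1.0
        assert min(p_d, p_m) - 1e-12 <= theta <= max(p_d, p_m) + 1e-12

    def test_monotone_in_model_variance(self):
        a1, _ = composite(0.2, 0.003, 0.4, 0.001)
        a2, _ = composite(0.2, 0.003, 0.4, 0.002)
        assert a2 > a1


class TestApplyFallback:
    def test_small_cell_uses_model(self):
        assert apply_fallback(4, 0.5, 0.45, 0.3) == (0.3, "model")

    def test_zero_prevalence_uses_model(self):
        assert apply_fallback(50, 0.0, 0.1, 0.3) == (0.3, "model")

    def test_unit_prevalence_uses_model(self):
        assert apply_fallback(50, 1.0, 0.9, 0.3) == (0.3, "model")

    def test_fractional_count_uses_model(self):
        # 50 * 0.01 = 0.5 expected smokers < 1
        assert apply_fallback(50, 0.01, 0.02, 0.3) == (0.3, "model")

    def test_stable_cell_uses_composite(self):
        assert apply_fallback(50, 0.3, 0.28, 0.35) == (0.28, "composite")


class TestSmokerTotals:
    def test_multiplication(self, frame_and_margins, population):
        frame, _ = frame_and_margins
        totals = smoker_totals(frame, population)
        assert np.allclose(totals, frame["chosen_p"] * frame["population"])
        assert (totals >= 0).all()

    def test_missing_population_named(self, frame_and_margins, population):
        frame, _ = frame_and_margins
        with pytest.raises(ValueError, match="population missing"):
            smoker_totals(frame, population.iloc[1:])


def oracle_ipf(seed, row_m, col_m, iters=20):
    """Brute-force 2-d IPF for cross-checking."""
    t = np.asarray(seed, dtype=float).copy()
    for _ in range(iters):
        t *= (np.asarray(row_m) / t.sum(axis=1))[:, None]
        t *= np.asarray(col_m) / t.sum(axis=0)
    return t


class TestRake:
    def test_fixed_point(self):
        seed = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = rake(seed, [seed.sum(axis=1), seed.sum(axis=0)])
        assert np.allclose(out, seed)

    def test_2x2_matches_oracle(self):
        seed = np.array([[1.0, 2.0], [3.0, 4.0]])
        row_m, col_m = [3.0, 7.0], [4.0, 6.0]
        out = rake(seed, [row_m, col_m])
        assert np.allclose(out.sum(axis=1), row_m)
        assert np.allclose(out.sum(axis=0), col_m)
        assert np.max(np.abs(out - oracle_ipf(seed, row_m, col_m))) < 1e-6

    def test_total_conserved(self):
        seed = np.arange(1.0, 25.0).reshape(2, 3, 4)
        margins = [np.array([10.0, 14.0]), np.array([6.0, 8.0, 10.0]),
                   np.array([5.0, 6.0, 6.0, 7.0])]
        out = rake(seed, margins)
        assert out.sum() == pytest.approx(24.0)

    def test_zero_seed_mass_with_positive_margin(self):
        seed = np.array([[0.0, 0.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="zero seed mass"):
            rake(seed, [[3.0, 7.0], [4.0, 6.0]])

    def test_inconsistent_margins_raise(self):
        seed = np.array([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(RuntimeError, match="did not converge"):
            rake(seed, [[3.0, 7.0], [5.0, 7.0]])

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_margins_match_random_tables(self, seed_int):
        rng = np.random.default_rng(seed_int)
        seed = rng.uniform(0.1, 5.0, (2, 3, 4))
        target = rng.uniform(0.1, 5.0, (2, 3, 4))
        margins = [
            target.sum(axis=(1, 2)), target.sum(axis=(0, 2)),
            target.sum(axis=(0, 1)),
        ]
        out = rake(seed, margins)
        for k, m in enumerate(margins):
            axes = tuple(a for a in range(3) if a != k)
            assert np.allclose(out.sum(axis=axes), m, rtol=1e-6)


class TestBuildFrame:
    def test_margin_conservation(self, frame_and_margins):
        frame, margins = frame_and_margins
        for factor in IPF_ORDER:
            got = frame.groupby(["domain", "wave", factor])["N"].sum()
            want = margins[margins["factor"] == factor].set_index(
                ["domain", "wave", "level"]
            )["total"]
            rel = np.abs(got.values - want.reindex(got.index).values) / np.maximum(
                want.reindex(got.index).values, 1e-300
            )
            assert np.max(rel) < 1e-6

    def test_theta_between_estimates(self, frame_and_margins):
        frame, _ = frame_and_margins
        comp = frame.dropna(subset=["theta"])
        lo = np.minimum(comp["p_direct"], comp["p_model"])
        hi = np.maximum(comp["p_direct"], comp["p_model"])
        assert ((comp["theta"] >= lo - 1e-12) & (comp["theta"] <= hi + 1e-12)).all()
        assert comp["a"].between(0, 1).all()

    def test_frame_covers_full_grid(self, frame_and_margins):
        frame, _ = frame_and_margins
        assert len(frame) == 3 * 4 * 72
        assert frame["N"].ge(0).all()

    def test_margin_totals_consistent_across_factors(self, frame_and_margins):
        _, margins = frame_and_margins
        totals = margins.groupby(["domain", "wave", "factor"])["total"].sum()
        for (d, t), block in totals.groupby(level=[0, 1]):
            assert np.allclose(block, block.iloc[0])

    def test_raked_totals_track_truth(self, truth):
        # frame recovery: raked N correlates with true smoker counts
        cfg = synthetic.default_truth_config(
            3, 2, seed=77,
            sample_sizes=synthetic.SampleSizes(smoking=12000),
        )
        big_truth = synthetic.build_truth(cfg)
        sm = synthetic.generate_smoking_survey(cfg, big_truth)
        pop = big_truth.table[["domain", "wave", *CELLS, "population"]]
        frame, _ = build_frame(sm, pop)
        merged = frame.merge(big_truth.table, on=["domain", "wave", *CELLS])
        r = np.corrcoef(merged["N"], merged["n_true"])[0, 1]
        assert r > 0.95


class TestSurveyMargins:
    def test_long_format_complete(self, smoking_survey, population):
        margins = survey_margins(smoking_survey, population)
        assert len(margins) == 3 * 4 * (2 + 3 + 4 + 3)
        assert (margins["total"] >= 0).all()

    def test_missing_population_raises(self, smoking_survey, population):
        clipped = population[population["domain"] != 0]
        with pytest.raises(ValueError, match="domain=0"):
            survey_margins(smoking_survey, clipped)
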