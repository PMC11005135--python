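import numpy as np
import pandas as pd
import pytest

from mrprev import design, frame_builder, glmm, synthetic

CELL_COLS = ["sex", "age_group", "race_eth", "ses"]


@pytest.fixture(scope="session")
def small_cfg():
    return synthetic.default_truth_config(
        n_domains=3,
        n_waves=4,
        seed=42,
        sample_sizes=synthetic.SampleSizes(outcome=500, smoking=2000, gold=1500),
    )


@pytest.fixture(scope="session")
def truth(small_cfg):
    return synthetic.build_truth(small_cfg)


@pytest.fixture(scope="session")
def population(truth):
    return truth.table[["domain", "wave", *CELL_COLS, "population"]]


@pytest.fixture(scope="session")
def labor_force(truth):
    return design.center_labor_force(truth.labor_force)


@pytest.fixture(scope="session")
def outcome_survey(small_cfg, truth, labor_force):
    df = synthetic.generate_outcome_survey(small_cfg, truth)
    df = df.merge(
        labor_force[["domain", "wave", "lf_partic_c"]], on=["domain", "wave"]
    )
    return glmm.rescale_weights(df)


@pytest.fixture(scope="session")
def smoking_survey(small_cfg, truth):
    return synthetic.generate_smoking_survey(small_cfg, truth)


@pytest.fixture(scope="session")
def frame_and_margins(smoking_survey, population):
    return frame_builder.build_frame(smoking_survey, population)


@pytest.fixture(scope="session")
def model1_fit(outcome_survey):
    spec = design.default_model_specs(4)[0]
    fitted = glmm.fit(outcome_survey, spec)
    assert fitted.converged
    return fitted


@pytest.fixture(scope="session")
def predictions(model1_fit, labor_force):
    return glmm.predict_cells(model1_fit, labor_force)
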