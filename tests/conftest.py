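import warnings

import numpy as np
import pandas as pd
import pytest

import riskequity as req

warnings.filterwarnings("ignore", message="MCMC convergence")


def make_records(rows):
    """Birth-record DataFrame from (mother, order, bdate, died, ddate) tuples."""
    base = {
        "survey_id": "s1",
        "cluster_id": 0,
        "survey_date": 2015.0,
        "sex": "female",
        "maternal_age_at_birth": 25.0,
        "maternal_education": 6.0,
        "wealth_score": 1.0,
        "urban": "rural",
    }
    recs = []
    for i, (mother, order, bdate, died, ddate) in enumerate(rows):
        recs.append(
            dict(
                base,
                birth_id=i,
                mother_id=mother,
                birth_order=order,
                birth_date=bdate,
                died_u5=died,
                death_date=ddate,
                wealth_score=1.0 + mother,  # distinct households
            )
        )
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def gradient_data():
    """A moderately sized pro-poor-gradient survey plus its ground truth."""
    cfg = req.gradient_scenario(n_mothers=3000, seed=42)
    dataset, truth = req.generate_survey(cfg)
    table, _ = req.build_analysis_table(dataset.births)
    return cfg, dataset, truth, table


@pytest.fixture(scope="session")
def small_fit(gradient_data):
    """A quick main-effects model fit shared across model/metrics tests."""
    _, _, _, table = gradient_data
    model = req.BayesianRiskModel(
        max_interaction_order=1, chains=2, warmup=300, draws_total=400, seed=7
    ).fit(table)
    return model, table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
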