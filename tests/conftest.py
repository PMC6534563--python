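import numpy as np
import pandas as pd
import pytest

from battery_ontology.battery import DVMatrix
from battery_ontology.synthetic import (
    CategoryConfig,
    GeneratorConfig,
    OutcomeConfig,
    generate_battery,
    generate_covariates,
    generate_outcomes,
    generate_retest,
)


def small_config(seed=0, **kw):
    """A fast, well-structured battery: 3 task factors, 4 survey factors."""
    defaults = dict(
        n_participants=400,
        n_retest=120,
        task=CategoryConfig(n_dvs=18, n_factors=3,
                            reliability_mean=0.45, reliability_sd=0.21),
        survey=CategoryConfig(n_dvs=20, n_factors=4,
                              reliability_mean=0.80, reliability_sd=0.06),
        outcomes=OutcomeConfig(n_latent=3, target_r2=(0.25, 0.10, 0.0)),
        seed=seed,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_world():
    """Battery + retest + covariates + outcomes from one generator draw."""
    cfg = small_config(seed=11)
    battery, gt = generate_battery(cfg)
    pair = generate_retest(cfg, gt, battery)
    cov = generate_covariates(cfg, battery.participant_ids)
    outcomes, gt = generate_outcomes(gt, cfg, cov)
    return {"cfg": cfg, "battery": battery, "gt": gt, "retest": pair,
            "covariates": cov, "outcomes": outcomes}


@pytest.fixture
def tiny_dvm():
    data = pd.DataFrame(
        {"stroop_rt": [1.0, 2.0, 3.0, 4.0], "bis_total": [2.0, 1.0, 4.0, 3.0]},
        index=["p1", "p2", "p3", "p4"],
    )
    meta = pd.DataFrame(
        {"measure": ["stroop", "bis11"], "category": ["task", "survey"]},
        index=pd.Index(["stroop_rt", "bis_total"], name="dv_name"),
    )
    return DVMatrix(data, meta)
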