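import numpy as np
import pandas as pd
import pytest

from camcat import (
    OccupancyModelSpec,
    SimulationConfig,
    SurveyDesign,
    simulate_covariates,
    simulate_occupancy_data,
    standardize,
)


@pytest.fixture(scope="session")
def small_study():
    """An 80-site synthetic study (jungle-cat preset) with its truth."""
    cfg = SimulationConfig(n_sites=80, seed=11)
    rng = np.random.default_rng(cfg.seed)
    cov = simulate_covariates(cfg, rng)
    cov["othercat"] = cov["leopardcat"]
    history, truth = simulate_occupancy_data(cfg, cov, "junglecat", rng)
    spec = OccupancyModelSpec()
    names = sorted(set(spec.psi_covariates) | set(spec.p_covariates))
    design = standardize(cov, names)
    return {"config": cfg, "covariates": cov, "history": history,
            "truth": truth, "design": design, "spec": spec}


@pytest.fixture
def toy_records():
    """Three sites, 21-day deployment from 2023-01-01; five jungle-cat events
    at site B all inside occasion 2 (days 7-13)."""
    ts = [f"2023-01-{d:02d} {h:02d}:00" for d, h in
          [(9, 1), (9, 6), (10, 12), (12, 3), (13, 22)]]
    return pd.DataFrame({
        "site_id": ["B"] * 5,
        "species": ["junglecat"] * 5,
        "timestamp": pd.to_datetime(ts),
        "count": [1, 2, 1, 1, 3],
    })


@pytest.fixture
def toy_design():
    return SurveyDesign(n_sites=3, deployment_days=21, occasion_days=7)
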