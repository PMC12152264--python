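import numpy as np
import pandas as pd
import pytest

from respscore import synthetic_trial as st
from respscore import trial_io


@pytest.fixture(scope="session")
def grid_trial():
    """Small four-outcome trial with grid-aligned events and trajectories."""
    cfg = st.scenario("table2_like", n_patients=400, seed=3, snap_to_grid=True)
    dataset, truth = st.simulate_trial(cfg)
    visits = st.simulate_visit_trajectories(dataset.baselines, dataset.events, cfg)
    return cfg, dataset, truth, visits


@pytest.fixture(scope="session")
def xy_variable_set():
    """Abstract two-covariate set for the single-modifier scenarios."""
    return trial_io.VariableSet("XY", (("x1", "identity"), ("x2", "identity")))


def make_visits(rows, patient_id="P1"):
    """Visit frame from (day, score) pairs for one score column."""
    (col,) = {k for r in rows for k in r if k != "day"}
    return pd.DataFrame(
        [{"patient_id": patient_id, "day": r["day"], col: r[col]} for r in rows]
    )


@pytest.fixture
def baseline_frame():
    rng = np.random.default_rng(42)
    n = 60
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "arm": np.where(rng.random(n) < 2 / 3, "treatment", "control"),
            "age": rng.uniform(18, 60, n).round(1),
            "sex": np.where(rng.random(n) < 0.6, "female", "male"),
            "edss": rng.choice([3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5], n),
            "relapses_2y": rng.poisson(0.7, n),
            "disease_duration": rng.lognormal(2.5, 0.5, n).round(2),
        }
    )
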