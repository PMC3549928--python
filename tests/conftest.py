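"""Shared fixtures: small random model fixtures and session-scoped
Monte-Carlo replication runs reused by several tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gamar.model_core import Dataset, ModelSpec, ParameterVector, SmoothTerm, build_design
from gamar.simulator import (
    SyntheticSeriesConfig,
    cosine_study_truth,
    run_replications,
    spline_study_truth,
    synth_temperature,
)


def make_small_fixture(seed: int, n: int = 50, m: int = 3, p: int = 2):
    """A tiny random design + counts + parameters for oracle checks.

    Counts are genuine Poisson draws from a randomly parameterised model so
    y, X and theta are mutually consistent in scale.
    """
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(0, 1, size=(n, m - 1))])
    beta = rng.normal(0, 0.3, size=m)
    beta[0] = rng.uniform(1.0, 2.5)
    c = rng.uniform(-0.3, 0.3, size=p)
    y = rng.poisson(np.exp(np.clip(X @ beta, None, 6.0)))
    from gamar.model_core import DesignInfo

    design = DesignInfo(
        X=X,
        column_names=["(intercept)"] + [f"x{i}" for i in range(1, m)],
        column_map={"(intercept)": [0]},
        spline_specs={},
        offset=0,
    )
    theta = ParameterVector(beta, c)
    ystar = np.maximum(y.astype(float), 0.5)
    return design, theta, y.astype(float), ystar


@pytest.fixture(scope="session")
def spline_replicate():
    """One replicate of the spline-mean AR(3) process plus its covariate."""
    truth = spline_study_truth()
    x = synth_temperature(SyntheticSeriesConfig(n_days=truth.n_days, seed=11))
    from gamar.simulator import simulate_gamar

    return x, truth, simulate_gamar(x, truth, seed=12)


@pytest.fixture(scope="session")
def study1_run():
    """Simulation study 1: GAM and GAMAR(3) fitted to the same replicates.

    1000 replicates of 1461 days each, matching the scale the summary
    statistics are quoted at.
    """
    truth = spline_study_truth()
    specs = [
        ModelSpec([SmoothTerm("temp", 5)], ar_order=0),
        ModelSpec([SmoothTerm("temp", 5)], ar_order=3),
    ]
    gam, gamar3 = run_replications(truth, specs, n_reps=1000, base_seed=20260901)
    return truth, gam, gamar3


@pytest.fixture(scope="session")
def study2_run():
    """Simulation study 2: cosine truth fitted with an ns(x, 6) smoother."""
    truth = cosine_study_truth()
    specs = [
        ModelSpec([SmoothTerm("temp", 6)], ar_order=0),
        ModelSpec([SmoothTerm("temp", 6)], ar_order=3),
    ]
    gam, gamar3 = run_replications(truth, specs, n_reps=1000, base_seed=20260902)
    return truth, gam, gamar3
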