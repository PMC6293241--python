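"""Shared fixtures and independent oracles for the test suite."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pushmrt as pm
from pushmrt.emee import ModelMatrixSpec

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def medium_sim() -> pd.DataFrame:
    """One moderate simulated trial (150 users, full 89-day design)."""
    rng = np.random.default_rng(8)
    return pm.simulate_trial_dataset(
        pm.TrialConfig(), pm.CohortConfig(n_users=150), pm.OutcomeModelParams(), rng
    )


@pytest.fixture(scope="session")
def toy_intercept() -> pd.DataFrame:
    return pm.read_records(DATA_DIR / "toy_intercept.csv")


@pytest.fixture(scope="session")
def toy_moderated() -> pd.DataFrame:
    return pm.read_records(DATA_DIR / "toy_moderated.csv")


def brute_force_root(
    data: pd.DataFrame,
    moderator_terms: tuple[str, ...] = (),
    control_terms: tuple[str, ...] = (),
) -> np.ndarray:
    """Independent root of the estimating equation via plain-Python loops.

    Re-derives the estimating function from scratch (no shared code with
    the package's matrix implementation) and hands it to a generic
    numerical root finder.
    """
    from scipy.optimize import root

    rows = data[data["considered"] == 1]
    y = rows["outcome_24h"].tolist()
    a = rows["push"].tolist()
    p = rows["prob"].tolist()
    g_cols = [[1.0] * len(rows)] + [rows[t].tolist() for t in control_terms]
    f_cols = [[1.0] * len(rows)] + [rows[t].tolist() for t in moderator_terms]
    qa, qb = len(g_cols), len(f_cols)

    def U(theta):
        alpha, beta = theta[:qa], theta[qa:]
        out = [0.0] * (qa + qb)
        for i in range(len(y)):
            g = [col[i] for col in g_cols]
            f = [col[i] for col in f_cols]
            resid = (
                np.exp(-a[i] * sum(fj * bj for fj, bj in zip(f, beta))) * y[i]
                - np.exp(sum(gj * aj for gj, aj in zip(g, alpha)))
            )
            for j in range(qa):
                out[j] += g[j] * resid
            for j in range(qb):
                out[qa + j] += (a[i] - p[i]) * f[j] * resid
        return out

    x0 = np.zeros(qa + qb)
    x0[0] = np.log(max(np.mean([yi for yi, ai in zip(y, a) if ai == 0]), 1e-6))
    sol = root(U, x0, method="hybr", tol=1e-13)
    assert sol.success, sol.message
    return sol.x


@pytest.fixture(scope="session")
def oracle_root():
    return brute_force_root


def analysis_spec(moderator_terms=(), control_terms=()) -> ModelMatrixSpec:
    return ModelMatrixSpec(
        moderator_terms=tuple(moderator_terms), control_terms=tuple(control_terms)
    )
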