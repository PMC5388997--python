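"""Shared fixtures: the default synthetic cohort and the three fitted
models are expensive enough (leave-one-out refits in particular) to be
built once per session."""

import numpy as np
import pytest

import gaitlda as g
import gaitlda.models as gm

SEED = 1


@pytest.fixture(scope="session")
def default_obs():
    """Default synthetic cohort (seed 1), regularity-filtered."""
    return g.apply_regularity_filter(g.simulate_cohort(g.default_config(SEED)))


@pytest.fixture(scope="session")
def fitted1(default_obs):
    return gm.fit_model(default_obs, gm.model_spec(1))


@pytest.fixture(scope="session")
def fitted2(default_obs):
    return gm.fit_model(default_obs, gm.model_spec(2))


@pytest.fixture(scope="session")
def fitted3(default_obs):
    return gm.fit_model(default_obs, gm.model_spec(3))


@pytest.fixture(scope="session")
def report1(fitted1, default_obs):
    data, _ = gm.build_design(default_obs, fitted1.spec)
    return gm.run_report(fitted1, data, loo=True)


@pytest.fixture(scope="session")
def report2(fitted2, default_obs):
    data, _ = gm.build_design(default_obs, fitted2.spec)
    return gm.run_report(fitted2, data, loo=True)


@pytest.fixture(scope="session")
def report3(fitted3, default_obs):
    data, _ = gm.build_design(default_obs, fitted3.spec)
    return gm.run_report(fitted3, data, loo=True)


@pytest.fixture
def toy_two_group():
    """6-point 2-D two-group set with fixed integer coordinates; small
    enough that every quantity can be recomputed by hand/closed form."""
    X = np.array([[0, 0], [2, 1], [1, 2],
                  [5, 4], [6, 6], [7, 5]], dtype=float)
    y = np.array(["a", "a", "a", "b", "b", "b"])
    return g.LabeledMatrix(X, y, ["x1", "x2"])


def fisher_direction(X, y):
    """Closed-form two-group Fisher discriminant direction
    S_W^{-1} (mu_1 - mu_2): the independent oracle for canonical axes."""
    labels = np.unique(y)
    assert len(labels) == 2
    X1, X2 = X[y == labels[0]], X[y == labels[1]]
    S_W = np.zeros((X.shape[1], X.shape[1]))
    for part in (X1, X2):
        c = part - part.mean(axis=0)
        S_W += c.T @ c
    return np.linalg.solve(S_W, X1.mean(axis=0) - X2.mean(axis=0))
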