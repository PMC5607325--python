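"""Shared fixtures: toy constraint systems, site models and small ensembles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import ventlim as vl
from ventlim.compile import ConstraintSystem

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_system(E, f, G, h, n, labels=None) -> ConstraintSystem:
    """Assemble a small dense system with synthetic flow labels."""
    labels = labels or [f"s{i}->t{i}" for i in range(n)]
    E = np.asarray(E, dtype=float).reshape(-1, n) if np.size(E) else np.zeros((0, n))
    G = np.asarray(G, dtype=float).reshape(-1, n) if np.size(G) else np.zeros((0, n))
    return ConstraintSystem(
        E, f, G, h, labels,
        [f"eq{i}" for i in range(E.shape[0])],
        [f"ineq{i}" for i in range(G.shape[0])],
    )


def simplex_system(n=3) -> ConstraintSystem:
    """{sum x = 1, x >= 0}: the flat-Dirichlet test polytope."""
    return make_system([np.ones(n)], [1.0], np.eye(n), np.zeros(n), n)


def halfspace_system(n=3) -> ConstraintSystem:
    """{x >= 0, sum x <= 1}."""
    G = np.vstack([np.eye(n), -np.ones((1, n))])
    h = np.concatenate([np.zeros(n), [-1.0]])
    return make_system([], [], G, h, n)


@pytest.fixture(scope="session")
def fixtures_by_site() -> dict[str, vl.FoodWebModel]:
    return vl.bransfield_fixtures()


@pytest.fixture(scope="session")
def hr1_model(fixtures_by_site) -> vl.FoodWebModel:
    return fixtures_by_site["HR1"]


@pytest.fixture(scope="session")
def hr1_system(hr1_model) -> ConstraintSystem:
    return vl.compile(hr1_model)


@pytest.fixture(scope="session")
def hr1_ensemble(hr1_system) -> vl.FlowEnsemble:
    return vl.sample_polytope(hr1_system, 5000, seed=11)


@pytest.fixture(scope="session")
def vent_dataset() -> vl.SiteDataset:
    return vl.generate_site("low_activity_vent", seed=42)
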