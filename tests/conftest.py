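"""Shared fixtures: small meshes/graphs and the expensive trained cohort.

The session-scoped ``trained_study`` fixture runs the full synthetic
individualization experiment once (generate, fingerprint, mask, train,
parcellate, evaluate) and is shared by every test that needs trained
outputs; ``behavior_study`` does the same for the behavior-prediction
experiment.
"""

from __future__ import annotations

import numpy as np
import pytest

import msgcn
from msgcn import (
    SyntheticCohortConfig,
    TrainingConfig,
    build_adjacency,
    make_mesh,
    normalized_laplacian,
    scale_laplacian,
)


@pytest.fixture(scope="session")
def ico0():
    """Icosahedron mesh: 12 vertices, 20 triangles, all cortical."""
    return make_mesh(0)


@pytest.fixture(scope="session")
def ico2_graph():
    """Subdivision-2 icosphere graph (162 vertices) with scaled Laplacian."""
    mesh = make_mesh(2)
    graph = build_adjacency(mesh)
    lap = normalized_laplacian(graph)
    w = np.linalg.eigvalsh(lap.L.toarray())
    scale_laplacian(lap, lambda_max=float(w[-1]))
    return mesh, graph, lap


@pytest.fixture(scope="session")
def tiny_cohort():
    """Fast cohort for unit tests: 162 vertices, 8 parcels, 6 subjects."""
    config = SyntheticCohortConfig(
        mesh_subdivisions=2, n_parcels=8, n_subjects=6,
        n_timepoints=200, seed=42,
    )
    return msgcn.make_cohort(config)


@pytest.fixture(scope="session")
def trained_study():
    """Full-scale synthetic individualization experiment, run once.

    Cohort: subdivision-4 icosphere (2,562 vertices), 50 parcels, 30
    subjects (16 train / 4 validation / 10 held out), 2 sessions of 400
    timepoints; training follows the standard protocol (100 epochs, batch of
    one subject-session, early stopping after 10 stale epochs, weight decay
    5e-4, dropout 0.5).
    """
    config = SyntheticCohortConfig(seed=7, n_subjects=30)
    training = TrainingConfig(epochs=100, patience=10, seed=0)
    return msgcn.run_individualization_study(
        config=config, n_train=16, n_val=4, n_test=10, training=training
    )


@pytest.fixture(scope="session")
def behavior_study():
    """Noise-free topography-linked behavior experiment on 60 subjects."""
    return msgcn.run_behavior_study(
        n_subjects=60,
        n_train=40,
        config=SyntheticCohortConfig(seed=11, behavior_noise=0.0),
        seed=0,
    )
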