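"""Shared fixtures.

The planted-effect recovery cohort (40 participants, 30 ROIs, 4 runs) is
expensive to build and train on, so it is generated once per session and
shared by the connectivity, interpretation and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import xmiconnect as xc

# Planted-cohort study conditions for parameter-recovery testing: a scaled
# cohort with strong label-dependent coupling (0.8 vs 0.3 mixing), 12
# label-independent background connections, and near-orthogonal labels.
RECOVERY_SPEC = dict(
    n_participants=40,
    n_controls=15,
    n_runs=4,
    n_rois=30,
    n_timepoints=154,
    n_background_pairs=12,
    coupling_strong=0.8,
    coupling_weak=0.3,
    seed=11,
)


@pytest.fixture(scope="session")
def recovery_cohort():
    spec = xc.CohortSpec(**RECOVERY_SPEC)
    series, labels, truth = xc.generate_cohort(spec)
    return spec, series, labels, truth


@pytest.fixture(scope="session")
def recovery_dataset(recovery_cohort):
    _, series, labels, _ = recovery_cohort
    clean = [xc.preprocess_series(ts) for ts in series]
    matrices = [xc.correlation_matrix(ts) for ts in clean]
    cois = xc.select_cois(matrices)
    return xc.build_connectivity_dataset(clean, cois, labels, preprocessed=True)


@pytest.fixture(scope="session")
def recovery_experiment(recovery_dataset):
    return xc.run_experiment(recovery_dataset, n_batches=6, k=5, seed=29)


@pytest.fixture(scope="session")
def recovery_weight_table(recovery_experiment, recovery_dataset):
    per_model = [xc.summed_path_weights(m) for m in recovery_experiment.models]
    return xc.normalize_path_weights(
        per_model, feature_names=recovery_dataset.feature_names
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort for fast structural tests."""
    spec = xc.CohortSpec(
        n_participants=12,
        n_controls=5,
        n_runs=2,
        n_rois=22,
        n_timepoints=64,
        planted_clinical_pairs=((0, 1), (2, 3)),
        planted_igt_pairs=((2, 3), (4, 5)),
        n_background_pairs=3,
        seed=5,
    )
    series, labels, truth = xc.generate_cohort(spec)
    return spec, series, labels, truth


def make_dataset(
    n_participants: int = 20,
    n_runs: int = 2,
    n_features: int = 6,
    informative: bool = True,
    seed: int = 0,
) -> xc.ConnectivityDataset:
    """Synthetic ConnectivityDataset straight from arrays (no time series):
    feature 0/1 separate diagnosis, feature 2/3 separate IGT class when
    ``informative``; remaining features are noise."""
    rng = np.random.default_rng(seed)
    diagnosis = np.repeat(rng.permutation([0, 1] * (n_participants // 2)), n_runs)
    igt = np.repeat(rng.permutation([0, 1] * (n_participants // 2)), n_runs)
    n = n_participants * n_runs
    X = rng.normal(0, 1, size=(n, n_features))
    if informative:
        X[:, 0] += 3.0 * diagnosis
        X[:, 1] -= 3.0 * diagnosis
        X[:, 2] += 3.0 * igt
        X[:, 3] -= 3.0 * igt
    tags = pd.DataFrame(
        {
            "participant_id": np.repeat(
                [f"P{i:03d}" for i in range(1, n_participants + 1)], n_runs
            ),
            "run_id": np.tile(np.arange(n_runs), n_participants),
            "diagnosis": diagnosis,
            "igt_class": igt,
        }
    )
    pairs = [(i, i + 100) for i in range(n_features)]
    return xc.ConnectivityDataset(X, pairs, tags)


@pytest.fixture
def toy_dataset():
    return make_dataset()
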