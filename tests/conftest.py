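"""Shared fixtures: a small simulated dataset (cheap) and the favorable-regime
replicate set reused by several validation tests (expensive, session-scoped)."""

import pytest

from introscan import DemographicModel, Scenario, simulate_dataset
from introscan import validation


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny sweep dataset for fast structural tests (not for accuracy)."""
    dem = DemographicModel(Ne=1000, m=0.2, t=80)
    table, truth = simulate_dataset(
        dem, Scenario.single_sweep(pos_M=0.5, s=0.1), n_diploids=8, n_sites=300,
        seed=1234,
    )
    return table, truth, dem


@pytest.fixture(scope="session")
def favorable_replicates():
    """Ten seeded replicates of the favorable validation regime (m=0.1,
    s=0.05, t=200, 25 diploids at Poisson depth 2), shared by the
    parameter-recovery, misspecification and pooled-mode tests."""
    return validation.favorable_datasets(n_replicates=10, seed=12345)
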