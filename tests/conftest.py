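import warnings

import numpy as np
import pytest

from microcog import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def baseline(default_cohort):
    """Baseline tables, metadata rows and group labels of the shared cohort."""
    meta = default_cohort.metadata.samples_at("bsl")
    return {
        "species": default_cohort.species["bsl"],
        "metabolites": default_cohort.metabolites["bsl"],
        "meta": meta,
        "groups": meta["npz6_group"].to_numpy(),
        "truth": default_cohort.truth,
    }


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Rare all-zero species trigger expected zero-variance warnings."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=r"\d+ zero-variance feature", category=UserWarning
        )
        warnings.filterwarnings(
            "ignore", message="PC1 explains only", category=UserWarning
        )
        yield


def rng_seeds(n, base=1000):
    return [base + i for i in range(n)]
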