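import numpy as np
import pytest

import nirage as ng

MASTER_SEED = 0


@pytest.fixture(scope="session")
def sim_dataset():
    """Default-conditions simulated dataset, trimmed to the analysis window."""
    spectra, meta = ng.simulate(ng.default_config(seed=1))
    return ng.trim_window(spectra, 700, 2350), meta


@pytest.fixture(scope="session")
def lab_subset(sim_dataset):
    spectra, meta = sim_dataset
    ids = meta.df.loc[meta.df.cohort == "lab", "sample_id"].tolist()
    sub = spectra.subset(ids)
    aligned = meta.subset(ids).aligned_to(ids)
    return sub, aligned["age_days"].to_numpy(), aligned["group"].to_numpy()


@pytest.fixture(scope="session")
def field_subset(sim_dataset):
    spectra, meta = sim_dataset
    ids = meta.df.loc[meta.df.cohort == "field", "sample_id"].tolist()
    sub = spectra.subset(ids)
    aligned = meta.subset(ids).aligned_to(ids)
    return sub, aligned["age_days"].to_numpy(), aligned["group"].to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)
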