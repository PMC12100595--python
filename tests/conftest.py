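import numpy as np
import pytest

from radpop import models
from radpop.coalescent import LocusConfig, SampleConfig, simulate_dataset


@pytest.fixture(scope="session")
def constant_one_deme():
    """Single constant-size deme (haploid N = 10,000)."""
    return models.DemographicModel(
        "constant", 1,
        [models.DemographicEvent("deme_size_change", 0.0,
                                 {"deme": 0, "size": 10_000.0})])


def one_deme_model(N: float) -> models.DemographicModel:
    return models.DemographicModel(
        "one-deme", 1,
        [models.DemographicEvent("deme_size_change", 0.0,
                                 {"deme": 0, "size": float(N)})])


@pytest.fixture(scope="session")
def split_dataset():
    """Small two-deme dataset under M1 with a deep split (clear structure)."""
    m1 = models.get_model("M1")
    params = models.ModelParameters({
        "N_NA_cur": 2e5, "N_PAL_cur": 2e5, "N_anc": 2e5, "T_split": 8e5})
    ds = simulate_dataset(m1, params, SampleConfig((12, 12)),
                          LocusConfig(n_loci=300, locus_length=312), seed=42)
    return ds


@pytest.fixture(scope="session")
def m4_small_dataset():
    """Reference-history dataset at reduced locus count for cheap tests."""
    ds = simulate_dataset(models.get_model("M4"),
                          models.reference_m4_parameters(),
                          SampleConfig((38, 64)),
                          LocusConfig(n_loci=400), seed=7)
    return ds
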