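import numpy as np
import pytest

from emergehurdle.hurdle import SamplerConfig, fit
from emergehurdle.synthetic import GroupHyper, StudyDesign, simulate_dataset
from emergehurdle.trial_data import Dataset, Group, Sex, TrialRecord


def small_scenario() -> tuple[dict[Group, GroupHyper], StudyDesign]:
    """A down-scaled two-group scenario for fast fitting in unit tests."""
    hypers = {
        Group.VIRUS_FREE: GroupHyper(
            mu_a=-1.5, sigma_a=1.0, mu_b=0.0, sigma_b=0.3,
            mu_c=150.0, sigma_c=60.0, mu_d=-8.0, sigma_d=5.0,
        ),
        Group.INFECTED: GroupHyper(
            mu_a=0.8, sigma_a=0.6, mu_b=0.0, sigma_b=0.3,
            mu_c=280.0, sigma_c=60.0, mu_d=3.0, sigma_d=15.0,
        ),
    }
    design = StudyDesign(
        n_per_group_sex={
            (Group.VIRUS_FREE, Sex.MALE): 7,
            (Group.VIRUS_FREE, Sex.FEMALE): 6,
            (Group.INFECTED, Sex.MALE): 6,
            (Group.INFECTED, Sex.FEMALE): 5,
        },
        trials_per_individual=6,
        residual_sd=50.0,
    )
    return hypers, design


@pytest.fixture(scope="session")
def small_dataset() -> Dataset:
    hypers, design = small_scenario()
    ds, _ = simulate_dataset(hypers, design, seed=11)
    return ds


@pytest.fixture(scope="session")
def small_posterior(small_dataset):
    """One short fit shared across tests that need a real posterior."""
    cfg = SamplerConfig(chains=2, warmup=300, iterations=500, seed=7, force=True)
    return fit(small_dataset, cfg)


@pytest.fixture
def six_record_dataset() -> Dataset:
    records = [
        TrialRecord("i1", Group.VIRUS_FREE, Sex.MALE, 1, False, None),
        TrialRecord("i1", Group.VIRUS_FREE, Sex.MALE, 2, False, None),
        TrialRecord("i1", Group.VIRUS_FREE, Sex.MALE, 3, True, 200.0),
        TrialRecord("i2", Group.VIRUS_FREE, Sex.FEMALE, 1, True, 150.0),
        TrialRecord("i2", Group.VIRUS_FREE, Sex.FEMALE, 2, True, 180.0),
        TrialRecord("i2", Group.VIRUS_FREE, Sex.FEMALE, 3, True, 120.0),
    ]
    return Dataset(records)
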