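import pytest
from hypothesis import settings

from monopheno import (CohortConfig, generate_donor, default_gate_config,
                       run_gating)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def small_cohort_config(seed: int = 7, **kwargs) -> CohortConfig:
    """Desk-scale cohort used by most tests."""
    defaults = dict(events_per_donor=20_000, isotype_events=4_000, seed=seed)
    defaults.update(kwargs)
    return CohortConfig(**defaults)


def fixed_fraction_config(seed: int = 7, **kwargs) -> CohortConfig:
    """Cohort with zero between-donor spread: every configured fraction is
    realized exactly (up to multinomial sampling)."""
    cfg = small_cohort_config(seed=seed, **kwargs)
    for table in (cfg.cluster_fractions, cfg.small_fractions, cfg.large_fractions):
        for key in table:
            table[key][1] = 0.0
    cfg.scatter_other_sd = 0.0
    cfg.sm_smear_sd = 0.0
    cfg.la_remainder_sd = 0.0
    return cfg


@pytest.fixture(scope="session")
def small_config():
    return small_cohort_config()


@pytest.fixture(scope="session")
def donor_sample(small_config):
    # donor 2: component profile "a", carries the sm14dim16neg subpopulation
    return generate_donor(small_config, 2, sets=[3])


@pytest.fixture(scope="session")
def gate_result(donor_sample):
    return run_gating(donor_sample.stained[3], donor_sample.isotype[3],
                      default_gate_config())
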