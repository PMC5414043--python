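"""Shared fixtures: simulated cohorts reused across test modules.

The recovery experiment (three replicate cohorts at the documented default
study conditions, base seed 100) is expensive, so it is built once per
session and shared between the unit-level and acceptance-level tests.
"""
import numpy as np
import pytest

import recombimorph as rm
from recombimorph.simulate import run_cohort

BASE_SEED = 100
N_REPLICATES = 3


@pytest.fixture(scope="session")
def genome():
    return rm.default_genome()


@pytest.fixture(scope="session")
def recovery_replicates():
    """Three replicate cohorts at the default study conditions (20 Mb genome,
    2,000 meioses per sex, desk MCMC schedule)."""
    return [
        run_cohort(BASE_SEED + 1 + r, BASE_SEED + 101 + r, BASE_SEED + 201 + 2 * r)
        for r in range(N_REPLICATES)
    ]


@pytest.fixture(scope="session")
def cohort(recovery_replicates):
    """One simulated cohort (the first replicate) for unit-level checks."""
    return recovery_replicates[0]


@pytest.fixture(scope="session")
def null_cohort():
    """Equal-rate cohort: identical female and male truth maps (shared
    hotspots with perfectly correlated magnitudes, equal backgrounds)."""
    spec = rm.HotspotSpec(shared_fraction=1.0, sex_specific_fraction=0.0,
                          magnitude_correlation=1.0)
    return run_cohort(300, 301, 302, spec=spec, female_male_ratio=1.0,
                      female_background_cm_per_mb=0.1,
                      male_background_cm_per_mb=0.1, telomere_amplitude=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
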