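import dataclasses

import pytest

import riskamb as ra


@pytest.fixture(scope="session")
def behavioral_design():
    return ra.build_behavioral_design(1)


@pytest.fixture(scope="session")
def fmri_design():
    return ra.build_fmri_design(7)


@pytest.fixture(scope="session")
def fitted_cohort():
    """A 50-participant synthetic cohort with per-participant attitude fits.

    Session-scoped: the fits take tens of seconds and several tests only
    read from the result.
    """
    config = dataclasses.replace(ra.CohortConfig(), n_participants=50, seed=1)
    cohort = ra.simulate_cohort(config)
    fits = [
        ra.fit_attitudes(cohort.behavioral_design, p.behavioral_choices["choice"])
        for p in cohort.participants
    ]
    fits = ra.apply_exclusions(fits)
    return cohort, fits
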