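"""Shared fixtures: one small synthetic cohort reused across test modules."""

import pytest

import paindelta as pdl


@pytest.fixture(scope="session")
def small_cohort():
    """(records, truth) for a default-calibrated cohort of 6,000 residents."""
    cfg = pdl.default_config(n_residents=6000, seed=42)
    return pdl.generate_cohort(cfg)


@pytest.fixture(scope="session")
def prepared(small_cohort):
    """(prepared records, exclusion tally, truth) for the shared cohort."""
    records, truth = small_cohort
    rec, tally = pdl.prepare_cohort(records)
    return rec, tally, truth
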