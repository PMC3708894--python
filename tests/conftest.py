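import logging

import pytest

from dmnrest import pipeline, synth

logging.getLogger("dmnrest").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def space1():
    """One vertex per ROI, exactly on the canonical centroids."""
    return synth.make_source_space(1, seed=0)


@pytest.fixture(scope="session")
def lf1(space1):
    return synth.make_lead_field(space1)


@pytest.fixture(scope="session")
def space2():
    return synth.make_source_space(2, seed=0)


@pytest.fixture(scope="session")
def lf2(space2):
    return synth.make_lead_field(space2)


@pytest.fixture(scope="session")
def small_cohort(space2, lf2):
    """4 + 4 subjects with the default AD-like / MCI-like profiles."""
    spec_ad = synth.ad_like_spec(n_subjects=4, duration_s=64.0)
    spec_mci = synth.mci_like_spec(n_subjects=4, duration_s=64.0)
    return synth.make_cohort(spec_ad, spec_mci, space2, lf2)


@pytest.fixture(scope="session")
def no_ica_config():
    cfg = pipeline.RunConfig()
    cfg.preprocess.ica = False
    return cfg


@pytest.fixture(scope="session")
def small_result(small_cohort, space2, lf2, no_ica_config):
    return pipeline.analyze_cohort(small_cohort, space2, lf2, no_ica_config)
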