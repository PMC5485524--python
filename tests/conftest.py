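import pytest

from lambhap import assoc, phasing, synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort: 17 sires x 70 lambs, seed 1."""
    return synthetic.generate_cohort(synthetic.SimConfig(seed=1))


@pytest.fixture(scope="session")
def phased_default(default_cohort):
    return phasing.phase_cohort(default_cohort.records)


@pytest.fixture(scope="session")
def default_dataset(default_cohort, phased_default):
    return assoc.build_dataset(default_cohort.records, phased_default)


@pytest.fixture(scope="session")
def truth_dataset(default_cohort):
    """Modelling frame using the generator's latent diplotypes directly."""
    truth = {a: t.diplotype for a, t in default_cohort.truth.items()}
    return assoc.build_dataset(default_cohort.records, truth)
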