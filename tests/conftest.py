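import pytest

from amiclade import seqio, simulate, thermo


@pytest.fixture(scope="session")
def model():
    return thermo.load_model()


@pytest.fixture()
def config():
    return seqio.DesignConfig()


@pytest.fixture(scope="session")
def small_family():
    """A 4-gene family with low divergence: shared 21-mers abound."""
    spec = simulate.FamilySimSpec(
        n_genes=4, cds_length=201, per_branch_sub_prob=0.02,
        seed=7, family_id="FAM1", class_label="ABC",
    )
    return simulate.simulate_family(spec)


def pytest_configure(config):
    # derandomise hypothesis so runs are reproducible
    try:
        from hypothesis import settings

        settings.register_profile("ci", derandomize=True, max_examples=50)
        settings.load_profile("ci")
    except ImportError:
        pass
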