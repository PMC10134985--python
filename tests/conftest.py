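import pytest

from mixstock import (
    MSAConfig,
    build_mixture,
    filter_orphans,
    load_packaged_grouping,
    load_packaged_table,
    pool_rookeries,
    run_msa,
)


@pytest.fixture(scope="session")
def table():
    return load_packaged_table()


@pytest.fixture(scope="session")
def grouping():
    return load_packaged_grouping()


@pytest.fixture(scope="session")
def baseline(table, grouping):
    return pool_rookeries(table, grouping)


@pytest.fixture(scope="session")
def swao_mixture(table, baseline):
    """The pooled UR+BA+SBR foraging mixture with orphans removed (n = 182)."""
    return filter_orphans(build_mixture(table, ["UR", "BA", "SBR"]), baseline)


@pytest.fixture(scope="session")
def default_posterior(swao_mixture, baseline):
    """Flat-prior MSA at the default configuration (7 x 15,000, burn 10,000).

    Session-scoped: the run takes a few seconds and several tests inspect it.
    """
    return run_msa(swao_mixture, baseline, MSAConfig(prior_mode="flat", rng_seed=20230408))
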