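import numpy as np
import pytest

from eltrack import ddcs, fixtures, transport, xs


@pytest.fixture(scope="session")
def recommended_set():
    return fixtures.load_fixture_set("1m5ni_recommended")


@pytest.fixture(scope="session")
def tcs_set():
    return fixtures.load_fixture_set("1m5ni_tcs_reference")


@pytest.fixture(scope="session")
def anion_branching():
    return fixtures.load_anion_branching()


@pytest.fixture(scope="session")
def cation_table():
    return fixtures.load_cation_intensities()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_models(recommended_set):
    """Transport model bundle with the synthetic screened-Coulomb DCS."""
    elastic = recommended_set[xs.Channel.ELASTIC]
    dcs = fixtures.make_toy_dcs(lambda e: xs.interpolate(elastic, e))
    return transport.TransportModels(
        elastic_dcs=dcs,
        ddcs=ddcs.DDCSModel(elastic_dcs=dcs),
        anion_branching=fixtures.load_anion_branching(),
        cation_intensities=fixtures.load_cation_intensities(),
        elastic_dcs_is_fallback=True,
    )
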