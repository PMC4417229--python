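"""Shared fixtures; the long simulations are session-scoped and reused."""

import pytest

import purkinje2c as pk


@pytest.fixture(scope="session")
def default_trace():
    """120 s of the unperturbed model (1-ms sampling)."""
    return pk.simulate(pk.SimConfig(duration_ms=120000.0, stride=40))


@pytest.fixture(scope="session")
def alcohol_trace():
    """Pump-block protocol on the K_Na = 12 mM background, 100 s."""
    params = pk.set_kna(pk.ModelParams(), 12.0)
    cfg = pk.SimConfig(
        params=params, duration_ms=100000.0, stride=40,
        protocol=pk.AlcoholProtocol(),
    )
    return pk.simulate(cfg)


@pytest.fixture(scope="session")
def kna12_trace():
    params = pk.set_kna(pk.ModelParams(), 12.0)
    return pk.simulate(pk.SimConfig(params=params, duration_ms=30000.0, stride=40))


@pytest.fixture(scope="session")
def bk_knockout_trace():
    params = pk.bk_knockout(pk.ModelParams())
    return pk.simulate(pk.SimConfig(params=params, duration_ms=25000.0, stride=40))


@pytest.fixture(scope="session")
def erg_rescue_trace():
    params = pk.add_erg(pk.bk_knockout(pk.ModelParams()))
    return pk.simulate(pk.SimConfig(params=params, duration_ms=25000.0, stride=40))
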