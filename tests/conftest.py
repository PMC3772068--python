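import pytest

from optochr2.params import ChR2Params, scale_to_temperature
from optochr2.protocols import LightProtocol, SolverSettings, run_voltage_clamp


@pytest.fixture(scope="session")
def params():
    return ChR2Params()


@pytest.fixture(scope="session")
def params37(params):
    return scale_to_temperature(params, 37.0)


@pytest.fixture(scope="session")
def fast_solver():
    """Looser tolerances for tests where integration accuracy is not the point."""
    return SolverSettings(rtol=1e-8, atol=1e-8)


@pytest.fixture(scope="session")
def pulse_trace():
    """Session-cached 500 ms pulse traces keyed by (v, irradiance)."""
    cache = {}

    def get(v=-80.0, irr=5.5, params=None, **kwargs):
        key = (v, irr, tuple(sorted(kwargs.items())), id(params))
        if key not in cache:
            cache[key] = run_voltage_clamp(
                v, LightProtocol.single_pulse(10.0, 500.0, irr),
                params or ChR2Params(), **kwargs)
        return cache[key]

    return get
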