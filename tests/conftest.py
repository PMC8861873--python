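import pytest

from lbpcea import (
    DTC,
    TAU,
    REPRODUCTION_PROFILE,
    base_parameters,
    run_strategy,
)


@pytest.fixture(scope="session")
def params():
    return base_parameters()


@pytest.fixture(scope="session")
def dtc_totals(params):
    return run_strategy(params, DTC, conventions=REPRODUCTION_PROFILE)


@pytest.fixture(scope="session")
def tau_totals(params):
    return run_strategy(params, TAU, conventions=REPRODUCTION_PROFILE)
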