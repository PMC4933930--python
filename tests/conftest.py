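import pytest

from niptcca import ScreeningParams, Strategy, get_preset


@pytest.fixture(scope="session")
def national() -> ScreeningParams:
    return get_preset("national")


@pytest.fixture(scope="session")
def rapid() -> ScreeningParams:
    return get_preset("rapid")


@pytest.fixture(scope="session")
def s150() -> Strategy:
    return Strategy("contingent", 150)


@pytest.fixture(scope="session")
def s150_nodirect() -> Strategy:
    return Strategy("contingent", 150, direct_ipd_allowed=False)


@pytest.fixture(scope="session")
def current() -> Strategy:
    return Strategy("current")


def approx_printed(actual: float, printed: float) -> bool:
    """Published-value tolerance: +/-1% relative, at least +/-1 unit."""
    return abs(actual - printed) <= max(1.0, 0.01 * abs(printed))
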