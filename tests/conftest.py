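import pytest

from nlmedrc import FourPL, ScenarioSpec, fit_nlme_pooled, simulate_screen


@pytest.fixture(scope="session")
def null_screen_50():
    """One null screen: 50 triplicate lines, shared generating curve."""
    return simulate_screen(ScenarioSpec(n_lines=50, seed=20))


@pytest.fixture(scope="session")
def null_fit_50(null_screen_50):
    fit = fit_nlme_pooled(null_screen_50.screen, "drug1")
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def shifted_screen_20():
    """Small alternative screen with a 0.5 log10-unit x-mid shift in group 2."""
    spec = ScenarioSpec(n_lines=20, group2=FourPL(100.0, 10.0, 0.0, -0.5), seed=21)
    return simulate_screen(spec)
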