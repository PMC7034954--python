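import pytest

from dendroclock import IntegratorConfig, ModelParameters


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Shipped default parameter set."""
    return ModelParameters()


@pytest.fixture(scope="session")
def coarse_cfg() -> IntegratorConfig:
    """Coarse-step config for cheap behavioural tests (250 µs, 1 ms recording)."""
    return IntegratorConfig(dt=2.5e-4, record_stride=4)


@pytest.fixture(scope="session")
def cfg100() -> IntegratorConfig:
    """100 µs config used for the ISI sweep (per the published step-size margin)."""
    return IntegratorConfig(dt=1e-4, record_stride=10)


@pytest.fixture(scope="session")
def prod_cfg() -> IntegratorConfig:
    """The production 25 µs backward-Euler configuration."""
    return IntegratorConfig(dt=25e-6, record_stride=40)


#: the ISI grid used for learning-curve checks (seconds)
ISI_GRID = (0.15, 0.3, 0.5, 0.75, 1.0)


@pytest.fixture(scope="session")
def sweep_table(params, cfg100):
    """Pairings-to-learn table over the standard ISI grid (shared: the sweep
    is the most expensive computation in the suite)."""
    from dendroclock import isi_sweep

    return isi_sweep(list(ISI_GRID), params, cfg100, max_pairings=70)
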