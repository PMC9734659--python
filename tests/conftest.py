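import pytest

from chimertrack import MarkerAssay, Panel, SimulationParams, default_panel


@pytest.fixture(scope="session")
def panel() -> Panel:
    return default_panel()


@pytest.fixture()
def small_panel() -> Panel:
    return Panel(
        assays=(
            MarkerAssay(id="KMR019", allele_freq=0.25, cq_window=(15.0, 38.0)),
            MarkerAssay(id="KMR028", allele_freq=0.25, cq_window=(15.0, 38.0)),
        ),
        reference_id="REF901",
    )


@pytest.fixture()
def default_params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture()
def noise_free_params() -> SimulationParams:
    """Deterministic copies, no Cq jitter, no thinning: closed forms hold."""
    return SimulationParams(cq_noise_sd=0.0, p_det=1.0, deterministic=True)
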