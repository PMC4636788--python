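import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_landscape():
    """One default 3-condition landscape, shared across tests."""
    from sepipe import SimulationConfig, simulate_landscape

    cfg = SimulationConfig(n_ce=300, n_coding=120, n_lncrna=40, n_mirna=15)
    return simulate_landscape(cfg, seed=11)


@pytest.fixture(scope="session")
def called_landscape(small_landscape):
    """The small landscape with SEs called in every condition."""
    from sepipe import TSSIndex, call_superenhancers

    land = small_landscape
    tss = TSSIndex(land.coding_tss())
    rankings = {
        cond: call_superenhancers(
            land.peaks[cond], tss, land.signals[cond], land.control
        )
        for cond in land.conditions
    }
    return land, rankings
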