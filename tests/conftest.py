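import numpy as np
import pytest

from photoswitch_sim.model import RateTable, SystemSpec, build_single_model
from photoswitch_sim.presets import cy5_rate_table


def toy_rates(**kw) -> RateTable:
    """A rate table with every channel silent unless overridden."""
    base = dict(
        kEXC=0.0, kFLU=0.0, kIC=0.0, kISC_S1T1=0.0, kISC_T1S0=0.0,
        kISO=0.0, kBISO=0.0, kBLE=0.0, kPET_S=0.0, kPET_T=0.0,
        kTE=0.0, kPU=0.0, kOXI=0.0,
    )
    base.update(kw)
    return RateTable(**base)


@pytest.fixture(scope="session")
def cy5_rates() -> RateTable:
    return cy5_rate_table()


@pytest.fixture(scope="session")
def cy5_model(cy5_rates):
    """Single Cy5, photobleaching disabled (the reference fluorophore)."""
    return build_single_model(cy5_rates, bleaching=False)


@pytest.fixture(scope="session")
def emitter_model():
    """Two-state S0/S1 emitter cycle: excitation and fluorescence only."""
    return build_single_model(toy_rates(kEXC=1.0e4, kFLU=2.5e4), bleaching=False)
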