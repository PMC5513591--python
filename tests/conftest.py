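import numpy as np
import pytest

from lactoflow.model import Dose, KineticRates, WaterPools


@pytest.fixture
def np_like_rates() -> KineticRates:
    """Rate constants near the normal-protein group medians."""
    return KineticRates(k_out_dam=0.0122, k_dam_to_litter=0.0122, k_out_litter=0.02)


@pytest.fixture
def np_like_pools() -> WaterPools:
    return WaterPools(tbw_dam_mass=259.7, tbw_litter_mass=152.0)


@pytest.fixture
def np_like_dose() -> Dose:
    """5 g/kg bolus to a 337.7 g dam at 99.9 mole % purity."""
    return Dose(d2o_mass=1.6885, dam_body_mass=337.7, purity=0.999)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
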