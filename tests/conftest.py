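import numpy as np
import pytest

from fishhealth.model import FishSpecimen, Season
from fishhealth.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full synthetic cohort under the default survey calibration."""
    return generate_cohort(GeneratorConfig(seed=11))


@pytest.fixture
def small_specimens():
    """A tiny hand-built specimen list with known values."""
    return [
        FishSpecimen("f1", "Hoplias malabaricus", Season.RAINY,
                     length_cm=30.0, weight_g=300.0, liver_weight_g=4.5,
                     parasite_count=0, thg_ugg=0.30, trophic_level=4.5),
        FishSpecimen("f2", "Hoplias malabaricus", Season.RAINY,
                     length_cm=28.0, weight_g=250.0, liver_weight_g=3.0,
                     parasite_count=2, thg_ugg=0.25, trophic_level=4.5),
        FishSpecimen("f3", "Hoplias malabaricus", Season.DRY,
                     length_cm=29.0, weight_g=260.0, liver_weight_g=None,
                     parasite_count=4, thg_ugg=None, trophic_level=4.5),
        FishSpecimen("f4", "Caquetaia kraussii", Season.DRY,
                     length_cm=18.0, weight_g=75.0, liver_weight_g=0.6,
                     parasite_count=0, thg_ugg=0.27, trophic_level=3.4),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
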