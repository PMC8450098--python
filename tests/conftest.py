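import numpy as np
import pytest

from srmotif import (
    Baselines,
    MeltSimSpec,
    ThermoParams,
    dh_from_dg_ds,
)
from srmotif.simulate import DEFAULT_BASELINES

#: (label, printed dG37 kcal/mol, printed dS e.u.) for the three duplexes
#: whose free energy and entropy are both tabulated: the bulged-G
#: prototype and its bulged-A / bulged-C variants.
PRINTED_DUPLEXES = [
    ("prototype_G4", -16.6, -260.5),
    ("bulge_A4", -10.6, -114.2),
    ("bulge_C4", -11.5, -158.3),
]


def params_from_printed(dg37: float, ds: float) -> ThermoParams:
    return ThermoParams(dh_from_dg_ds(dg37, ds), ds)


@pytest.fixture
def prototype_params() -> ThermoParams:
    return params_from_printed(-16.6, -260.5)


@pytest.fixture
def baselines() -> Baselines:
    return DEFAULT_BASELINES


@pytest.fixture
def prototype_spec(prototype_params) -> MeltSimSpec:
    return MeltSimSpec(params=prototype_params, seed=1234,
                       label="prototype")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
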