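import pathlib
import sys

import pytest

sys.path.insert(0, str(pathlib.Path(__file__).parent))

from asdsorption.eos import PcSaft
from asdsorption.isotherm import SorptionSystem
from asdsorption.kinetics import FilmGeometry
from asdsorption.netgp import DryASDSpec
from asdsorption.registry import load_registry

T_REF = 298.15


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def water_eos(registry):
    return PcSaft(registry.mixture("water"))


@pytest.fixture(scope="session")
def ternary_mixture(registry):
    return registry.mixture("water", "pvp", "ind")


@pytest.fixture(scope="session")
def film():
    # a typical spin-coated film: 8 um on a 14.5 mm circular base
    return FilmGeometry.from_thickness(8e-6, 1210.0)


@pytest.fixture(scope="session")
def pvpva_system(registry):
    return SorptionSystem(registry, DryASDSpec(polymer="pvpva", drug_load=0.0))


@pytest.fixture(scope="session")
def pvpva_ind_50(registry):
    return SorptionSystem(registry, DryASDSpec(polymer="pvpva", api="ind", drug_load=0.5))
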