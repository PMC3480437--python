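import numpy as np
import pytest

from meltshift.curves import ConditionMeta, MeltCurve
from meltshift.thermo import SpeciesThermo


@pytest.fixture
def boltzmann_curve():
    """Exact Boltzmann points: LL=0, UL=1, Tm=50, a=2 on a 1 °C grid."""
    t = np.arange(20.0, 76.0)
    f = 1.0 / (1.0 + np.exp((50.0 - t) / 2.0))
    return MeltCurve("exact_boltzmann", "A1", 1, t, f)


@pytest.fixture
def kinase_thermo():
    """A stable kinase-like species (apo midpoint 49 °C)."""
    return SpeciesThermo("kinase", 49.0, 420.0, dcp=6.0)


@pytest.fixture
def simple_condition():
    return ConditionMeta(proteins=(("kinase", 5.0),))
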