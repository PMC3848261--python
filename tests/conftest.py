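import numpy as np
import pytest

from isograd.fixtures import load_sugar_fixture


@pytest.fixture(scope="session")
def sugar_cal():
    return load_sugar_fixture()


@pytest.fixture(scope="session")
def analyte_by_name(sugar_cal):
    return {a.name: a for a in sugar_cal.analytes}


# calibration concentrations used throughout (5 isocratic runs, 2-98 mM)
CAL_CONCS = np.array([2.0, 26.0, 50.0, 74.0, 98.0])
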