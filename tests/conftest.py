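import numpy as np
import pytest

import triadscale as ts

STUDY_STANDARDS = {30, 40, 50, 60, 70}


@pytest.fixture(scope="session")
def full_design():
    """The study's full 320-triad design."""
    return ts.build_design(STUDY_STANDARDS)


@pytest.fixture(scope="session")
def filtered_design(full_design):
    """The 192 analyzable triads (standards >= 50, darkest stimulus L* 20)."""
    return ts.filter_by_standard(full_design, 50)


@pytest.fixture(scope="session")
def infamily_concave_g():
    """A concave perceptual-curve truth representable by the fitted knot family."""
    x = np.linspace(20.0, 100.0, 5)
    y = np.array([0.0, 30.0, 52.0, 68.0, 80.0])
    return ts.ScalingModel(variant="g", g=ts.KnotCurve(x, y))
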