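import numpy as np
import pytest

import tissuescan as ts
from tissuescan.models import optical_properties


@pytest.fixture(scope="session")
def lib():
    return ts.default_library()


@pytest.fixture(scope="session")
def geom():
    return ts.ProbeGeometry()


@pytest.fixture(scope="session")
def grid():
    return ts.WavelengthGrid()


@pytest.fixture(scope="session")
def wl(grid):
    return grid.wavelengths


def make_props(wl, lib, A=1.5, B=1.2, C=0.2, c_hb=1.0, c_bcar=0.1):
    return optical_properties(
        wl,
        ts.ScatteringParams(A=A, B=B, C=C),
        ts.AbsorberConcentrations(c_hb=c_hb, c_bcar=c_bcar),
        lib,
    )


def draw_params(rng):
    """One physiologically plausible random parameter draw, bounded away
    from zero so relative errors are meaningful."""
    return dict(
        A=rng.uniform(0.5, 3.0),
        B=rng.uniform(0.3, 2.5),
        C=rng.uniform(0.05, 0.5),
        c_hb=rng.uniform(0.1, 4.0),
        c_bcar=rng.uniform(0.02, 0.5),
    )
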