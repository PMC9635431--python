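import numpy as np
import pytest

from twinstack.cellgeom import CD9_CELL, UnitCell, build_basis
from twinstack.twinlaw import idealize_cell, make_twin_op


@pytest.fixture(scope="session")
def cd9_basis():
    return build_basis(CD9_CELL)


@pytest.fixture(scope="session")
def cd9_twin_op(cd9_basis):
    return make_twin_op(cd9_basis, "reciprocal", (1, 1, 0), 180.0)


@pytest.fixture(scope="session")
def idealized(cd9_twin_op):
    """(cell, basis, op) for the idealized CD9 cell on which the twin
    twofold about (1,1,0)* is exact."""
    return idealize_cell(cd9_twin_op)


@pytest.fixture(scope="session")
def cubic_basis():
    return build_basis(UnitCell(10, 10, 10, 90, 90, 90))


@pytest.fixture(scope="session")
def ortho_basis():
    return build_basis(UnitCell(2, 3, 4, 90, 90, 90))
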