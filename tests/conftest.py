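import pytest

import cochlearbox as cb


@pytest.fixture(scope="session")
def geometry():
    return cb.default_geometry()


@pytest.fixture(scope="session")
def materials():
    return cb.default_materials()


@pytest.fixture(scope="session")
def stiffness_const(geometry, materials):
    return cb.calibrated_stiffness_constant(geometry, materials)


@pytest.fixture(scope="session")
def matrix_records(geometry, materials):
    """The full 60-cell run matrix, solved once per session."""
    return cb.run_matrix(geometry, materials)


@pytest.fixture(scope="session")
def matrix_frame(matrix_records):
    return cb.records_to_frame(matrix_records)
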