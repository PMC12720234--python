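import numpy as np
import pytest

from modescan.mode_io import DisplacementGrid, Geometry, ModeSet, NormalMode, default_grid


@pytest.fixture
def grid21() -> DisplacementGrid:
    return default_grid()


@pytest.fixture
def water() -> Geometry:
    # O-H 0.9584 A, H-O-H 104.45 deg
    r, half = 0.9584, np.deg2rad(104.45 / 2)
    return Geometry(
        elements=["O", "H", "H"],
        coords=np.array([
            [0.0, 0.0, 0.0],
            [r * np.sin(half), r * np.cos(half), 0.0],
            [-r * np.sin(half), r * np.cos(half), 0.0],
        ]),
        label="water",
    )


@pytest.fixture
def formaldehyde() -> Geometry:
    return Geometry(
        elements=["C", "O", "H", "H"],
        coords=np.array([
            [0.0, 0.0, 0.0],
            [0.0, 1.205, 0.0],
            [0.943, -0.587, 0.0],
            [-0.943, -0.587, 0.0],
        ]),
        label="formaldehyde",
    )


@pytest.fixture
def diatomic_modeset() -> ModeSet:
    geom = Geometry(elements=["C", "O"], coords=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.13]]))
    mode = NormalMode.from_raw(1, 2000.0, np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]))
    return ModeSet(equilibrium=geom, modes=[mode])
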