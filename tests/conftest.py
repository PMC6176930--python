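import numpy as np
import pandas as pd
import pytest

from micropat.geometry import default_shape
from micropat.synthetic import Colony


def make_colony(shape, positions, t_labels, colony_id="c0", label_column="t_label"):
    """Build a Colony directly from positions and labels (no generator)."""
    positions = np.asarray(positions, dtype=float)
    cells = pd.DataFrame(
        {
            "colony_id": colony_id,
            "cell_id": np.arange(len(positions)),
            "x_um": positions[:, 0],
            "y_um": positions[:, 1],
            "z_um": 0.0,
            label_column: list(t_labels),
        }
    )
    return Colony(colony_id=colony_id, shape=shape, cells=cells)


@pytest.fixture(scope="session")
def disc_m():
    return default_shape("disc_m")


@pytest.fixture(scope="session")
def ellipse_m():
    return default_shape("ellipse_m")


@pytest.fixture(scope="session")
def hollow():
    return default_shape("hollow_ellipse")
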