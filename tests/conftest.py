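import numpy as np
import pandas as pd
import pytest

from qpop.design import DrugPanel, generate_oacd
from qpop.plate import PlateReadout
from qpop.surface import surface_from_coefficients


@pytest.fixture(scope="session")
def k2_truth():
    """Two-drug reference surface with known coefficients:
    y = 1 - 0.3 x1 - 0.2 x2 + 0.05 x1^2 - 0.15 x1 x2."""
    return surface_from_coefficients(
        intercept=1.0,
        linear=[-0.3, -0.2],
        quadratic=[0.05, 0.0],
        interaction=[-0.15],
        drug_names=["A", "B"],
    )


@pytest.fixture(scope="session")
def full_3x3_design():
    """Full 3^2 factorial as coded levels (9 rows)."""
    return np.array([[a, b] for a in (0, 1, 2) for b in (0, 1, 2)])


@pytest.fixture(scope="session")
def toy_panel():
    return DrugPanel(
        drugs=("A", "B"),
        doses=((0.0, 1e-6, 5e-6), (0.0, 2e-7, 1e-6)),
        cmax={"A": 5e-5, "B": 1e-5},
    )


@pytest.fixture(scope="session")
def oacd12():
    return generate_oacd(12)


def make_plate(neg, pos, design_signals=None):
    """Assemble a PlateReadout from explicit control/treated signal lists."""
    rows = []
    for i, s in enumerate(neg):
        rows.append((f"N{i}", s, "negative_control", pd.NA, 0))
    for i, s in enumerate(pos):
        rows.append((f"P{i}", s, "positive_control", pd.NA, 0))
    for i, (row_idx, s) in enumerate(design_signals or []):
        rows.append((f"D{i}", s, "design_row", row_idx, 0))
    return PlateReadout(
        pd.DataFrame(rows, columns=["well", "signal", "role", "design_row", "replicate"])
    )


@pytest.fixture
def plate_factory():
    return make_plate
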