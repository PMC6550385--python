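import numpy as np
import pandas as pd
import pytest

from tmespat.io import CellTable
from tmespat.phenotype import assign_phenotypes, call_hla1_status
from tmespat.synthetic import SyntheticConfig, generate_fov


def make_cells(df_dict, markers=(), unit="um"):
    """Tiny hand-built cell table; fills identity/QC columns with defaults."""
    df = pd.DataFrame(df_dict)
    n = len(df)
    defaults = {
        "cell_id": [f"c{i}" for i in range(n)],
        "fov_id": "F1",
        "sample_id": "S1",
        "qc_alignment": 0.95,
        "nucleus_pixels": 50,
        "membrane_pixels": 50,
        "cytoplasm_pixels": 50,
        "n_nuclei": 1,
    }
    for col, val in defaults.items():
        if col not in df.columns:
            df[col] = val
    return CellTable(df, unit=unit, markers=tuple(markers))


@pytest.fixture(scope="session")
def phenotyped_fov():
    """One mid-size synthetic FOV, phenotyped and HLA-called (fixed seed)."""
    table, truth = generate_fov(SyntheticConfig(seed=42, attraction=1.0, hla1pos_fraction=0.6))
    ph = call_hla1_status(assign_phenotypes(table))
    return ph, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
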