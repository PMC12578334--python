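from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from cphmdkit import ResidueComposition, TitrationModel

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def table2_path(data_dir) -> Path:
    return data_dir / "table2_anomalous_pka.csv"


@pytest.fixture(scope="session")
def s1_path(data_dir) -> Path:
    return data_dir / "synthetic_s1_pka_table.csv"


@pytest.fixture
def single_site_model() -> TitrationModel:
    return TitrationModel(conformers=((1.0, 4.0),))


@pytest.fixture
def mixture_model() -> TitrationModel:
    return TitrationModel(conformers=((0.5, 2.5), (0.5, 4.5)))


@pytest.fixture
def small_composition() -> ResidueComposition:
    return ResidueComposition(
        pd.DataFrame(
            {
                "residue": ["D1", "D2", "E1", "K1"],
                "res_type": ["ASP", "ASP", "GLU", "LYS"],
                "model_pka": [3.65, 3.65, 4.25, 10.4],
            }
        )
    )
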