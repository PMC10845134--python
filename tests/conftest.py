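import numpy as np
import pandas as pd
import pytest

from spikebench import MixDesign, QuantMatrix, RunDesign, make_run_design


@pytest.fixture(scope="session")
def hye_design() -> MixDesign:
    """The canonical human/yeast/E. coli 65:30:5 vs 65:15:20 design."""
    return MixDesign(["human", "yeast", "ecoli"], [65, 30, 5], [65, 15, 20])


@pytest.fixture(scope="session")
def run_design_3v3() -> RunDesign:
    return make_run_design(3)


@pytest.fixture
def tiny_matrix(run_design_3v3) -> QuantMatrix:
    """Six entries x six runs, hand-constructed, with missingness."""
    rows = {
        "P1_HUMAN": [100, 110, 90, 100, 95, 105],
        "P2_HUMAN": [100, np.nan, 90, 100, 95, 105],
        "P3_YEAST": [200, 220, 180, 100, 95, 105],
        "P4_ECOLI": [50, 55, 45, 200, 190, 210],
        "P5_YEAST": [np.nan, np.nan, 180, 100, 95, 105],
        "CON__P6": [10, 11, 9, 10, 11, 9],
    }
    inten = pd.DataFrame.from_dict(rows, orient="index", columns=list(run_design_3v3.run_ids))
    inten.index.name = "Protein.Group"
    return QuantMatrix(inten)
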