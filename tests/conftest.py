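import warnings

import numpy as np
import pandas as pd
import pytest

from pedqtl import sim
from pedqtl.core import GeneticMap, GenotypeMatrix, PhenotypeTable


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Library warnings (drops, fills) are part of tested behaviour; keep logs clean."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def study_panel():
    """One synthetic association panel under the study conditions."""
    return sim.simulate_study_panel(seed=11)


@pytest.fixture
def two_marker_map():
    return GeneticMap(
        pd.DataFrame(
            {
                "marker_id": ["m1", "m2"],
                "linkage_group": ["LG1", "LG1"],
                "position_cm": [0.0, 10.0],
                "map_source": ["synthetic", "synthetic"],
            }
        )
    )


def toy_matrix(rows: list[str], accession_prefix: str = "a") -> GenotypeMatrix:
    """Build a matrix from strings like '01N1' (N = missing)."""
    code = {"0": 0, "1": 1, "N": -1}
    calls = np.array([[code[c] for c in row] for row in rows], dtype=np.int8)
    accs = [f"{accession_prefix}{i + 1}" for i in range(len(rows))]
    markers = [f"m{j + 1}" for j in range(len(rows[0]))]
    return GenotypeMatrix(accs, markers, calls)


def long_phenotypes(cell_values: np.ndarray, trait: str = "FlYd") -> PhenotypeTable:
    """Genotype x environment cell-mean array -> long phenotype table."""
    rows = []
    g, e = cell_values.shape
    for i in range(g):
        for j in range(e):
            rows.append((f"a{i + 1}", f"E{j + 1}", 1, trait, float(cell_values[i, j])))
    return PhenotypeTable(
        pd.DataFrame(rows, columns=["accession", "environment", "replicate", "trait", "value"])
    )
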