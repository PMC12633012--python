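import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from alveoniche.datatypes import CountMatrix, SpatialCellMap
from alveoniche import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    cfg = synthetic.CohortConfig(
        n_specimens_per_class=2, cells_per_specimen=250, seed=42
    )
    return synthetic.generate_expression_cohort(cfg), cfg


@pytest.fixture(scope="session")
def spatial_sections():
    cfg = synthetic.SpatialConfig(n_sections=2, cells_per_section=1500, seed=7)
    return synthetic.generate_spatial_sections(cfg), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_count_matrix(counts, genes=None, cells=None, meta=None):
    counts = np.asarray(counts)
    n_g, n_c = counts.shape
    genes = genes if genes is not None else [f"g{i}" for i in range(n_g)]
    cells = cells if cells is not None else [f"c{i}" for i in range(n_c)]
    meta = meta if meta is not None else pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    return CountMatrix(
        genes=np.array(genes, dtype=object),
        cells=np.array(cells, dtype=object),
        counts=sp.csr_matrix(counts),
        cell_meta=meta,
    )


def make_section(x, y, labels, section_id="S1"):
    df = pd.DataFrame(
        {
            "cell_id": [f"{section_id}_c{i}" for i in range(len(x))],
            "x_um": x,
            "y_um": y,
            "label": labels,
        }
    )
    return SpatialCellMap(section_id=section_id, cells=df)
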