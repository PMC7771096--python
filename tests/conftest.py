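import numpy as np
import pytest

from hemanet import SpeciesPairConfig, generate_species_pair
from hemanet.containers import CellClustering, ExpressionMatrix


SMALL_CONFIG = dict(n_genes=300, n_cells_per_species=250, n_types=5, n_tfs=20,
                    module_count=5, module_size=8, dropout_rate=0.3,
                    nb_dispersion=2.0)


@pytest.fixture(scope="session")
def small_pair():
    """One reduced-scale paired-species draw shared across tests."""
    cfg = SpeciesPairConfig(**SMALL_CONFIG, seed=11)
    return generate_species_pair(cfg)


@pytest.fixture(scope="session")
def small_clusterings(small_pair):
    e1, e2, _, truth = small_pair
    c1 = CellClustering({c: truth.type_of_cell[c] for c in e1.cell_ids})
    c2 = CellClustering({c: truth.type_of_cell[c] for c in e2.cell_ids})
    return c1, c2


def expr_from_values(values, prefix="G", cell_prefix="C", species="s"):
    values = np.asarray(values)
    genes = [f"{prefix}{i}" for i in range(values.shape[0])]
    cells = [f"{cell_prefix}{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(values, genes, cells, species=species)
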