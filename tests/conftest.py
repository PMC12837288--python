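import numpy as np
import pandas as pd
import pytest

from germcore.genotypes import MISSING, GenotypeMatrix
from germcore.simulate import SimulationConfig, simulate_panel


def make_matrix(dosage, ids=None, chrom="chr1"):
    """Build a GenotypeMatrix from a plain dosage array (None -> missing)."""
    dosage = np.array(
        [[MISSING if v is None else v for v in row] for row in dosage], dtype=np.int8
    )
    n, l = dosage.shape
    ids = ids or [f"acc{i + 1}" for i in range(n)]
    loci = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(1, l + 1),
            "ref": "A",
            "alt": "T",
            "maf": np.nan,
            "missing_rate": np.nan,
        }
    )
    return GenotypeMatrix(accession_ids=ids, loci=loci, dosage=dosage)


@pytest.fixture(scope="session")
def small_panel():
    """Default-condition simulated panel, shrunk to 300 loci for speed."""
    cfg = SimulationConfig(seed=7, n_loci=300)
    g, phen, truth = simulate_panel(cfg)
    return g, phen, truth


@pytest.fixture
def tiny_g():
    return make_matrix(
        [
            [0, 1, 2, 0, 1, 2],
            [0, 1, 2, 0, 1, 2],
            [2, 1, 0, 1, None, 0],
            [1, 0, 1, 2, 1, None],
            [0, 2, 1, 1, 0, 1],
        ]
    )
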