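import numpy as np
import pandas as pd
import pytest

from exonsi.counts_io import CountTable
from exonsi.simulate import SimConfig, make_differential_dataset

SAMPLES = ["control_1", "control_2", "control_3",
           "knockdown_1", "knockdown_2", "knockdown_3"]
CONDITIONS = {s: s.rsplit("_", 1)[0] for s in SAMPLES}


def _count_table(feature_ids, gene_ids, lengths, counts):
    index = pd.Index(feature_ids, name="feature_id")
    return CountTable(
        features=pd.DataFrame({"gene_id": gene_ids, "length": lengths},
                              index=index),
        counts=pd.DataFrame(np.asarray(counts, dtype=np.int64), index=index,
                            columns=SAMPLES),
        conditions=dict(CONDITIONS),
    )


@pytest.fixture
def toy_tables():
    """Three genes: G1 two exons, G2 one exon (filtered), G3 two exons."""
    exon = _count_table(
        ["E1", "E2", "E3", "E4", "E5"],
        ["G1", "G1", "G2", "G3", "G3"],
        [100, 200, 150, 300, 120],
        [
            [10, 12, 11, 20, 22, 21],     # E1
            [40, 44, 39, 38, 42, 41],     # E2
            [100, 100, 100, 100, 100, 100],  # E3: only exon of G2
            [6, 7, 8, 0, 0, 0],           # E4: passes min-reads via control
            [5, 9, 9, 4, 9, 9],           # E5: fails strict > 5
        ],
    )
    gene = _count_table(
        ["G1", "G2", "G3"],
        ["G1", "G2", "G3"],
        [1000, 1500, 2000],
        [
            [100, 110, 105, 98, 107, 103],
            [400, 400, 400, 400, 400, 400],
            [60, 70, 80, 50, 90, 90],
        ],
    )
    return exon, gene


@pytest.fixture(scope="session")
def planted_dataset():
    config = SimConfig(n_genes=300, seed=11)
    return make_differential_dataset(config), config
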