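import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ampliconcnv.io import AmpliconDataset, DESIGN_COLUMNS

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


def make_design(rows):
    """Build a design table from (amplicon_id, chrom, start, end, gene, pool)."""
    df = pd.DataFrame.from_records(
        rows, columns=["amplicon_id"] + DESIGN_COLUMNS
    ).set_index("amplicon_id")
    return df


def make_dataset(rows, depths, samples=None, meta=None):
    """Assemble an AmpliconDataset directly (already in genomic order)."""
    design = make_design(rows)
    depths = np.asarray(depths)
    if samples is None:
        samples = [f"S{i + 1:03d}" for i in range(depths.shape[1])]
    dm = pd.DataFrame(depths, index=design.index, columns=samples)
    return AmpliconDataset(design=design, depths=dm, meta=meta)


def uniform_rows(n, chrom="chr1", gene="GENE", pools=2, start=1000, step=300):
    """n amplicons of one gene, pools interleaved."""
    return [
        (f"A{i + 1:03d}", chrom, start + i * step, start + i * step + 250,
         gene, (i % pools) + 1)
        for i in range(n)
    ]


@pytest.fixture
def single_pool_dataset():
    """5 amplicons, one pool, 3 samples with simple integer depths."""
    rows = uniform_rows(5, pools=1)
    depths = [
        [100, 200, 400],
        [100, 200, 400],
        [100, 200, 400],
        [100, 200, 400],
        [100, 200, 400],
    ]
    return make_dataset(rows, depths)
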