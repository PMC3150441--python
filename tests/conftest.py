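import numpy as np
import pandas as pd
import pytest

from evoscan.genome import GeneModel, GenomeSequence
from evoscan.pileup import COUNT_COLUMNS


@pytest.fixture
def toy_genome():
    # chrT: pad(5) + ATG CCA TAA (+ strand) + pad(5) + rc(ATG GGG TGA) + pad(4)
    seq = "AACCA" + "ATGCCATAA" + "GTTTC" + "TCACCCCAT" + "ACGT"
    return GenomeSequence({"chrT": seq})


@pytest.fixture
def toy_genes():
    return [
        GeneModel("FWD1", "chrT", "+", ((6, 14),), "CDS"),
        GeneModel("REV1", "chrT", "-", ((20, 28),), "CDS"),
    ]


def make_site_table(rows):
    """Build a pileup site table from dicts with sparse count keys."""
    full = []
    for r in rows:
        base = {c: 0 for c in COUNT_COLUMNS}
        base.update({"N": 0, "*": 0, "indels": None})
        base.update(r)
        full.append(base)
    df = pd.DataFrame(full)
    for c in ["pos"] + COUNT_COLUMNS + ["N", "*"]:
        df[c] = df[c].astype(np.int64)
    return df[["chrom", "pos", "ref"] + COUNT_COLUMNS + ["N", "*", "indels"]]


@pytest.fixture
def site_table_factory():
    return make_site_table
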