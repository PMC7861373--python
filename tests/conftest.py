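import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from msatpop.genotype_io import MISSING, GenotypeTable

# property tests must be reproducible run-to-run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_table(genotypes, loci=None, ids=None, metadata=None):
    """Build a GenotypeTable from a list of per-individual allele-pair
    lists, e.g. [[(10, 10), (12, 13)], ...]; None marks a missing locus."""
    n = len(genotypes)
    L = len(genotypes[0])
    loci = loci or [f"L{j + 1}" for j in range(L)]
    ids = ids or [f"iso{i + 1}" for i in range(n)]
    alleles = np.full((n, L, 2), MISSING, dtype=np.int64)
    for i, row in enumerate(genotypes):
        for j, pair in enumerate(row):
            if pair is not None:
                alleles[i, j] = pair
    meta = metadata if metadata is not None else pd.DataFrame()
    return GenotypeTable(ids, loci, alleles, meta)


@pytest.fixture
def two_cluster_table():
    """8 isolates in two tight groups, far apart at every locus."""
    g_a = [(10, 10), (12, 12), (14, 14)]
    g_b = [(20, 20), (22, 22), (24, 24)]
    rows = []
    for k in range(4):
        rows.append([(a + (1 if k == 1 else 0), b) for a, b in g_a])
    for k in range(4):
        rows.append([(a + (1 if k == 3 else 0), b) for a, b in g_b])
    return make_table([[tuple(sorted(p)) for p in r] for r in rows])
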