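import numpy as np
import pandas as pd
import pytest

from coevostab.io_formats import GeneCatalog, MUTATION_COLUMNS
from coevostab import synthetic_data as sd


@pytest.fixture
def tiny_catalog() -> GeneCatalog:
    return GeneCatalog(pd.Series({"geneA": 100, "geneB": 200, "geneC": 700}))


@pytest.fixture
def small_mutation_table() -> pd.DataFrame:
    rows = [
        # pop, treatment, species, gene, pos, ref, alt, class, freq
        ("C1", "coculture", "LP", "geneA", 10, "A", "G", "nonsynonymous", 0.50),
        ("C1", "coculture", "LP", "geneA", 55, "C", "T", "nonsynonymous", 0.10),
        ("C2", "coculture", "LP", "geneA", 120, "G", "A", "nonsense", 0.90),
        ("C2", "coculture", "LP", "geneB", 210, "T", "C", "synonymous", 0.30),
        ("C3", "coculture", "LP", "geneC", 400, "A", "C", "nonsynonymous", 0.05),
        ("C3", "coculture", "LP", "INTERGENIC", 99999, "G", "T", "intergenic", 0.80),
    ]
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


@pytest.fixture(scope="session")
def big_catalog() -> GeneCatalog:
    """The default synthetic genome: 3006 genes, log-normal lengths."""
    return sd.synthetic_gene_catalog(seed=1)


@pytest.fixture(scope="session")
def stable_params() -> sd.CommunityParams:
    return sd.CommunityParams.stable()


@pytest.fixture(scope="session")
def released_params() -> sd.CommunityParams:
    return sd.CommunityParams.released()
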