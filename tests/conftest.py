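import numpy as np
import pytest

import adaptarch as aa
from adaptarch.synthetic_data import simulate_expression_counts


@pytest.fixture(scope="session")
def panel():
    """A 189-founder panel on the default 5-arm uniform map."""
    return aa.generate_founder_haplotypes(n_haplotypes=189, n_loci=800, seed=1234)


@pytest.fixture(scope="session")
def big_panel():
    """Larger panel with near-independent loci for closed-form checks."""
    return aa.generate_founder_haplotypes(n_haplotypes=2000, n_loci=400, seed=99)


@pytest.fixture(scope="session")
def default_counts():
    """Default-design synthetic count matrix (2 ancestral + 2 evolved pops)."""
    return simulate_expression_counts(n_genes=2000, seed=777)
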