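import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from rangexpand import synthetic
from rangexpand.genotypes import GenotypeMatrix

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def two_pop_panel():
    """Two moderately differentiated populations, 2x30 diploids, 500 SNPs."""
    cfg = synthetic.SimPanelConfig(
        n_pops=2, pop_sizes=(30, 30), fst=(0.1, 0.1), n_snps=500, seed=42
    )
    G, truth = synthetic.simulate_genotype_panel(cfg)
    return G, truth


@pytest.fixture
def pop_labels(two_pop_panel):
    G, truth = two_pop_panel
    return pd.Series(truth.pop_labels, index=G.sample_ids)


def make_matrix(dosage, positions=None, chrom="chrI", sample_ids=None):
    """Small GenotypeMatrix from a literal dosage array."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_snps = dosage.shape
    if positions is None:
        positions = [(j + 1) * 1000 for j in range(n_snps)]
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "C"}
    )
    return GenotypeMatrix(sample_ids=sample_ids, snps=snps, dosage=dosage)
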