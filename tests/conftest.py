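import numpy as np
import pandas as pd
import pytest

from herloc import sim
from herloc.geno_io import GenotypeMatrix


def make_geno(dosage, chrom=None, pos=None, ids=None):
    """Build a GenotypeMatrix from a raw dosage array with default metadata."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    if chrom is None:
        chrom = np.ones(m, dtype=int)
    if ids is None:
        ids = [f"s{j}" for j in range(m)]
    snp_meta = pd.DataFrame(
        {"chrom": chrom, "pos_bp": pos, "id": ids, "allele1": "A", "allele2": "B"}
    )
    sample_meta = pd.DataFrame(
        {"fid": [f"F{i}" for i in range(n)], "iid": [f"I{i}" for i in range(n)],
         "sex": 0, "phenotype": -9}
    )
    return GenotypeMatrix(dosage=dosage, snp_meta=snp_meta, sample_meta=sample_meta)


@pytest.fixture(scope="session")
def ld_panel():
    """Medium LD-structured panel shared across read-only tests."""
    return sim.simulate_genotypes(
        sim.GenoSimConfig(n_samples=300, n_snps=1200, ld_rho=0.8,
                          low_freq_fraction=0.3, bp_spacing=2000, seed=42)
    )


@pytest.fixture(scope="session")
def free_panel():
    """LD-free panel (independent SNPs) shared across read-only tests."""
    return sim.simulate_genotypes(
        sim.GenoSimConfig(n_samples=400, n_snps=2000, ld_rho=0.0,
                          low_freq_fraction=0.3, bp_spacing=2000, seed=43)
    )
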