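import numpy as np
import pandas as pd
import pytest

from pleiogene.panel import GenotypePanel


def make_panel(genotypes, chrom=None, pos=None, alleles=None, ids=None):
    """Hand-built panel from a dosage matrix (individuals x markers)."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    m = genotypes.shape[1]
    chrom = chrom if chrom is not None else [1] * m
    pos = pos if pos is not None else [100 * (i + 1) for i in range(m)]
    alleles = alleles if alleles is not None else [("A", "G")] * m
    ids = ids if ids is not None else [f"s{i}" for i in range(m)]
    markers = pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": chrom,
            "pos": pos,
            "allele_a": [a for a, _ in alleles],
            "allele_b": [b for _, b in alleles],
        }
    )
    return GenotypePanel(markers, genotypes)


@pytest.fixture
def toy_panel():
    """20 individuals, 4 markers: s0/s1 perfectly anticorrelated, s2 in
    partial LD with s0, s3 independent."""
    rng = np.random.default_rng(42)
    g0 = rng.integers(0, 3, size=20)
    g1 = 2 - g0
    g2 = np.where(rng.random(20) < 0.7, g0, rng.integers(0, 3, size=20))
    g3 = rng.integers(0, 3, size=20)
    return make_panel(np.stack([g0, g1, g2, g3], axis=1))


@pytest.fixture(scope="session")
def bench_study():
    """One small planted benchmark study shared across tests (seed fixed)."""
    from pleiogene import synthetic

    cfg = synthetic.benchmark_config(seed=7, n_regions=12, n_individuals=800,
                                     decoys_per_filter=2)
    panel, genes_df, truth, stats, decoys = synthetic.simulate_study(cfg)
    return cfg, panel, genes_df, truth, stats, decoys
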