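import numpy as np
import pandas as pd
import pytest

from replifst import SimulationConfig, simulate_dataset
from replifst.simulate import GenotypeTable


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def dataset(default_config):
    """One full synthetic dataset shared across tests (read-only)."""
    return simulate_dataset(default_config)


def make_genotype_table(dosages, pops, genes=None, pos=None, **snp_meta):
    """Hand-build a small genotype table for fixtures.

    ``dosages``: (n_snps, n_samples) array; ``pops``: per-sample labels.
    """
    dosages = np.asarray(dosages, dtype=np.int8)
    m, s = dosages.shape
    genes = ["G1"] * m if genes is None else genes
    pos = list(range(0, 1000 * m, 1000)) if pos is None else pos
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{i}" for i in range(m)],
            "gene": genes,
            "pos": pos,
            "annotation": snp_meta.get("annotation", ["intronic"] * m),
            "ancestral": snp_meta.get("ancestral", ["A"] * m),
            "derived": snp_meta.get("derived", ["G"] * m),
            "outgroup_chimp": snp_meta.get("outgroup_chimp", ["A"] * m),
            "outgroup_macaque": snp_meta.get("outgroup_macaque", ["A"] * m),
            "chrom": ["chr1"] * m,
        }
    )
    samples = pd.DataFrame(
        {"sample_id": [f"i{j}" for j in range(s)], "population": list(pops)}
    )
    return GenotypeTable(snps, dosages, samples)
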