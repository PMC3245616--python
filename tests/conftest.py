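import numpy as np
import pytest

from regentx.synthetic import SimConfig, generate_genome, generate_transcriptome


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(
        seed=101,
        n_scaffolds=12,
        scaffold_length_dist=(8_000.0, 3_000.0),
        n_genes=40,
        split_gene_fraction=0.15,
        n_read_pairs=800,
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return generate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_transcriptome(small_cfg, small_genome):
    return generate_transcriptome(small_genome, small_cfg)
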