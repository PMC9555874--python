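import numpy as np
import pytest

import daeimpute as d


@pytest.fixture
def toy_panel() -> d.GenotypePanel:
    """3 samples x 4 variants with every genotype state represented."""
    variants = [
        d.Variant("22", 100, "A", "G"),
        d.Variant("22", 200, "C", "T"),
        d.Variant("22", 300, "G", "A"),
        d.Variant("22", 400, "T", "C"),
    ]
    geno = np.array(
        [
            [0, 1, 2, -1],
            [1, 1, 0, 2],
            [2, 0, 0, 1],
        ],
        dtype=np.int8,
    )
    return d.GenotypePanel(["s1", "s2", "s3"], variants, geno)


@pytest.fixture
def block_panel():
    """400 haplotypes, 3 strong-LD blocks of 60 separated by 20-variant
    hotspot gaps, with the generator's truth metadata."""
    blocks = [d.BlockSpec(n_variants=60, within_block_r2=0.95) for _ in range(3)]
    panel, truth = d.generate_panel(
        400, blocks, hotspot_gap_variants=20, rng=np.random.default_rng(12)
    )
    return panel, truth
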