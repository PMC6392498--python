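import numpy as np
import pytest

from stra8pipe.annotation import GeneAnnotation, Transcript
from stra8pipe.simulate import SimulationConfig, make_genome


@pytest.fixture(scope="session")
def small_cfg():
    """A fast small cohort: 200 genes on a 0.7-Mb chromosome."""
    return SimulationConfig(n_genes=200, chrom_length=700_000, seed=7)


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    return make_genome(small_cfg)


@pytest.fixture
def toy_annotation():
    """Two genes; gene A has two transcripts with distinct TSSs."""
    return GeneAnnotation(
        [
            Transcript("A.t1", "A", "chr1", "+", 5000),
            Transcript("A.t2", "A", "chr1", "-", 7000),
            Transcript("B.t1", "B", "chr1", "+", 20000),
        ],
        chrom_lengths={"chr1": 100_000},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
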