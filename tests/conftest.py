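import numpy as np
import pytest

from tsakit import simgen


@pytest.fixture(scope="session")
def small_triple():
    """A compact genome triple with the quadripartite plastid and a 600 nt
    plastid-homologous tract in the mitochondrion."""
    return simgen.make_genomes(
        lsc=3000, ssc=1200, ir=800, mito=6000, nuclear=8000, homology_tract=600, seed=1
    )


@pytest.fixture(scope="session")
def small_library(small_triple):
    """14,000 error-free pairs at copy folds 100:10:1 from the compact triple."""
    params = simgen.ReadSimParams(total_pairs=14000, copy_folds=(100.0, 10.0, 1.0), seed=2)
    pairs, truth = simgen.sample_read_pairs(small_triple, params)
    return pairs, truth, params


@pytest.fixture(scope="session")
def circular_genome_reads():
    """Error-free ~100x uniform single-end coverage of a repeat-free 5 kb circle."""
    from tsakit._seq import revcomp

    rng = np.random.default_rng(3)
    genome = simgen.random_sequence(5000, rng)
    ext = genome + genome
    reads = []
    for _ in range(5000):
        s = int(rng.integers(0, len(genome)))
        r = ext[s : s + 100]
        reads.append(r if rng.integers(0, 2) else revcomp(r))
    return genome, reads
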