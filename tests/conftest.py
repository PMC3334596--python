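import numpy as np
import pytest

from ribotraffic import SynthSpec, ToyBackend, synth_genome
from ribotraffic.tai import CodonWeights, TRNAPool, codon_weights


@pytest.fixture(scope="session")
def toy_backend():
    return ToyBackend()


@pytest.fixture(scope="session")
def small_synth():
    """Shared synthetic data set: 40 genes x 150 codons, default ramp."""
    return synth_genome(SynthSpec(n_genes=40, length_mean=150, seed=11))


@pytest.fixture(scope="session")
def simple_weights():
    """Codon weights from a small deterministic tRNA pool."""
    rng = np.random.default_rng(5)
    from ribotraffic.seq_core import SENSE_CODONS
    from ribotraffic.tai import _revcomp

    anticodons = sorted({_revcomp(c) for c in SENSE_CODONS})
    copies = {ac: int(rng.integers(1, 12)) for ac in anticodons}
    return codon_weights(TRNAPool(copies))
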