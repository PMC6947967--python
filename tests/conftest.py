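import numpy as np
import pytest

from gbsim import GenomeSpec, PopulationDesign


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A short two-chromosome genome for fast unit tests."""
    return GenomeSpec(n_chromosomes=2, chrom_length_cm=20.0, n_qtl_per_chrom=10)


@pytest.fixture
def small_design():
    """A miniature breeding design: tiny historical phases, few parents."""
    return PopulationDesign(
        hist_phase1_generations=20, hist_phase1_size=60,
        hist_phase2_generations=10, hist_phase2_end_size=40,
        founder_males=4, founder_females=16,
        recent_sires=4, recent_dams=16, recent_generations=4,
        litter_size=5)
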