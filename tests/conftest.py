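import numpy as np
import pytest

from mirforge import simlib, preprocess


@pytest.fixture(scope="session")
def small_library():
    """A small simulated library shared by integration-style tests."""
    cfg = simlib.SimConfig(
        n_hairpins=10, genome_length=20_000, read_depth=4000,
        contaminant_fraction=0.3, substitution_error_rate=0.0,
        nta_rate=0.05, equal_weights=True, rng_seed=123)
    truth = simlib.simulate_genome(cfg)
    reads = simlib.simulate_reads(truth, cfg)
    tags, stats = preprocess.run_preprocess(
        reads, cfg.adapter_3p, cfg.adapter_5p)
    return cfg, truth, reads, tags, stats


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_reads(seqs, qual_char="I"):
    """FASTQ-style tuples from plain sequences (constant quality)."""
    return [(f"r{i}", s, qual_char * len(s)) for i, s in enumerate(seqs)]
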