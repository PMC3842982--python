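import pytest

from ipemsat.fastq_io import ReadPair
from ipemsat.pipeline import RunConfig, run_pipeline
from ipemsat.simulate import SimParams, simulate_dataset


def make_pair(pair_id="p1", seq1="ACGT" * 25, seq2="TGCA" * 25, q=40):
    return ReadPair(
        pair_id, seq1, [q] * len(seq1), seq2, [q] * len(seq2)
    )


@pytest.fixture(scope="session")
def small_sim():
    """A 5k-pair simulated dataset with two multi-copy loci, plus its
    end-to-end pipeline result (shared across tests; nothing mutates it)."""
    params = SimParams(
        seed=42,
        n_loci=12,
        n_pairs=5_000,
        genome_len=400_000,
        copy_number_spec={0: 3, 1: 2},
    )
    pairs, manifest, genome = simulate_dataset(params)
    result = run_pipeline(pairs, RunConfig())
    return params, pairs, manifest, genome, result
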