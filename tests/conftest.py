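import pytest

from driseq import simgen, sss, toyalign


@pytest.fixture(scope="session")
def tiny_pair():
    """Small genome pair: 10 genes, ~25 kb, 2% divergence."""
    return simgen.generate_genome_pair(n_genes=10, divergence=0.02, seed=11)


@pytest.fixture(scope="session")
def tiny_reads(tiny_pair):
    """400 error-free fragments (800 reads) from the tiny pair."""
    return simgen.simulate_reads(tiny_pair, 400, read_length=75, error_rate=0.0, seed=12)


@pytest.fixture(scope="session")
def tiny_aligner(tiny_pair):
    return toyalign.PairAligner(tiny_pair)


@pytest.fixture(scope="session")
def tiny_sorted(tiny_reads, tiny_aligner):
    """Aligned and sorted tiny read set: (records, table, summary, assignments)."""
    records = [(r.name, *tiny_aligner.align(r.name, r.sequence)) for r in tiny_reads]
    table, summary, assignments = sss.sort_sample(records)
    return records, table, summary, assignments
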