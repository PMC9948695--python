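import numpy as np
import pytest

from curdcat.records import ContigRecord, GenomeRecord, Provenance, Thresholds
from curdcat.simulate import mutate_sequence, random_genome_sequence


@pytest.fixture
def thresholds():
    return Thresholds()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_genome(
    genome_id,
    sequence=None,
    length=5000,
    n_contigs=1,
    provenance=Provenance.TIMEPOINT,
    circular=False,
    completeness=95.0,
    contamination=1.0,
    taxonomy=(),
    seed=0,
):
    """Small helper to build GenomeRecords for unit tests."""
    rng = np.random.default_rng(seed)
    if sequence is None:
        sequence = random_genome_sequence(length, 0.5, rng)
    n = len(sequence)
    bounds = np.linspace(0, n, n_contigs + 1).astype(int)
    contigs = [
        ContigRecord(f"{genome_id}.c{i:03d}", sequence[a:b])
        for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]), start=1)
    ]
    return GenomeRecord(
        genome_id=genome_id,
        contigs=contigs,
        provenance=provenance,
        circular=circular and n_contigs == 1,
        completeness=completeness,
        contamination=contamination,
        taxonomy=taxonomy,
    )


def alignment_identity(parent: str, variant: str) -> float:
    """Independent ANI oracle for the substitution-only strain model:
    percent identity over the known homologous coordinates (the two
    sequences are positionally aligned by construction)."""
    assert len(parent) == len(variant)
    a = np.frombuffer(parent.encode(), dtype=np.uint8)
    b = np.frombuffer(variant.encode(), dtype=np.uint8)
    return 100.0 * float(np.mean(a == b))


@pytest.fixture
def strain_pair(rng):
    """A 100 kb parent and a 1%-substituted variant with its oracle ANI."""
    parent = random_genome_sequence(100_000, 0.5, rng)
    variant = mutate_sequence(parent, 0.01, rng)
    return parent, variant, alignment_identity(parent, variant)
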