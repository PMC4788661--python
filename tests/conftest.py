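"""Shared fixtures: a small synthetic study reused across test modules."""

from __future__ import annotations

import pytest

from phasekit import synthgen
from phasekit.annotate import map_to_genome
from phasekit.preprocess import SmallRNARead, collapse, normalize, trim_reads


@pytest.fixture(scope="session")
def bundle():
    """Small reference bundle: 2 chromosomes x 100 kb, seed 7."""
    return synthgen.generate_reference(chromosome_length=100_000, n_chromosomes=2,
                                       seed=7)


@pytest.fixture(scope="session")
def planted(bundle):
    """Twelve phased loci planted into the bundle's genome."""
    return synthgen.plant_phased_loci(bundle, n_loci=12, seed=8)


@pytest.fixture(scope="session")
def simulation(bundle, planted):
    """Two 20k-read libraries plus ground truth."""
    reads_a, reads_b, truth = synthgen.simulate_libraries(
        planted, bundle, library_sizes=(20_000, 20_000), seed=9
    )
    return reads_a, reads_b, truth


@pytest.fixture(scope="session")
def distincts(simulation):
    """Trimmed, collapsed and normalised distinct-sequence table."""
    reads_a, reads_b, _ = simulation
    reads = [SmallRNARead(i, s, q, "A") for i, s, q in reads_a]
    reads += [SmallRNARead(i, s, q, "B") for i, s, q in reads_b]
    trimmed, _ = trim_reads(reads, synthgen.DEFAULT_ADAPTER)
    table, _ = collapse(trimmed)
    return normalize(table)


@pytest.fixture(scope="session")
def genome_alignments(distincts, bundle):
    """Exact genomic alignments of every distinct sequence."""
    return map_to_genome(distincts["sequence"].tolist(), bundle.genome)
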