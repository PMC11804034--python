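"""Shared fixtures: a session-scoped toy genome and default cohort."""

from __future__ import annotations

import numpy as np
import pytest

from bilecirc.annotation import find_eccgenes
from bilecirc.synthetic import (CohortSpec, GenomeSpec, simulate_cohort,
                                simulate_genome)


@pytest.fixture(scope="session")
def genome():
    """Default two-chromosome 1-Mb genome (seed 1)."""
    return simulate_genome(GenomeSpec(), seed=1)


@pytest.fixture(scope="session")
def small_genome():
    """Fast 200-kb single-chromosome genome for read-level tests."""
    return simulate_genome(GenomeSpec(n_chromosomes=1, chrom_length=200_000,
                                      genes_per_mb=30, enhancers_per_mb=8,
                                      enhancer_length_range=(3_000, 8_000)),
                           seed=2)


@pytest.fixture(scope="session")
def default_cohort(genome):
    """The study-condition training cohort: 17 cancer + 11 noncancer,
    10,000 circles/sample, marker fold change 8 (seed 11)."""
    spec = CohortSpec()
    return spec, simulate_cohort(genome, spec, seed=spec.seed)


@pytest.fixture(scope="session")
def default_cohort_gene_hits(genome, default_cohort):
    _, profiles = default_cohort
    return {p.sample_id: find_eccgenes(p.eccdna, genome.bundle)
            for p in profiles}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
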