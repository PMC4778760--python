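"""Shared fixtures: a tiny population design mirroring the scanned study
(2 diploid + 1 haploid "dog", 3 diploid "wolf", 1 diploid outgroup) and
small deterministic site tables."""

import numpy as np
import pytest

from sweepscan.nullsim import default_population_spec
from sweepscan.popspec import IntervalSet, PopulationSpec, SiteTable


@pytest.fixture(scope="session")
def spec() -> PopulationSpec:
    return default_population_spec(outgroup=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def make_sites(contig, positions, alt_dog, alt_wolf, alt_out=None,
               n=None):
    """Small SiteTable builder for the default design (5/6/2 chromosomes)."""
    n = n or {"dog": 5, "wolf": 6, "outgroup": 2}
    m = len(positions)
    alt = {"dog": alt_dog, "wolf": alt_wolf,
           "outgroup": alt_out if alt_out is not None else [0] * m}
    return SiteTable([contig] * m, positions, alt, n)


@pytest.fixture
def tiny_sites():
    # three biallelic sites on one contig
    return make_sites("chr1", [10, 20, 30], [2, 0, 5], [1, 3, 0])


@pytest.fixture
def full_mask():
    return IntervalSet([("chr1", 0, 100_000)])
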