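"""Shared fixtures: one synthetic genome with ground truth, scanned once."""

from __future__ import annotations

import pytest

from nor5s.scan import assemble_units, scan_genome
from nor5s.simulate import (
    RdnaUnitSpec,
    build_genome,
    default_variant_pair,
    make_variant_pair,
)
from nor5s.types import SequenceRecord

GENOME_SEED = 20230417


@pytest.fixture(scope="session")
def variant_pair():
    return default_variant_pair()


@pytest.fixture(scope="session")
def gene_pair(variant_pair):
    """(nts_sequence, nor_sequence) of the default 119-nt variant pair."""
    return make_variant_pair(variant_pair)


@pytest.fixture(scope="session")
def genome(variant_pair):
    """(contigs, truth) for the default three-unit synthetic genome."""
    return build_genome(RdnaUnitSpec(), variant_pair, seed=GENOME_SEED)


@pytest.fixture(scope="session")
def references(genome):
    _, truth = genome
    return [
        SequenceRecord(name, truth.genes[name])
        for name in ("18S", "5.8S", "28S", "5S")
    ]


@pytest.fixture(scope="session")
def scanned(genome, references):
    """Hits and units for the default genome, computed once per session."""
    contigs, _ = genome
    hits_by = scan_genome(contigs, references)
    units_by = {
        c.identifier: assemble_units(hits_by[c.identifier], len(c))[0] for c in contigs
    }
    return hits_by, units_by
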