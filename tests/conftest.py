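"""Shared fixtures: toy genomes with hand-checkable trap behaviour."""

import pytest

from sigmatrap import (
    Gene,
    GenomeAnnotation,
    PromoterSite,
    TerminatorSite,
    TranscriptionUnit,
)


def make_unit(uid, strand, genes, prom_pos, term_pos, read_through=0.0):
    term = None
    if term_pos is not None:
        term = TerminatorSite(id=f"T_{uid}", position=term_pos, strand=strand,
                              read_through_prob=read_through)
    return TranscriptionUnit(
        id=uid, strand=strand, genes=tuple(genes),
        promoter=PromoterSite(id=f"P_{uid}", position=prom_pos, strand=strand, parent_tu=uid),
        terminator=term,
    )


@pytest.fixture
def g1():
    """Circular 1 kb genome, one '+' unit: promoter at 100, terminator at 400.

    At fixed length 200 under the promoterless trap with full recognition the
    exact positive fraction is 0.10 (200 of 2,000 placements).
    """
    genome = GenomeAnnotation(name="G1", length=1000, circular=True, units=[
        make_unit("TU0", "+", [Gene("g0", 100, 400, "+")], prom_pos=100, term_pos=400),
    ])
    genome.validate()
    return genome


@pytest.fixture
def g1_early_terminator():
    """G1 with the terminator moved to 150: exact fraction drops to 0.025."""
    genome = GenomeAnnotation(name="G1e", length=1000, circular=True, units=[
        make_unit("TU0", "+", [Gene("g0", 100, 150, "+")], prom_pos=100, term_pos=150),
    ])
    genome.validate()
    return genome


@pytest.fixture
def terminator_free_genome():
    """Circular genome whose units carry promoters but no terminators."""
    genome = GenomeAnnotation(name="NT", length=2000, circular=True, units=[
        make_unit("TU0", "+", [Gene("g0", 100, 500, "+")], prom_pos=100, term_pos=None),
        make_unit("TU1", "-", [Gene("g1", 900, 1400, "-")], prom_pos=1399, term_pos=None),
    ])
    genome.validate()
    return genome


@pytest.fixture
def two_strand_genome():
    """Linear 3 kb genome with one unit per strand, both terminated."""
    genome = GenomeAnnotation(name="TS", length=3000, circular=False, units=[
        make_unit("TU0", "+", [Gene("g0", 200, 800, "+")], prom_pos=200, term_pos=800),
        make_unit("TU1", "-", [Gene("g1", 1500, 2200, "-")], prom_pos=2199, term_pos=1500),
    ])
    genome.validate()
    return genome
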