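"""Genomic-library coverage statistics and related formulaic metrics.

Clarke-Carbon clone numbers: for insert fraction f = insert_bp / genome_bp,
the number of random clones giving probability P that every genomic position
is represented is N = ln(1 - P) / ln(1 - f).  Fold coverage is an achieved
clone count over that N.  Also here: the inverse (coverage probability of a
given clone count), colony-count survival rates, and RPKM normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd


@dataclass(frozen=True)
class CoverageSpec:
    """Resolved Clarke-Carbon triple for one library."""

    P: float
    insert_bp: float
    genome_bp: float
    f: float
    N: float
    N_ceil: int


def clarke_carbon_clones(P: float, insert_bp: float, genome_bp: float) -> CoverageSpec:
    """Clones required for coverage probability ``P``: N = ln(1-P)/ln(1-f)."""
    if not (0.0 < P < 1.0):
        raise ValueError("P must lie strictly between 0 and 1")
    if not (0.0 < insert_bp < genome_bp):
        raise ValueError("require 0 < insert_bp < genome_bp")
    f = insert_bp / genome_bp
    N = math.log(1.0 - P) / math.log(1.0 - f)
    return CoverageSpec(P=P, insert_bp=insert_bp, genome_bp=genome_bp,
                        f=f, N=N, N_ceil=math.ceil(N))


def clarke_carbon_small_f(P: float, f: float) -> float:
    """Small-f closed form N = -ln(1-P)/f (first-order in f)."""
    if not (0.0 < P < 1.0) or not (0.0 < f < 1.0):
        raise ValueError("require P, f in (0, 1)")
    return -math.log(1.0 - P) / f


@dataclass(frozen=True)
class FoldCoverage:
    value: float          # rounded to 1 decimal, ties half-up
    unrounded: float


def fold_coverage(n_clones: float, required_clones: float) -> FoldCoverage:
    """Achieved clone count over the Clarke-Carbon requirement, at 1 decimal."""
    if required_clones <= 0:
        raise ValueError("required_clones must be positive")
    raw = n_clones / required_clones
    rounded = float(Decimal(repr(raw)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return FoldCoverage(value=rounded, unrounded=raw)


def coverage_probability(n_clones: float, f: float) -> float:
    """Probability every position is covered by ``n_clones``: 1 - (1-f)^n."""
    if not (0.0 < f < 1.0):
        raise ValueError("f must lie strictly between 0 and 1")
    if n_clones < 0:
        raise ValueError("n_clones must be non-negative")
    return 1.0 - (1.0 - f) ** n_clones


@dataclass(frozen=True)
class SurvivalRecord:
    cfu_0: float
    cfu_t: float
    timepoint_h: float

    def __post_init__(self) -> None:
        if self.cfu_0 <= 0:
            raise ValueError("cfu_0 must be positive")
        if self.cfu_t < 0:
            raise ValueError("cfu_t must be non-negative")


def survival_rate(record: SurvivalRecord) -> float:
    """Specific survival rate in percent: cfu(t) / cfu(0) * 100."""
    return record.cfu_t / record.cfu_0 * 100.0


def fold_change(rate_a: float, rate_b: float) -> float:
    """Ratio of two survival rates (or any two positive rates)."""
    if rate_b == 0:
        raise ValueError("rate_b must be nonzero")
    return rate_a / rate_b


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    mapped_reads: float
    gene_length_bp: float
    library_mapped_total: float

    def __post_init__(self) -> None:
        if self.gene_length_bp <= 0:
            raise ValueError("gene_length_bp must be positive")
        if self.library_mapped_total <= 0:
            raise ValueError("library_mapped_total must be positive")
        if self.mapped_reads < 0:
            raise ValueError("mapped_reads must be non-negative")


def rpkm(record: ExpressionRecord) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    return (record.mapped_reads
            / (record.gene_length_bp / 1_000.0)
            / (record.library_mapped_total / 1_000_000.0))


# ---------------------------------------------------------------------------
# Reference library statistics
#
# Published characteristics of five genome-wide promoter-trap entry libraries:
# mean sequenced insert size, entry-library clone count (the
# coverage-limiting step), and the published required-clone count at P=0.95.
# RefSeq total genome sizes (chromosome plus plasmids) are listed where the
# assembly is unambiguous; the C. pasteurianum assembly underlying its
# published requirement is not identifiable, so its genome size is omitted
# and its published requirement is used directly.

LIBRARY_TABLE = pd.DataFrame.from_records(
    [
        ("LPL", "Lactobacillus plantarum WCFS1", 726, 110_000, 13_820, 3_348_625),
        ("BSU", "Bacillus subtilis 168", 1_684, 21_733, 7_505, 4_215_606),
        ("DRA", "Deinococcus radiodurans R1", 736, 49_140, 13_350, 3_284_156),
        ("CPA", "Clostridium pasteurianum", 562, 219_350, 26_850, None),
        ("CAC", "Clostridium acetobutylicum ATCC 824", 267, 237_260, 46_337, 4_132_880),
    ],
    columns=["library", "source", "insert_bp", "n_clones",
             "required_clones_published", "genome_bp"],
)


def library_coverage_table(P: float = 0.95) -> pd.DataFrame:
    """Coverage summary for the five reference promoter-trap libraries.

    For each library: the Clarke-Carbon requirement at ``P`` computed from
    the RefSeq genome size (where available; otherwise the published
    requirement), and the fold coverage of the entry-library clone count
    against the published requirement.
    """
    rows = []
    for rec in LIBRARY_TABLE.itertuples(index=False):
        if rec.genome_bp is not None and not pd.isna(rec.genome_bp):
            spec = clarke_carbon_clones(P, rec.insert_bp, rec.genome_bp)
            n_req_computed = spec.N
        else:
            n_req_computed = float("nan")
        fold = fold_coverage(rec.n_clones, rec.required_clones_published)
        rows.append({
            "library": rec.library,
            "source": rec.source,
            "insert_bp": rec.insert_bp,
            "n_clones": rec.n_clones,
            "required_clones_published": rec.required_clones_published,
            "required_clones_computed": n_req_computed,
            "fold_coverage": fold.value,
            "fold_coverage_unrounded": fold.unrounded,
        })
    return pd.DataFrame(rows)
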