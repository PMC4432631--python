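"""Seeded generator of synthetic annotated prokaryotic genomes.

The trap simulation only consumes annotation topology, so a synthetic genome
is a sequence of transcription units laid head-to-tail with intergenic gaps:

* gene lengths: log-normal with configurable mean (default 924 bp, the
  average prokaryotic gene size) and coefficient of variation (default 0.5);
* genes per unit: geometric on {1, 2, ...} (default mean 1.7, matching the
  observed decay of operon sizes);
* gaps between units: exponential (default mean 120 bp); gaps between genes
  inside a unit: fixed 20 bp;
* unit strand: independent Bernoulli (default 0.5 probability of '+').

One promoter point feature marks each unit's transcription start and one
terminator its end.  A single numpy Generator seeded once drives every draw
in a fixed order (strand, gene count, gene lengths, gaps, unit by unit), so
identical parameters and seed give a bit-identical genome and GFF3 stream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .annotation_io import (
    FORWARD,
    REVERSE,
    Gene,
    GenomeAnnotation,
    PromoterSite,
    TerminatorSite,
    TranscriptionUnit,
    write_gff3,
)

#: Average prokaryotic gene length in bp, the constant the insert size of a
#: promoter-trap library is deliberately chosen below.
MEAN_GENE_BP = 924

# refuse to build genomes with more features than this (memory guard)
_MAX_TOTAL_GENES = 5_000_000


@dataclass(frozen=True)
class SyntheticGenomeParams:
    """Parameters of the synthetic annotation generator."""

    n_units: int
    mean_gene_bp: float = MEAN_GENE_BP
    gene_len_cv: float = 0.5          # coefficient of variation of the log-normal
    genes_per_unit_mean: float = 1.7  # geometric mean on {1, 2, ...}
    intergenic_gap_mean: float = 120.0
    intragenic_gap_bp: int = 20       # fixed gap between genes within a unit
    strand_bias: float = 0.5          # probability a unit lies on '+'
    circular: bool = True
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_units < 0:
            raise ValueError("n_units must be >= 0")
        if self.mean_gene_bp <= 0:
            raise ValueError("mean_gene_bp must be positive")
        if self.gene_len_cv < 0:
            raise ValueError("gene_len_cv must be >= 0")
        if self.genes_per_unit_mean < 1:
            raise ValueError("genes_per_unit_mean must be >= 1 (units have at least one gene)")
        if self.intergenic_gap_mean < 0 or self.intragenic_gap_bp < 0:
            raise ValueError("gaps must be non-negative")
        if not (0.0 <= self.strand_bias <= 1.0):
            raise ValueError("strand_bias must lie in [0, 1]")


def generate_genome(params: SyntheticGenomeParams) -> GenomeAnnotation:
    """Generate a synthetic :class:`GenomeAnnotation` from ``params``.

    Units are laid out left to right; each unit is preceded by an exponential
    intergenic gap and followed, after the last unit, by one trailing gap so
    no feature touches the origin on circular genomes.  The genome length is
    the final cursor position.
    """
    if params.n_units * max(params.genes_per_unit_mean, 1.0) > _MAX_TOTAL_GENES:
        raise ValueError(
            f"n_units={params.n_units} would generate more than {_MAX_TOTAL_GENES} genes; "
            "reduce n_units or genes_per_unit_mean"
        )
    rng = np.random.default_rng(params.seed)
    # log-normal parametrized by arithmetic mean and CV
    cv2 = params.gene_len_cv ** 2
    sigma = math.sqrt(math.log1p(cv2))
    mu = math.log(params.mean_gene_bp) - sigma ** 2 / 2.0
    p_geom = 1.0 / params.genes_per_unit_mean

    units: list[TranscriptionUnit] = []
    cursor = 0
    for i in range(params.n_units):
        strand = FORWARD if rng.random() < params.strand_bias else REVERSE
        n_genes = int(rng.geometric(p_geom))
        lengths = np.maximum(np.rint(rng.lognormal(mu, sigma, size=n_genes)).astype(int), 30)
        gap = int(round(rng.exponential(params.intergenic_gap_mean))) + 1
        cursor += gap
        # physical layout left -> right
        genes: list[Gene] = []
        pos = cursor
        for j, glen in enumerate(lengths):
            genes.append(Gene(id=f"G{i:05d}_{j}", start=pos, end=pos + int(glen), strand=strand))
            pos += int(glen)
            if j < n_genes - 1:
                pos += params.intragenic_gap_bp
        lo, hi = cursor, pos
        uid = f"TU{i:05d}"
        if strand == FORWARD:
            ordered = tuple(genes)
            prom_pos, term_pos = lo, hi
        else:
            ordered = tuple(reversed(genes))
            prom_pos, term_pos = hi - 1, lo
        units.append(TranscriptionUnit(
            id=uid, strand=strand, genes=ordered,
            promoter=PromoterSite(id=f"P{i:05d}", position=prom_pos, strand=strand, parent_tu=uid),
            terminator=TerminatorSite(id=f"T{i:05d}", position=term_pos, strand=strand),
        ))
        cursor = hi
    # trailing gap keeps every feature coordinate strictly inside the genome
    cursor += int(round(rng.exponential(params.intergenic_gap_mean))) + 1
    length = max(cursor, 1)
    genome = GenomeAnnotation(name=params.name, length=length,
                              circular=params.circular, units=units)
    genome.validate()
    return genome


@dataclass(frozen=True)
class GenomeSummary:
    """Feature counts and size statistics of an annotation."""

    genome_length: int
    n_units: int
    n_genes: int
    n_promoters: int
    n_terminators: int
    n_units_forward: int
    n_units_reverse: int
    mean_gene_bp: float
    median_gene_bp: float


def summarize_genome(genome: GenomeAnnotation) -> GenomeSummary:
    """Per-strand feature counts and gene-length statistics."""
    gene_lengths = np.array([g.length for g in genome.genes()], dtype=float)
    fwd = sum(1 for u in genome.units if u.strand == FORWARD)
    return GenomeSummary(
        genome_length=genome.length,
        n_units=len(genome.units),
        n_genes=int(gene_lengths.size),
        n_promoters=len(genome.promoters()),
        n_terminators=len(genome.terminators()),
        n_units_forward=fwd,
        n_units_reverse=len(genome.units) - fwd,
        mean_gene_bp=float(gene_lengths.mean()) if gene_lengths.size else 0.0,
        median_gene_bp=float(np.median(gene_lengths)) if gene_lengths.size else 0.0,
    )


def write_genome(genome: GenomeAnnotation, params: SyntheticGenomeParams,
                 gff_path: str | Path) -> Path:
    """Write the genome as GFF3 plus a key=value parameter sidecar.

    The sidecar records the seed and every generator parameter so a run can
    be reproduced exactly; returns the sidecar path.
    """
    gff_path = Path(gff_path)
    write_gff3(genome, gff_path)
    sidecar = gff_path.with_suffix(gff_path.suffix + ".params.txt")
    lines = [f"{k}={v}" for k, v in sorted(asdict(params).items())]
    lines.append(f"genome_length={genome.length}")
    sidecar.write_text("\n".join(lines) + "\n")
    return sidecar
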