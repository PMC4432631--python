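"""Genome annotation model and interval I/O.

The promoter-trap simulation is purely topological: it needs to know where
transcription units start (promoters), where they end (terminators), and on
which strand they read — never the nucleotide sequence.  This module defines
that annotation model and the converters at its boundaries:

* GFF3 in (1-based, inclusive) -> internal coordinates (0-based, half-open),
* transcription-unit inference from a flat gene list (operon merging by
  intergenic gap),
* BED6 out for per-insert classification tracks.

All internal interval arithmetic is 0-based half-open, which keeps wraparound
on circular genomes unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

logger = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"
_STRANDS = (FORWARD, REVERSE)


@dataclass(frozen=True)
class Gene:
    """A gene interval, 0-based half-open, on one strand."""

    id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.id}: require 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PromoterSite:
    """Point feature at a transcription unit's start coordinate."""

    id: str
    position: int
    strand: str
    parent_tu: str

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"promoter {self.id}: bad strand {self.strand!r}")
        if self.position < 0:
            raise ValueError(f"promoter {self.id}: negative position")


@dataclass(frozen=True)
class TerminatorSite:
    """Point feature at a transcription unit's end coordinate.

    ``read_through_prob`` is the probability that elongating polymerase passes
    the terminator; 0 (the default everywhere) means absolute termination.
    """

    id: str
    position: int
    strand: str
    read_through_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"terminator {self.id}: bad strand {self.strand!r}")
        if self.position < 0:
            raise ValueError(f"terminator {self.id}: negative position")
        if not (0.0 <= self.read_through_prob <= 1.0):
            raise ValueError(f"terminator {self.id}: read_through_prob outside [0, 1]")


@dataclass(frozen=True)
class TranscriptionUnit:
    """A strand-aware operon: ordered genes, one promoter, one terminator.

    Genes are ordered in transcription direction (increasing coordinates on
    '+', decreasing on '-').  The promoter sits at the transcription start,
    the terminator at the transcription end.
    """

    id: str
    strand: str
    genes: tuple[Gene, ...]
    promoter: PromoterSite
    terminator: TerminatorSite | None  # None models a unit with no annotated terminator

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"unit {self.id}: bad strand {self.strand!r}")
        for g in self.genes:
            if g.strand != self.strand:
                raise ValueError(f"unit {self.id}: gene {g.id} strand differs from unit strand")
        if self.promoter.strand != self.strand:
            raise ValueError(f"unit {self.id}: promoter strand differs from unit strand")
        if self.terminator is not None and self.terminator.strand != self.strand:
            raise ValueError(f"unit {self.id}: terminator strand differs from unit strand")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic interval [min start, max end) covered by the unit's genes."""
        return (min(g.start for g in self.genes), max(g.end for g in self.genes))


@dataclass
class GenomeAnnotation:
    """A circular or linear genome carrying transcription units."""

    name: str
    length: int
    circular: bool
    units: list[TranscriptionUnit] = field(default_factory=list)

    def genes(self) -> list[Gene]:
        return [g for u in self.units for g in u.genes]

    def promoters(self) -> list[PromoterSite]:
        return [u.promoter for u in self.units]

    def terminators(self) -> list[TerminatorSite]:
        return [u.terminator for u in self.units if u.terminator is not None]

    def validate(self) -> None:
        """Raise ValueError on any structural inconsistency."""
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        ids: set[str] = set()
        for u in self.units:
            if not u.genes:
                raise ValueError(f"unit {u.id}: empty gene list")
            sites = (u.promoter,) if u.terminator is None else (u.promoter, u.terminator)
            for site in sites:
                if site.id in ids:
                    raise ValueError(f"duplicate feature id {site.id}")
                ids.add(site.id)
                if not (0 <= site.position < self.length):
                    raise ValueError(f"feature {site.id}: position {site.position} outside genome")
            for g in u.genes:
                if g.end > self.length:
                    raise ValueError(f"gene {g.id}: end {g.end} exceeds genome length {self.length}")
            # promoter precedes the first gene and terminator follows the last
            # gene in transcription direction
            lo, hi = u.span
            if u.strand == FORWARD:
                ok = u.promoter.position <= lo and (u.terminator is None
                                                    or u.terminator.position >= hi)
            else:
                ok = u.promoter.position >= hi - 1 and (u.terminator is None
                                                        or u.terminator.position <= lo)
            if not ok:
                raise ValueError(f"unit {u.id}: promoter/terminator not flanking genes")
            # genes within a unit must be non-overlapping and ordered in
            # transcription direction
            ordered = u.genes if u.strand == FORWARD else tuple(reversed(u.genes))
            for a, b in zip(ordered, ordered[1:]):
                if a.end > b.start:
                    raise ValueError(f"unit {u.id}: genes {a.id} and {b.id} overlap or are misordered")


def read_gff3(path: str | Path, genome_length: int, circular: bool = False) -> list[Gene]:
    """Read gene features from a GFF3 file into internal coordinates.

    GFF3 coordinates are 1-based inclusive; internally genes are 0-based
    half-open, so a GFF3 line ``1..300`` becomes ``[0, 300)``.  Features of
    type ``gene`` are used; if the file annotates only CDS, those are used
    instead.  Records without a strand are rejected with a warning; a feature
    extending past ``genome_length`` is a hard error.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    featuretypes = set(db.featuretypes())
    ftype = "gene" if "gene" in featuretypes else "CDS"
    genes: list[Gene] = []
    for i, feat in enumerate(db.features_of_type(ftype)):
        if feat.strand not in _STRANDS:
            logger.warning("skipping %s %s: missing strand", ftype, feat.id or f"#{i}")
            continue
        start0, end0 = feat.start - 1, feat.end
        if end0 > genome_length:
            raise ValueError(
                f"feature {feat.id or f'#{i}'} ends at {end0} beyond genome length {genome_length}"
            )
        gid = feat.id or feat.attributes.get("ID", [f"{ftype}{i:05d}"])[0]
        genes.append(Gene(id=gid, start=start0, end=end0, strand=feat.strand))
    genes.sort(key=lambda g: (g.start, g.end, g.id))
    return genes


def write_gff3(genome_or_genes: GenomeAnnotation | Sequence[Gene], path: str | Path,
               *, name: str = "genome", length: int | None = None) -> None:
    """Write an annotation (or bare gene list) as GFF3.

    For a full :class:`GenomeAnnotation`, promoter and terminator point
    features are emitted alongside genes so the topology survives on disk.
    Output is deterministic: identical input produces an identical byte
    stream.
    """
    path = Path(path)
    lines = ["##gff-version 3"]
    if isinstance(genome_or_genes, GenomeAnnotation):
        genome = genome_or_genes
        seqid = genome.name
        lines.append(f"##sequence-region {seqid} 1 {genome.length}")
        if genome.circular:
            lines.append(f"# circular=true")
        rows: list[tuple[int, str]] = []
        for u in genome.units:
            for g in u.genes:
                rows.append((g.start, _gff_line(seqid, "gene", g.start, g.end, g.strand,
                                                f"ID={g.id};Parent={u.id}")))
            p = u.promoter
            rows.append((p.position, _gff_line(seqid, "promoter", p.position, p.position + 1,
                                               p.strand, f"ID={p.id};Parent={u.id}")))
            if u.terminator is not None:
                t = u.terminator
                rows.append((t.position, _gff_line(seqid, "terminator", t.position, t.position + 1,
                                                   t.strand,
                                                   f"ID={t.id};Parent={u.id};read_through={t.read_through_prob:g}")))
        rows.sort(key=lambda r: (r[0], r[1]))
        lines.extend(r[1] for r in rows)
    else:
        genes = sorted(genome_or_genes, key=lambda g: (g.start, g.end, g.id))
        if length is None:
            length = max((g.end for g in genes), default=1)
        lines.append(f"##sequence-region {name} 1 {length}")
        lines.extend(_gff_line(name, "gene", g.start, g.end, g.strand, f"ID={g.id}") for g in genes)
    path.write_text("\n".join(lines) + "\n")


def _gff_line(seqid: str, ftype: str, start0: int, end0: int, strand: str, attrs: str) -> str:
    # internal 0-based half-open -> GFF3 1-based inclusive
    return f"{seqid}\tsigmatrap\t{ftype}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}"


def infer_transcription_units(genes: Iterable[Gene], gap_threshold: int = 50,
                              *, unit_prefix: str = "TU") -> list[TranscriptionUnit]:
    """Group genes into operons by strand and intergenic gap.

    Consecutive same-strand genes whose intergenic gap is at most
    ``gap_threshold`` bp are merged into one transcription unit; a strand
    switch always breaks the unit.  Each unit receives a promoter point
    feature at its transcription start and a terminator at its transcription
    end.  Overlapping same-strand genes are merged into the running unit with
    a warning (real annotations contain overlaps, and merging preserves the
    no-internal-terminator semantics).

    The result is independent of input order (genes are sorted first) and
    idempotent in the sense that re-running on the same gene list yields the
    same units.
    """
    if gap_threshold < 0:
        raise ValueError("gap_threshold must be non-negative")
    genes = sorted(genes, key=lambda g: (g.start, g.end, g.id))
    blocks: list[list[Gene]] = []
    for g in genes:
        if blocks:
            prev_block = blocks[-1]
            prev = prev_block[-1]
            if g.strand == prev.strand:
                gap = g.start - prev.end
                if gap < 0:
                    logger.warning("overlapping same-strand genes %s and %s merged into one unit",
                                   prev.id, g.id)
                    prev_block.append(g)
                    continue
                if gap <= gap_threshold:
                    prev_block.append(g)
                    continue
        blocks.append([g])

    units: list[TranscriptionUnit] = []
    for i, block in enumerate(blocks):
        strand = block[0].strand
        uid = f"{unit_prefix}{i:05d}"
        lo = min(g.start for g in block)
        hi = max(g.end for g in block)
        if strand == FORWARD:
            ordered = tuple(block)
            prom_pos, term_pos = lo, hi
        else:
            ordered = tuple(reversed(block))
            # transcription start is the right edge; as a point coordinate the
            # last base of the unit (hi - 1) keeps features inside the genome
            prom_pos, term_pos = hi - 1, lo
        units.append(TranscriptionUnit(
            id=uid,
            strand=strand,
            genes=ordered,
            promoter=PromoterSite(id=f"P{i:05d}", position=prom_pos, strand=strand, parent_tu=uid),
            terminator=TerminatorSite(id=f"T{i:05d}", position=term_pos, strand=strand),
        ))
    return units


def annotation_from_gff3(path: str | Path, genome_length: int, *, circular: bool = False,
                         gap_threshold: int = 50, name: str | None = None) -> GenomeAnnotation:
    """Convenience: read genes, infer units, return a validated annotation."""
    genes = read_gff3(path, genome_length, circular)
    units = infer_transcription_units(genes, gap_threshold)
    genome = GenomeAnnotation(name=name or Path(path).stem, length=genome_length,
                              circular=circular, units=units)
    genome.validate()
    return genome


def write_inserts_bed(inserts, classifications, path: str | Path, *,
                      genome: GenomeAnnotation) -> None:
    """Write classified inserts as BED6 (0-based half-open).

    The name column carries the call (``GFP+``/``GFP-``) plus the firing
    promoter id or read-through cause; the strand column carries the insert
    orientation ('+' for orientation A, '-' for B).  An insert that wraps the
    circular origin is emitted as two lines sharing one name.
    """
    path = Path(path)
    lines = ["# BED6: chrom start end name score strand (insert orientation)"]
    for ins, cls in zip(inserts, classifications, strict=True):
        call = "GFP+" if cls.gfp_positive else "GFP-"
        if cls.cause == "read_through":
            name = f"{call}:read_through"
        elif cls.cause == "none":
            name = f"{call}:none"
        else:
            name = f"{call}:{cls.cause_id}"
        strand = FORWARD if ins.orientation == "A" else REVERSE
        end = ins.start + ins.length
        if end <= genome.length:
            lines.append(f"{genome.name}\t{ins.start}\t{end}\t{name}\t.\t{strand}")
        else:
            if not genome.circular:
                raise ValueError("insert wraps on a linear genome")
            lines.append(f"{genome.name}\t{ins.start}\t{genome.length}\t{name}\t.\t{strand}")
            lines.append(f"{genome.name}\t0\t{end - genome.length}\t{name}\t.\t{strand}")
    path.write_text("\n".join(lines) + "\n")
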