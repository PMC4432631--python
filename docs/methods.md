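# Methods

## The model

`sigmatrap` simulates promoter-trap reporter libraries on annotated
prokaryotic genomes. A trap library is built by randomly shearing genomic
DNA, cloning each fragment non-directionally upstream of a promoterless
reporter gene (here called GFP), and scoring the fraction of clones that
fluoresce. Because a clone fluoresces only when transcription initiated (or
entering) inside its insert reaches the reporter, the positive fraction
measures how many promoters the host RNA polymerase — optionally armed with
a heterologous sigma factor — can fire.

The simulation is purely **topological**: a genome is a set of transcription
units (operons), each a run of same-strand genes with one promoter point
feature at its transcription start and one terminator point feature at its
end. No nucleotide sequence is used anywhere; promoter strength, spacing
motifs and RBS effects are all outside the model.

### Classification rule

All intervals are 0-based half-open. An insert is `(start, length,
orientation)`; orientation A means the genome `+` strand reads toward the
reporter, B the reverse. The insert's *sense strand* is the strand reading
toward the reporter; its *reporter-proximal end* is the high-coordinate end
for A and the low end for B.

* **promoterless** (the trap): positive iff a recognized sense-strand
  promoter lies inside the insert with no sense-strand terminator strictly
  between it and the reporter-proximal end. A terminator exactly at the
  reporter-proximal boundary does not block (strict betweenness); a promoter
  exactly at the insert start is inside (half-open convention).
* **upstream_promoter** (the induction control, an inducible vector promoter
  ahead of the insert): positive iff no sense-strand terminator lies inside
  the insert. With `internal_rescue` on, a recognized sense promoter
  downstream of the reporter-proximal-most terminator refires transcription
  — i.e. rescue is exactly the promoterless rule. (A literal "downstream of
  the first blocking terminator" rule would let a rescued transcript run
  into a later terminator; we use the physically consistent form.)

Terminators carry a read-through probability ρ (default 0, absolute
termination). With ρ > 0, each terminator inside an insert is sampled once
per classification: it blocks with probability 1 − ρ. The vectorized paths
(exact enumeration, Monte Carlo) require ρ = 0; the scalar classifier
handles leaky terminators with an explicit RNG.

Ties among several firing promoters resolve to the reporter-proximal-most
one, which is also the transcript that physically reaches the reporter
first. Because promoters and terminators alternate along each strand in any
operon-consistent annotation, at most one promoter per placement is
eligible, which makes the positive indicator exactly Bernoulli(p·w) under
partial recognition — the property the recovery estimator relies on.

### Two computation routes

`gfp_fraction_exact` enumerates every placement — all starts on a circular
genome (inserts may wrap the origin; features are index-duplicated at
position + G), starts `[0, G − L]` on a linear genome — times both
orientations, at fixed length L. `estimate_gfp_fraction_mc` samples starts
uniformly, orientations Bernoulli(0.5) (non-directional cloning), and
lengths from the configured model, then classifies with the same vectorized
core. The two routes must agree within Monte-Carlo error; the test suite
checks this on a hand-enumerable toy genome (exact fractions 0.10 and
0.025) and on randomized synthetic genomes.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| insert length model | fixed 726 bp, or truncated normal in [200, 1000] | sequenced mean insert of the reference trap library; gel-purified band limits |
| mean gene length | 924 bp | average prokaryotic gene size; insert size is deliberately below it |
| genes per unit | geometric, mean 1.7 | matches observed operon-size decay; no published value to pin, so exposed as config |
| intergenic gap | exponential, mean 120 bp (20 bp within units) | typical prokaryotic feature density; likewise configurable |
| strand bias | 0.5 | no strand preference in real annotations |
| operon gap threshold (unit inference) | 50 bp | common prokaryotic operon-calling heuristic |
| terminator read-through ρ | 0 | the trap rule is absolute; ρ exposed to explore observed-vs-predicted gaps |
| recognition model | all / none / subset / Bernoulli(p) per promoter | recognition is a promoter property, not a per-cell event; Bernoulli sets are nested in p for a fixed seed |

## Synthetic genomes

The generator lays units head-to-tail with exponential gaps, drawing gene
lengths log-normal (arithmetic mean 924 bp, CV 0.5 by default) and unit
sizes geometric. One `numpy` Generator seeded once drives every draw in a
fixed order, so identical parameters give byte-identical GFF3 output. A
parameter sidecar records the seed and all settings.

What it emulates: transcription-unit topology, operonic grouping, strand
mixing, realistic feature density. What it does not: real promoter/terminator
annotation sources, sequence content, bidirectional terminators, overlapping
genes, nested or internal promoters, leaderless transcripts. Tests passing on
synthetic genomes therefore validate the *simulator's arithmetic and
invariants*, not the fidelity of any particular genome's annotation.

The "WCFS1-scale surrogate" used in the analyses is such a synthetic genome
sized to the 3.35-Mb *L. plantarum* WCFS1 genome (1,964 units ≈ target
length / expected unit span, seed fixed in `analysis/02`); it is a labelled
synthetic stand-in, not the RefSeq annotation.

## Library-scale predictions and the reconstruction gap

With per-operon topology, full recognition and L = 726, exact enumeration on
the surrogate gives ≈ 20% positive for the promoterless trap and ≈ 79% for
the induction control (≈ 87% with internal rescue). The published simulation
of the original screen predicted 25% and 62% for these two quantities. A
per-gene topology (every gene its own promoter and terminator) moves them to
≈ 32% and ≈ 66%. No single annotation convention reproduces both figures:
the published pair lies between one-terminator-per-operon and
one-terminator-per-gene conventions, and the annotation source behind the
published prediction is not publicly documented. `analysis/03`
reports both topologies and both rescue variants rather than tuning either;
the induction-control fraction is the quantity most sensitive to terminator
density, the trap fraction to promoter density.

## Recognized-fraction estimation

The recognized promoter fraction is estimated as observed positive fraction
over the predicted maximum (the positive fraction at full recognition),
clipped to [0, 1] with a flag. Applied to the published flow-cytometry
endpoints (23% with the heterologous sigma factor, 6.5% in the unmodified
host, 25% predicted maximum) it gives 0.92 and 0.26.

Across seeded simulated libraries the estimator varies through two binomial
sources: insert sampling and the per-promoter recognition draw. Its CI
(`recognized_fraction_ci`) therefore combines a Wilson interval on the
observed fraction (scaled by the predicted maximum) with a binomial
assignment term `p(1−p)/n_eff`, where `n_eff = (Σw)²/Σw²` uses each
promoter's exact firing weight (placements it fires, from enumeration). The
two half-widths are taken at α/2 each and summed — a Bonferroni-style
construction whose coverage is at least the nominal 95% (empirically ≈ 99%
in `analysis/04`). This conservatism is deliberate: underestimating the
assignment variance is the easy mistake here.

## Numerical choices and degenerate inputs

* Vectorized classification uses sorted-array binary search
  (`np.searchsorted`) per strand; circular wraparound is handled by
  duplicating feature positions at +G, so no modular arithmetic appears in
  hot paths. Exact enumeration over a 3.35-Mb genome (6.7M placements)
  takes a few seconds.
* Fold coverage is rounded to 1 decimal with ties half-up (`decimal`), the
  convention of the published tables; the unrounded value is always carried.
* Clarke–Carbon comparisons against published clone requirements use 0.2%
  relative tolerance because the genome sizes behind the published numbers
  are not printed; recomputation from RefSeq totals agrees within 0.12%.
* Degenerate inputs are errors, not silent defaults: wrapping inserts on
  linear genomes, fragments longer than the genome, empty recognition
  denominators, non-positive clone requirements, P or f outside (0, 1).
* Empty genomes (`n_units = 0`) are valid and produce empty summaries;
  genomes whose parameters imply more than 5M genes are refused with a
  message (memory guard).

## Problem sizes used in the shipped analyses

Exact enumeration runs at full surrogate scale (3.35 Mb). Monte-Carlo
estimates use n = 10⁵ inserts (s.e. ≤ 0.16 pp at p = 0.25). The recovery
experiment uses a 1.36-Mb genome (800 units), 2,000 inserts per library and
100 seeded libraries per true fraction — sizes at which the two CI
components are comparable, which is the regime the CI construction is meant
for.

## Known limitations

* Promoter recognition is binary per promoter; no strength, no induction
  kinetics, no fluorescence intensities, no sorting/enrichment.
* Terminators are points with strand-specific absolute (or iid leaky)
  action; real rho-independent terminators are often partially
  bidirectional.
* Unit inference from gene annotations is a heuristic (50-bp gap); curated
  operon maps would change promoter/terminator density and hence the
  predicted fractions — this is exactly the sensitivity documented above.
* Multi-replicon genomes are handled by concatenation only.
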