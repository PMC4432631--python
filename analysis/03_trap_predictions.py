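"""Predict reporter-positive library fractions at published library scale.

On the WCFS1-scale surrogate genome with 726-bp inserts and full promoter
recognition, this computes by exact placement enumeration the positive
fraction of the promoterless trap and of the upstream-promoter (induction
control) vector, under two terminator-annotation conventions:

* per-operon: one promoter and one terminator per transcription unit (the
  package's default topology), and
* per-gene: every gene carries its own promoter and terminator — the
  densest plausible annotation.

plus a Monte-Carlo run with gel-band insert lengths (truncated normal
200-1,000 bp, mean 726) to show length dispersion barely moves the numbers.
Writes results/trap_predictions.tsv.
"""

from pathlib import Path

import pandas as pd

from sigmatrap import (
    FragmentLengthModel,
    GenomeAnnotation,
    PromoterSite,
    SigmaRecognitionModel,
    TerminatorSite,
    TranscriptionUnit,
    VectorMode,
    estimate_gfp_fraction_mc,
    generate_genome,
    gfp_fraction_exact,
)

import importlib.util as _ilu
_spec = _ilu.spec_from_file_location("synth", Path(__file__).parent / "02_synthetic_genome.py")
_synth = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_synth)

RESULTS = Path(__file__).resolve().parent.parent / "results"
ALL = SigmaRecognitionModel("all")
L = 726

MODES = [
    ("promoterless", VectorMode("promoterless")),
    ("upstream_promoter", VectorMode("upstream_promoter")),
    ("upstream_promoter+rescue", VectorMode("upstream_promoter", internal_rescue=True)),
]


def per_gene_variant(genome: GenomeAnnotation) -> GenomeAnnotation:
    """Same genes, but every gene is its own unit with its own terminator."""
    units = []
    for i, gene in enumerate(genome.genes()):
        uid = f"U{i}"
        if gene.strand == "+":
            prom_pos, term_pos = gene.start, gene.end
        else:
            prom_pos, term_pos = gene.end - 1, gene.start
        units.append(TranscriptionUnit(
            uid, gene.strand, (gene,),
            PromoterSite(f"p{i}", prom_pos, gene.strand, uid),
            TerminatorSite(f"t{i}", term_pos, gene.strand)))
    variant = GenomeAnnotation(genome.name + "_per_gene", genome.length,
                               genome.circular, units)
    variant.validate()
    return variant


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    operon_genome = generate_genome(_synth.SURROGATE)
    rows = []
    for topo, genome in [("per-operon", operon_genome),
                         ("per-gene", per_gene_variant(operon_genome))]:
        for label, mode in MODES:
            frac = gfp_fraction_exact(genome, mode, ALL, L)
            rows.append({"topology": topo, "mode": label, "method": f"exact (L={L})",
                         "gfp_positive_pct": round(100 * frac, 2)})

    band = FragmentLengthModel("truncated_normal", mean_bp=726, sd_bp=200,
                               min_bp=200, max_bp=1000)
    for label, mode in MODES[:2]:
        est = estimate_gfp_fraction_mc(operon_genome, mode, ALL, band, 100_000, seed=2)
        rows.append({"topology": "per-operon", "mode": label,
                     "method": "MC, 200-1000 bp band",
                     "gfp_positive_pct": round(100 * est.fraction, 2)})

    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "trap_predictions.tsv", sep="\t", index=False)
    print(df.to_string(index=False))

    get = lambda topo, mode: df[(df["topology"] == topo) & (df["mode"] == mode)
                                & df["method"].str.startswith("exact")]["gfp_positive_pct"].iloc[0]
    print()
    print("Findings:")
    print(f"  * promoterless trap ceiling: {get('per-operon', 'promoterless'):.1f}% of inserts")
    print(f"    (per-operon promoters) to {get('per-gene', 'promoterless'):.1f}% (per-gene);")
    print(f"  * induction control: {get('per-operon', 'upstream_promoter'):.1f}% read-through")
    print(f"    with per-operon terminators vs {get('per-gene', 'upstream_promoter'):.1f}% per-gene —")
    print("    the published prediction pair (25%, 62%) falls between the two")
    print("    topologies, i.e. between one terminator per operon and one per gene;")
    print("  * internal-promoter rescue raises the control fraction further and")
    print("    cannot explain a lower observed value.")


if __name__ == "__main__":
    main()
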