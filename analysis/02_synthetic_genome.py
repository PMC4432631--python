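"""Generate the WCFS1-scale synthetic surrogate genome and summarize it.

The surrogate emulates the annotation statistics of the 3.35-Mb L. plantarum
WCFS1 genome: mean gene length 924 bp (log-normal, CV 0.5), operons of
geometric size (mean 1.7 genes), exponential intergenic gaps (mean 120 bp),
units on both strands, circular.  The unit count (1,964) is the target
genome size divided by the expected unit span.

The summary lands in results/; the full GFF3 (several hundred kB) goes to
scratch/ since only its summary statistics matter downstream — every
consumer regenerates the genome from the seed.
"""

import json
from dataclasses import asdict
from pathlib import Path

from sigmatrap import SyntheticGenomeParams, generate_genome, summarize_genome, write_genome

ROOT = Path(__file__).resolve().parent.parent
RESULTS, SCRATCH = ROOT / "results", ROOT / "scratch"

SURROGATE = SyntheticGenomeParams(n_units=1964, seed=42, name="wcfs1_surrogate")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    genome = generate_genome(SURROGATE)
    sidecar = write_genome(genome, SURROGATE, SCRATCH / "wcfs1_surrogate.gff3")
    summary = summarize_genome(genome)
    (RESULTS / "surrogate_genome_summary.json").write_text(
        json.dumps({"params": asdict(SURROGATE), "summary": asdict(summary)}, indent=2) + "\n")

    print(f"surrogate genome: {summary.genome_length:,} bp, {summary.n_units:,} units, "
          f"{summary.n_genes:,} genes")
    print(f"mean gene length {summary.mean_gene_bp:.1f} bp (target 924), "
          f"strand split {summary.n_units_forward}/{summary.n_units_reverse}")
    print(f"GFF3 + sidecar written under scratch/ ({sidecar.name})")


if __name__ == "__main__":
    main()
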