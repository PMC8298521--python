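#!/usr/bin/env python
"""Refine the candidate interval by two-point linkage.

Uses the individually genotyped segregants from step 01 in two rounds: a
sparse genome-spanning panel (every 20th marker) followed by every marker
inside the round-one interval.  The refined interval is bounded by the
nearest flanking markers that still show recombinants with the phenotype.
"""

from pathlib import Path

from mossmap.cross import load_genotype_table
from mossmap.genome import load_marker_map, write_bed
from mossmap.linkage import two_round_refine

OUT = Path("results/analysis")
CHROM_LENGTH = 20_000_000


def main() -> None:
    geno = load_genotype_table(OUT / "genotypes.tsv")
    markers = load_marker_map(OUT / "markers.tsv")
    n_inf = int((geno.phenotype != "undetermined").sum())
    print(f"{len(geno)} segregants ({n_inf} with scored phenotype), "
          f"{len(markers)} markers available")

    interval, link = two_round_refine(geno, markers.to_frame(), "chr1",
                                      CHROM_LENGTH, coarse_every=20)
    link.to_csv(OUT / "linkage.tsv", sep="\t", index=False, na_rep="NA")
    write_bed([interval], OUT / "refined_interval.bed", ["refined"])

    zero = link[link.n_recombinant == 0]
    print(f"round 2 genotyped {len(link)} markers; "
          f"{len(zero)} fully cosegregating")
    print(f"refined interval: {interval.chrom}:{interval.start:,}-"
          f"{interval.end:,} ({interval.length_kb} kb)")


if __name__ == "__main__":
    main()
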