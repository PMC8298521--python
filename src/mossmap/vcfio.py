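"""Minimal VCF round-trip for pooled allele depths.

The bulk depth table can travel as an uncompressed VCF with one sample
("bulk") whose AD field holds (gd_depth, vx_depth) — REF is the Gd allele,
ALT the Vx allele.  pysam handles the format; the TSV in
:mod:`mossmap.cross` remains the primary interchange form.
"""

from __future__ import annotations

import pandas as pd
import pysam

from .cross import DEPTH_COLUMNS
from .genome import MarkerMap, ToyGenome


def write_depth_vcf(depths: pd.DataFrame, markers: MarkerMap,
                    genome: ToyGenome, path) -> None:
    header = pysam.VariantHeader()
    for chrom in genome:
        header.contigs.add(chrom.name, length=chrom.length)
    header.formats.add("AD", number="R", type="Integer",
                       description="Allelic depths (Gd ref, Vx alt)")
    header.add_sample("bulk")
    alleles = {m.id: (m.gd_allele, m.vx_allele) for m in markers}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in depths.itertuples():
            gd, vx = alleles[row.id]
            rec = vcf.new_record(contig=row.chrom, start=row.pos_bp - 1,
                                 stop=row.pos_bp, alleles=(gd, vx), id=row.id)
            rec.samples["bulk"]["AD"] = (int(row.gd_depth), int(row.vx_depth))
            vcf.write(rec)


def load_depth_vcf(path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ad = rec.samples["bulk"]["AD"]
            rows.append((rec.contig, rec.pos, rec.id, int(ad[0]), int(ad[1])))
    return pd.DataFrame(rows, columns=DEPTH_COLUMNS)
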