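"""Toy-scale variant-effect classification and the candidate filter.

Single-nucleotide variants are placed against single-isoform gene models:
coding changes are classified at the codon level with the standard nuclear
genetic code (synonymous / missense / stop_gained / stop_lost / start_lost),
intronic positions within 2 bp of an exon boundary are splice_site (the
canonical GT/AG dinucleotides), and the candidate filter retains the
nonsynonymous classes — missense and stop_gained — inside the mapped
interval, optionally adding splice_site.

Protein changes use one-letter residues with "X" for a stop codon, e.g. a
Gln codon CAG mutated to TAG at codon 598 is reported as Q598X.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome import GeneModel, GenomicInterval, ToyGenome

# Standard nuclear genetic code; "*" denotes a stop codon.
CODON_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SPLICE_WINDOW = 2  # bp into the intron at each junction

CODING_EFFECTS = {"synonymous", "missense", "stop_gained", "stop_lost", "start_lost"}
VARIANT_COLUMNS = ["chrom", "pos_bp", "ref_base", "alt_base", "gene_id",
                   "effect", "protein_change"]


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon not in CODON_TABLE:
        raise ValueError(f"invalid codon {codon!r}")
    return CODON_TABLE[codon]


def classify_codon_change(ref_codon: str, alt_codon: str) -> tuple[str, str]:
    """Effect of a codon substitution: (effect, 'Q>X'-style residue change).

    stop_gained: residue -> stop; stop_lost: stop -> residue; synonymous:
    same translation (including stop -> stop); missense otherwise.
    """
    aa_ref = translate_codon(ref_codon)
    aa_alt = translate_codon(alt_codon)
    if aa_ref == aa_alt:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "stop_gained"
    elif aa_ref == "*":
        effect = "stop_lost"
    else:
        effect = "missense"
    disp = lambda aa: "X" if aa == "*" else aa
    return effect, f"{disp(aa_ref)}>{disp(aa_alt)}"


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos_bp: int
    ref_base: str
    alt_base: str
    gene_id: str | None
    effect: str
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if (self.effect == "intergenic") != (self.gene_id is None):
            raise ValueError("intergenic iff no gene_id")
        if self.protein_change is not None and self.effect not in CODING_EFFECTS:
            raise ValueError("protein_change only applies to coding effects")


def _splice_or_intron(gene: GeneModel, pos: int) -> str:
    exons = gene.cds_exons
    for a, b in zip(exons, exons[1:]):
        if a.end < pos < b.start:
            dist = min(pos - a.end, b.start - pos)
            return "splice_site" if dist <= SPLICE_WINDOW else "intronic"
    raise AssertionError("position not intronic")  # caller guarantees


def classify_variant(genome: ToyGenome, genes: list[GeneModel],
                     snv: tuple[str, int, str, str]) -> VariantCall:
    """Classify one SNV against the genome and gene models.

    The reference base must match the genome.  Positions inside a CDS are
    located to their codon (strand-aware) and classified with
    :func:`classify_codon_change`; codon 1 changes that destroy the ATG
    start are start_lost.
    """
    chrom, pos, ref, alt = snv
    ref, alt = ref.upper(), alt.upper()
    genome_base = genome.base_at(chrom, pos)
    if genome_base != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: genome has {genome_base!r}, "
            f"variant says {ref!r}"
        )
    if ref == alt:
        raise ValueError(f"{chrom}:{pos}: ref and alt are both {ref!r}")
    for gene in genes:
        if not gene.span.contains(chrom, pos):
            continue
        off = gene.cds_offset(pos)
        if off is None:
            cds_lo = min(e.start for e in gene.cds_exons)
            cds_hi = max(e.end for e in gene.cds_exons)
            if pos < cds_lo or pos > cds_hi:
                return VariantCall(chrom, pos, ref, alt, gene.gene_id, "utr")
            return VariantCall(chrom, pos, ref, alt, gene.gene_id,
                               _splice_or_intron(gene, pos))
        cds = gene.cds_sequence(genome)
        codon_idx = off // 3 + 1
        within = off % 3
        ref_codon = cds[off - within : off - within + 3]
        alt_cds_base = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
        alt_codon = (ref_codon[:within] + alt_cds_base + ref_codon[within + 1 :])
        effect, change = classify_codon_change(ref_codon, alt_codon)
        if codon_idx == 1 and ref_codon == "ATG" and effect != "synonymous":
            effect = "start_lost"
        aa_ref, aa_alt = change.split(">")
        return VariantCall(chrom, pos, ref, alt, gene.gene_id, effect,
                           f"{aa_ref}{codon_idx}{aa_alt}")
    return VariantCall(chrom, pos, ref, alt, None, "intergenic")


def classify_variants(genome: ToyGenome, genes: list[GeneModel],
                      snvs: list[tuple[str, int, str, str]]) -> list[VariantCall]:
    return [classify_variant(genome, genes, s) for s in snvs]


RETAINED_EFFECTS = frozenset({"missense", "stop_gained"})
_REPORT_RANK = {"stop_gained": 0, "splice_site": 1, "missense": 2}


def filter_candidates(variants: list[VariantCall], interval: GenomicInterval,
                      include_splice: bool = False) -> list[VariantCall]:
    """Candidate filter: nonsynonymous and nonsense changes inside the interval.

    Keeps missense and stop_gained (plus splice_site when ``include_splice``),
    sorted by position.  Idempotent; output is always a subset of the input.
    """
    keep = set(RETAINED_EFFECTS)
    if include_splice:
        keep.add("splice_site")
    out = [v for v in variants
           if v.effect in keep and interval.contains(v.chrom, v.pos_bp)]
    out.sort(key=lambda v: (v.chrom, v.pos_bp))
    return out


def rank_for_report(candidates: list[VariantCall]) -> list[VariantCall]:
    """Report order: stop_gained above splice_site above missense, then position."""
    return sorted(candidates,
                  key=lambda v: (_REPORT_RANK.get(v.effect, 9), v.chrom, v.pos_bp))


# ---------------------------------------------------------------------------
# Tabular I/O


def variants_to_frame(variants: list[VariantCall],
                      interval: GenomicInterval | None = None) -> pd.DataFrame:
    rows = []
    for v in variants:
        row = (v.chrom, v.pos_bp, v.ref_base, v.alt_base,
               v.gene_id if v.gene_id is not None else "NA",
               v.effect, v.protein_change if v.protein_change else "NA")
        rows.append(row)
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    if interval is not None:
        df["in_interval"] = [interval.contains(v.chrom, v.pos_bp) for v in variants]
    return df


def load_snv_table(path) -> list[tuple[str, int, str, str]]:
    """SNVs from a TSV with columns chrom,pos_bp,ref,alt (header required)."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    need = ["chrom", "pos_bp", "ref", "alt"]
    missing = [c for c in need if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing SNV columns {missing}")
    return [(str(r[cols['chrom']]), int(r[cols['pos_bp']]),
             str(r[cols['ref']]), str(r[cols['alt']]))
            for _, r in df.iterrows()]
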