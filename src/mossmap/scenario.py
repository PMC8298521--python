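"""Ready-made synthetic scenarios at the study's conditions.

The standard mapping scenario is one 20 Mb chromosome carrying a 100 cM
linear genetic map with 2,000 evenly spaced markers and the causal
stop-gained mutation at 10 Mb; the cross produces 192 haploid progeny from
which a 48-member downward-growing bulk is drawn and pool-sequenced at a
mean of 50 reads per marker with 1% allele-flip error.  Builders here also
assemble sequence-bearing toy genomes with embedded gene models and planted
variants so the annotation stage can run end to end.
"""

from __future__ import annotations

import numpy as np

from .cross import CrossConfig
from .genome import (Chromosome, GeneModel, GenomicInterval, Marker, MarkerMap,
                     ToyGenome)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

DEFAULT_CHROM_LENGTH = 20_000_000
DEFAULT_TOTAL_CM = 100.0
DEFAULT_N_MARKERS = 2000
DEFAULT_CAUSAL_POS = 10_000_000


def random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    """Random A/C/G/T sequence as a mutable uint8 array."""
    return _BASES[rng.integers(0, 4, size=length)]


def make_toy_genome(lengths: dict[str, int], rng: np.random.Generator | None = None,
                    with_sequence: bool = False) -> ToyGenome:
    chroms = []
    for name, length in lengths.items():
        seq = None
        if with_sequence:
            if rng is None:
                raise ValueError("with_sequence requires an rng")
            seq = random_sequence(length, rng).tobytes().decode()
        chroms.append(Chromosome(name, length, seq))
    return ToyGenome(tuple(chroms))


def make_marker_map(genome: ToyGenome, n_markers: int,
                    total_cM: float = DEFAULT_TOTAL_CM,
                    rng: np.random.Generator | None = None) -> MarkerMap:
    """Evenly spaced markers with a linear cM map on every chromosome.

    With a sequence present the Gd allele is the reference base (the mutant
    strain is the reference background); the Vx allele is a random different
    base.  Without a sequence, alleles default to G-strand/V-strand dummy
    bases A/C.
    """
    markers = []
    for chrom in genome:
        spacing = chrom.length / n_markers
        for i in range(1, n_markers + 1):
            pos = int(round(i * spacing))
            pos = min(max(pos, 1), chrom.length)
            cM = pos / chrom.length * total_cM
            if chrom.sequence is not None:
                gd = chrom.sequence[pos - 1]
                if gd == "N":
                    continue
                choices = [b for b in "ACGT" if b != gd]
                vx = choices[int(rng.integers(0, 3))] if rng is not None else choices[0]
            else:
                gd, vx = "A", "C"
            markers.append(Marker(chrom.name, pos, cM,
                                  f"{chrom.name}_m{i:05d}", gd, vx))
    return MarkerMap(tuple(markers))


# ---------------------------------------------------------------------------
# Gene embedding


def _random_codons(n: int, rng: np.random.Generator) -> list[str]:
    out = []
    while len(out) < n:
        codon = "".join(chr(b) for b in _BASES[rng.integers(0, 4, size=3)])
        if codon in _STOPS or codon == "ATG":
            continue
        out.append(codon)
    return out


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def make_gene(seq_array: np.ndarray, gene_id: str, chrom: str, start: int,
              strand: str, n_codons: int, exon_codon_splits: list[int],
              intron_length: int, rng: np.random.Generator,
              codon_overrides: dict[int, str] | None = None) -> GeneModel:
    """Embed a valid protein-coding gene into a mutable chromosome array.

    The CDS is ATG + random non-stop codons + stop, with ``codon_overrides``
    forcing specific codons (1-based codon index).  ``exon_codon_splits``
    gives the cumulative codon counts at which the CDS is cut into exons;
    introns get canonical GT..AG donor/acceptor dinucleotides in
    transcription orientation.  Returns the GeneModel; the array is modified
    in place.
    """
    codons = ["ATG"] + _random_codons(n_codons - 2, rng) + ["TAA"]
    for idx, codon in (codon_overrides or {}).items():
        if not 1 < idx < n_codons:
            raise ValueError("cannot override the start or stop codon")
        if codon in _STOPS:
            raise ValueError("override would truncate the toy CDS")
        codons[idx - 1] = codon
    cds = "".join(codons)
    bounds = [0] + [3 * c for c in exon_codon_splits] + [len(cds)]
    if sorted(bounds) != bounds or len(set(bounds)) != len(bounds):
        raise ValueError("exon_codon_splits must be strictly increasing")
    pieces = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
    introns = []
    for _ in range(len(pieces) - 1):
        body = random_sequence(intron_length - 4, rng).tobytes().decode()
        introns.append("GT" + body + "AG")
    # assemble in transcription order, then orient onto the plus strand
    tx = pieces[0]
    for intron, piece in zip(introns, pieces[1:]):
        tx += intron + piece
    plus = tx if strand == "+" else _revcomp(tx)
    end = start + len(plus) - 1
    if start < 1 or end > len(seq_array):
        raise ValueError(f"gene {gene_id} does not fit the chromosome")
    seq_array[start - 1 : end] = np.frombuffer(plus.encode(), dtype=np.uint8)
    # exon coordinates: transcription-order offsets -> genomic intervals
    exons_tx = []
    off = 0
    for i, piece in enumerate(pieces):
        exons_tx.append((off, off + len(piece) - 1))
        off += len(piece) + (len(introns[i]) if i < len(introns) else 0)
    intervals = []
    for a, b in exons_tx:
        if strand == "+":
            intervals.append(GenomicInterval(chrom, start + a, start + b))
        else:
            intervals.append(GenomicInterval(chrom, end - b, end - a))
    return GeneModel(gene_id, chrom, strand, tuple(intervals))


def plant_snv(gene: GeneModel, genome: ToyGenome, codon_index: int,
              within_codon: int, alt_cds_base: str) -> tuple[str, int, str, str]:
    """An SNV defined at the CDS level, returned in genomic (chrom,pos,ref,alt)."""
    off = 3 * (codon_index - 1) + within_codon
    pos = gene.genomic_position(off)
    ref = genome.base_at(gene.chrom, pos)
    alt = alt_cds_base if gene.strand == "+" else _revcomp(alt_cds_base)
    if alt == ref:
        raise ValueError("planted SNV does not change the reference base")
    return gene.chrom, pos, ref, alt


# ---------------------------------------------------------------------------
# Standard scenarios


def bsa_scenario(seed: int,
                 chrom_length: int = DEFAULT_CHROM_LENGTH,
                 total_cM: float = DEFAULT_TOTAL_CM,
                 n_markers: int = DEFAULT_N_MARKERS,
                 causal_pos: int = DEFAULT_CAUSAL_POS,
                 **config_kwargs) -> CrossConfig:
    """The standard single-chromosome pooled-mapping scenario (no sequence)."""
    genome = make_toy_genome({"chr1": chrom_length})
    markers = make_marker_map(genome, n_markers, total_cM)
    return CrossConfig(genome=genome, markers=markers,
                       causal_locus=("chr1", causal_pos), seed=seed,
                       **config_kwargs)


def unlinked_scenario(seed: int, **config_kwargs) -> CrossConfig:
    """Two-chromosome variant: causal locus on chr1, chr2 fully unlinked.

    Markers on chr2 assort independently of the selected phenotype
    (recombination fraction exactly 1/2), providing the unlinked baseline
    of the pooled ratio statistic.
    """
    genome = make_toy_genome({"chr1": DEFAULT_CHROM_LENGTH,
                              "chr2": DEFAULT_CHROM_LENGTH})
    markers = make_marker_map(genome, DEFAULT_N_MARKERS, DEFAULT_TOTAL_CM)
    return CrossConfig(genome=genome, markers=markers,
                       causal_locus=("chr1", DEFAULT_CAUSAL_POS), seed=seed,
                       **config_kwargs)


def mapping_scenario(seed: int, chrom_length: int = DEFAULT_CHROM_LENGTH):
    """Sequence-bearing scenario with embedded genes and planted variants.

    Returns (config, genes, snvs).  The causal gene sits at the causal locus
    and carries a stop-gained mutation at codon 598 (Gln CAG -> TAG); decoys
    exercise every branch of the candidate filter: an in-interval missense,
    an in-interval synonymous and intronic change, and an out-of-interval
    stop-gained.
    """
    rng = np.random.default_rng(seed)
    seq = random_sequence(chrom_length, rng)
    genes = []

    causal_start = DEFAULT_CAUSAL_POS
    causal = make_gene(seq, "gene_causal", "chr1", causal_start, "+",
                       n_codons=650, exon_codon_splits=[200, 450],
                       intron_length=200, rng=rng,
                       codon_overrides={598: "CAG"})
    genes.append(causal)
    decoy_mis = make_gene(seq, "gene_decoy_missense", "chr1",
                          causal_start + 400_000, "-", n_codons=300,
                          exon_codon_splits=[150], intron_length=150, rng=rng,
                          codon_overrides={100: "GAA"})
    genes.append(decoy_mis)
    decoy_syn = make_gene(seq, "gene_decoy_synonymous", "chr1",
                          causal_start - 300_000, "+", n_codons=200,
                          exon_codon_splits=[100], intron_length=150, rng=rng,
                          codon_overrides={50: "CAG"})
    genes.append(decoy_syn)
    far = make_gene(seq, "gene_far_stop", "chr1", 3_000_000, "+",
                    n_codons=250, exon_codon_splits=[], intron_length=0,
                    rng=rng, codon_overrides={80: "CAG"})
    genes.append(far)

    genome = ToyGenome((Chromosome("chr1", chrom_length,
                                   seq.tobytes().decode()),))
    markers = make_marker_map(genome, DEFAULT_N_MARKERS, DEFAULT_TOTAL_CM, rng)

    causal_snv = plant_snv(causal, genome, 598, 0, "T")  # CAG > TAG, Q598X
    snvs = [
        causal_snv,
        plant_snv(decoy_mis, genome, 100, 1, "T"),     # GAA > GTA, E100V
        plant_snv(decoy_syn, genome, 50, 2, "A"),      # CAG > CAA, synonymous
        plant_snv(far, genome, 80, 0, "T"),            # stop gained, far away
    ]
    # intronic decoy: 20 bp into the causal gene's first intron
    intron_pos = causal.cds_exons[0].end + 20
    ref = genome.base_at("chr1", intron_pos)
    alt = "A" if ref != "A" else "G"
    snvs.append(("chr1", intron_pos, ref, alt))
    # intergenic decoy
    inter_pos = 5_000_000
    ref = genome.base_at("chr1", inter_pos)
    alt = "C" if ref != "C" else "T"
    snvs.append(("chr1", inter_pos, ref, alt))
    snvs.sort(key=lambda s: s[1])

    config = CrossConfig(genome=genome, markers=markers,
                         causal_locus=("chr1", causal_snv[1]), seed=seed)
    return config, genes, snvs
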