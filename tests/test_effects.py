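"""Variant-effect classification against translate-and-compare oracles, and
the nonsynonymous/nonsense candidate filter."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from mossmap.effects import (VariantCall, classify_codon_change,
                             classify_variant, filter_candidates,
                             rank_for_report, translate_codon)
from mossmap.genome import Chromosome, GeneModel, GenomicInterval, ToyGenome
from mossmap.scenario import make_gene, random_sequence

ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]


def oracle_effect(ref_codon, alt_codon):
    """Independent oracle: translate both codons with Biopython and compare."""
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "stop_gained"
    if aa_ref == "*":
        return "stop_lost"
    return "missense"


class TestClassifyCodonChange:
    @pytest.mark.parametrize("ref,alt,effect", [
        ("CAG", "TAG", "stop_gained"),   # Gln -> premature stop
        ("CAG", "TAA", "stop_gained"),   # the Q>X change, CAG > TAA
        ("CAG", "CAA", "synonymous"),    # Gln unchanged
        ("AGT", "TCA", "synonymous"),    # Ser by either codon
        ("TAA", "CAA", "stop_lost"),
        ("GAA", "GTA", "missense"),
    ])
    def test_named_codon_changes(self, ref, alt, effect):
        got, change = classify_codon_change(ref, alt)
        assert got == effect
        if effect == "stop_gained":
            assert change.endswith(">X")

    def test_exhaustive_against_translation_oracle(self):
        """All 4,096 ref/alt codon pairs agree with the Biopython oracle."""
        for ref in ALL_CODONS:
            for alt in ALL_CODONS:
                assert classify_codon_change(ref, alt)[0] == \
                    oracle_effect(ref, alt), (ref, alt)

    def test_invalid_codon_rejected(self):
        with pytest.raises(ValueError):
            translate_codon("CAN")
        with pytest.raises(ValueError):
            classify_codon_change("CA", "CAG")


def build_toy_gene(seed, strand="+", n_codons=120):
    rng = np.random.default_rng(seed)
    seq = random_sequence(50_000, rng)
    gene = make_gene(seq, "toy1", "chrT", 10_001, strand, n_codons,
                     exon_codon_splits=[40, 80], intron_length=100, rng=rng,
                     codon_overrides={60: "CAG"})
    genome = ToyGenome((Chromosome("chrT", 50_000, seq.tobytes().decode()),))
    return genome, gene


def oracle_classify(genome, gene, pos, alt):
    """Full-translation oracle: rebuild the mutant chromosome, re-extract the
    CDS, translate both proteins and diff them."""
    chrom = genome.chromosome(gene.chrom)
    mutant_seq = chrom.sequence[: pos - 1] + alt + chrom.sequence[pos:]
    mutant = ToyGenome((Chromosome(gene.chrom, chrom.length, mutant_seq),))
    ref_prot = str(Seq(gene.cds_sequence(genome)).translate())
    alt_prot = str(Seq(gene.cds_sequence(mutant)).translate())
    if ref_prot == alt_prot:
        return "synonymous", None
    diffs = [i for i, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
    i = diffs[0]
    a, b = ref_prot[i], alt_prot[i]
    if b == "*":
        eff = "stop_gained"
    elif a == "*":
        eff = "stop_lost"
    elif i == 0 and a == "M":
        eff = "start_lost"
    else:
        eff = "missense"
    disp = lambda x: "X" if x == "*" else x
    return eff, f"{disp(a)}{i + 1}{disp(b)}"


class TestClassifyVariant:
    def test_stop_gain_at_codon_598_reported_as_Q598X(self):
        rng = np.random.default_rng(4)
        seq = random_sequence(30_000, rng)
        gene = make_gene(seq, "big", "chrT", 1_001, "+", 650,
                         exon_codon_splits=[300], intron_length=200, rng=rng,
                         codon_overrides={598: "CAG"})
        genome = ToyGenome((Chromosome("chrT", 30_000, seq.tobytes().decode()),))
        pos = gene.genomic_position(3 * 597)
        call = classify_variant(genome, [gene], ("chrT", pos, "C", "T"))
        assert call.effect == "stop_gained"
        assert call.protein_change == "Q598X"

    def test_splice_site_and_intronic_windows(self):
        genome, gene = build_toy_gene(7)
        donor = gene.cds_exons[0].end
        for offset, expected in [(1, "splice_site"), (2, "splice_site"),
                                 (3, "intronic"), (50, "intronic")]:
            pos = donor + offset
            ref = genome.base_at("chrT", pos)
            alt = "A" if ref != "A" else "G"
            call = classify_variant(genome, [gene], ("chrT", pos, ref, alt))
            assert call.effect == expected, offset

    def test_intergenic_far_from_any_gene(self):
        genome, gene = build_toy_gene(8)
        pos = 40_000
        ref = genome.base_at("chrT", pos)
        alt = "C" if ref != "C" else "T"
        call = classify_variant(genome, [gene], ("chrT", pos, ref, alt))
        assert call.effect == "intergenic"
        assert call.gene_id is None and call.protein_change is None

    def test_reference_mismatch_names_position_and_bases(self):
        genome, gene = build_toy_gene(9)
        pos = 40_000
        ref = genome.base_at("chrT", pos)
        wrong = "A" if ref != "A" else "C"
        with pytest.raises(ValueError, match=f"{pos}"):
            classify_variant(genome, [gene], ("chrT", pos, wrong, "G"))

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_random_coding_snvs_match_full_translation_oracle(self, strand):
        """200 random coding SNVs agree with an oracle that rebuilds and
        translates the whole mutant CDS (both strands)."""
        genome, gene = build_toy_gene(11 if strand == "+" else 12, strand)
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 200:
            off = int(rng.integers(0, gene.cds_length))
            pos = gene.genomic_position(off)
            ref = genome.base_at("chrT", pos)
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt == ref:
                continue
            call = classify_variant(genome, [gene], ("chrT", pos, ref, alt))
            eff, change = oracle_classify(genome, gene, pos, alt)
            assert call.effect == eff, (off, pos, ref, alt)
            if eff not in ("synonymous", "start_lost"):
                assert call.protein_change == change
            checked += 1

    def test_minus_strand_equals_reverse_complement_construction(self):
        """A minus-strand gene classifies identically to the same gene built
        on the plus strand of the reverse-complemented chromosome."""
        genome, gene = build_toy_gene(21, "-")
        chrom = genome.chromosome("chrT")
        rc_seq = str(Seq(chrom.sequence).reverse_complement())
        rc_genome = ToyGenome((Chromosome("chrT", chrom.length, rc_seq),))
        L = chrom.length
        rc_exons = tuple(sorted(
            (GenomicInterval("chrT", L - e.end + 1, L - e.start + 1)
             for e in gene.cds_exons), key=lambda e: e.start))
        rc_gene = GeneModel(gene.gene_id, "chrT", "+", rc_exons)
        rng = np.random.default_rng(5)
        for _ in range(50):
            off = int(rng.integers(0, gene.cds_length))
            pos = gene.genomic_position(off)
            ref = genome.base_at("chrT", pos)
            alt = next(b for b in "ACGT" if b != ref)
            call = classify_variant(genome, [gene], ("chrT", pos, ref, alt))
            rc_pos = L - pos + 1
            rc_ref = rc_genome.base_at("chrT", rc_pos)
            rc_alt = str(Seq(alt).reverse_complement())
            rc_call = classify_variant(rc_genome, [rc_gene],
                                       ("chrT", rc_pos, rc_ref, rc_alt))
            assert call.effect == rc_call.effect
            assert call.protein_change == rc_call.protein_change


def toy_calls(interval_chrom="chr1"):
    mk = lambda pos, eff, gene, pc=None: VariantCall(
        interval_chrom, pos, "A", "T", gene, eff, pc)
    return [
        mk(1_000, "synonymous", "gA", "K1K"),
        mk(2_000, "missense", "gB", "K2E"),
        mk(3_000, "stop_gained", "gC", "Q3X"),
        mk(4_000, "intronic", "gD"),
        VariantCall(interval_chrom, 5_000, "A", "T", None, "intergenic"),
    ]


class TestFilterCandidates:
    def test_five_variant_toy_set(self):
        """Of {synonymous, missense, stop_gained, intronic, intergenic} inside
        the interval, exactly the missense and stop_gained survive."""
        interval = GenomicInterval("chr1", 1, 10_000)
        kept = filter_candidates(toy_calls(), interval)
        assert [v.effect for v in kept] == ["missense", "stop_gained"]

    def test_stop_gained_outside_interval_dropped(self):
        interval = GenomicInterval("chr1", 1, 2_500)
        kept = filter_candidates(toy_calls(), interval)
        assert [v.effect for v in kept] == ["missense"]

    def test_subset_and_idempotent(self):
        interval = GenomicInterval("chr1", 1, 10_000)
        calls = toy_calls()
        kept = filter_candidates(calls, interval)
        assert set(kept) <= set(calls)
        assert filter_candidates(kept, interval) == kept

    def test_splice_flag_and_report_ranking(self):
        interval = GenomicInterval("chr1", 1, 10_000)
        calls = toy_calls() + [VariantCall("chr1", 1_500, "A", "T", "gS",
                                           "splice_site")]
        default = filter_candidates(calls, interval)
        assert all(v.effect != "splice_site" for v in default)
        with_splice = filter_candidates(calls, interval, include_splice=True)
        assert any(v.effect == "splice_site" for v in with_splice)
        ranked = rank_for_report(with_splice)
        assert ranked[0].effect == "stop_gained"
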