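"""Domain types and coordinate conventions shared by every mapping stage.

Coordinates are 1-based and inclusive of both endpoints throughout the
package; sliding windows in :mod:`mossmap.bsa` are the one documented
exception (bp-anchored, half-open).  Intervals written to BED are converted
to BED's 0-based half-open convention on the way out and back on the way in.
"""

from __future__ import annotations

import os
import re
import tempfile
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = set("ACGTN")

MARKER_COLUMNS = ["chrom", "pos_bp", "pos_cM", "id", "gd_allele", "vx_allele"]


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be > 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"chromosome {self.name!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass(frozen=True)
class ToyGenome:
    """Named chromosomes; the physical coordinate frame for everything else."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate chromosome name {dup!r}")

    def __iter__(self):
        return iter(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"no chromosome named {name!r}")

    def length(self, name: str) -> int:
        return self.chromosome(name).length

    def base_at(self, chrom: str, pos_bp: int) -> str:
        """Reference base at a 1-based position; errors on N or missing sequence."""
        c = self.chromosome(chrom)
        if c.sequence is None:
            raise ValueError(f"chromosome {chrom!r} carries no sequence")
        if not 1 <= pos_bp <= c.length:
            raise ValueError(f"position {pos_bp} outside {chrom!r} [1, {c.length}]")
        base = c.sequence[pos_bp - 1]
        if base == "N":
            raise ValueError(f"{chrom}:{pos_bp} is an N base")
        return base


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """1-based interval, inclusive of both endpoints."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError("intervals are 1-based; start must be >= 1")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    @property
    def length_kb(self) -> float:
        """Length in kb, rounded half-up to two decimals (4,642 bp -> 4.64)."""
        return bp_to_kb(self.length_bp)

    def contains(self, chrom: str, pos_bp: int) -> bool:
        return chrom == self.chrom and self.start <= pos_bp <= self.end


def bp_to_kb(n_bp: int) -> float:
    """bp -> kb, two decimals, half-up (so 4,642 bp prints as 4.64 kb)."""
    import decimal

    q = decimal.Decimal(n_bp) / 1000
    return float(q.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class GeneModel:
    """A single-isoform protein-coding gene defined by its CDS exons.

    ``cds_exons`` are stored in ascending genomic order; transcription order
    is ascending on '+' and descending on '-'.  Optional ``tx_start/tx_end``
    extend the gene span beyond the CDS (untranslated region).
    """

    gene_id: str
    chrom: str
    strand: str
    cds_exons: tuple[GenomicInterval, ...]
    tx_start: int | None = None
    tx_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.cds_exons:
            raise ValueError(f"gene {self.gene_id}: no CDS exons")
        exons = sorted(self.cds_exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if a.end >= b.start:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS exons")
        object.__setattr__(self, "cds_exons", tuple(exons))
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"gene {self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e.length_bp for e in self.cds_exons)

    @property
    def span(self) -> GenomicInterval:
        start = min(e.start for e in self.cds_exons)
        end = max(e.end for e in self.cds_exons)
        if self.tx_start is not None:
            start = min(start, self.tx_start)
        if self.tx_end is not None:
            end = max(end, self.tx_end)
        return GenomicInterval(self.chrom, start, end)

    def cds_sequence(self, genome: ToyGenome) -> str:
        """Coding sequence in transcription order (reverse-complemented on '-')."""
        chrom = genome.chromosome(self.chrom)
        if chrom.sequence is None:
            raise ValueError(f"chromosome {self.chrom!r} carries no sequence")
        fwd = "".join(chrom.sequence[e.start - 1 : e.end] for e in self.cds_exons)
        if self.strand == "-":
            return str(Seq(fwd).reverse_complement())
        return fwd

    def cds_offset(self, pos_bp: int) -> int | None:
        """0-based offset of a genomic position within the CDS, in transcription
        order, or None if the position is not inside a CDS exon."""
        acc = 0
        for e in self.cds_exons:
            if e.start <= pos_bp <= e.end:
                off = acc + (pos_bp - e.start)
                if self.strand == "-":
                    return self.cds_length - 1 - off
                return off
            acc += e.length_bp
        return None

    def genomic_position(self, cds_offset: int) -> int:
        """Inverse of :meth:`cds_offset`: genomic bp of a 0-based CDS offset."""
        if not 0 <= cds_offset < self.cds_length:
            raise ValueError(f"CDS offset {cds_offset} outside [0, {self.cds_length})")
        off = cds_offset if self.strand == "+" else self.cds_length - 1 - cds_offset
        acc = 0
        for e in self.cds_exons:
            if off < acc + e.length_bp:
                return e.start + (off - acc)
            acc += e.length_bp
        raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# FASTA


def load_genome(path: str | os.PathLike) -> ToyGenome:
    """Read a FASTA file into a ToyGenome (sequences uppercased, validated)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    seen: set[str] = set()
    chroms = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record name {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{path}: record {rec.id!r} contains non-ACGTN characters {sorted(bad)}"
            )
        chroms.append(Chromosome(rec.id, len(seq), seq))
    return ToyGenome(tuple(chroms))


def write_genome(genome: ToyGenome, path: str | os.PathLike) -> None:
    records = []
    for c in genome.chromosomes:
        if c.sequence is None:
            raise ValueError(f"chromosome {c.name!r} has no sequence to write")
        records.append(SeqRecord(Seq(c.sequence), id=c.name, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Marker maps


@dataclass(frozen=True)
class Marker:
    chrom: str
    pos_bp: int
    pos_cM: float
    id: str
    gd_allele: str
    vx_allele: str

    def __post_init__(self) -> None:
        if self.gd_allele == self.vx_allele:
            raise ValueError(f"marker {self.id}: parental alleles identical")


@dataclass(frozen=True)
class MarkerMap:
    """Ordered biallelic markers with Gd/Vx parental alleles and bp + cM positions."""

    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        by_chrom: dict[str, Marker] = {}
        order = list(self.markers)
        if order != sorted(order, key=lambda m: (m.chrom, m.pos_bp)):
            raise ValueError("markers must be sorted by (chrom, pos_bp)")
        for m in self.markers:
            prev = by_chrom.get(m.chrom)
            if prev is not None and m.pos_cM < prev.pos_cM:
                raise ValueError(
                    f"marker {m.id}: pos_cM decreases along {m.chrom}"
                )
            by_chrom[m.chrom] = m

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def on_chrom(self, chrom: str) -> list[Marker]:
        return [m for m in self.markers if m.chrom == chrom]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.chrom, m.pos_bp, m.pos_cM, m.id, m.gd_allele, m.vx_allele)
             for m in self.markers],
            columns=MARKER_COLUMNS,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMap":
        markers = tuple(
            Marker(str(r.chrom), int(r.pos_bp), float(r.pos_cM), str(r.id),
                   str(r.gd_allele), str(r.vx_allele))
            for r in df.itertuples()
        )
        return cls(markers)


def load_marker_map(path: str | os.PathLike) -> MarkerMap:
    df = pd.read_csv(path, sep="\t")
    missing = set(MARKER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing marker columns {sorted(missing)}")
    return MarkerMap.from_frame(df)


def write_marker_map(markers: MarkerMap, path: str | os.PathLike) -> None:
    markers.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GFF3 gene models


def load_gene_models(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3: CDS features grouped by their gene.

    Accepts either CDS features with Parent= pointing at a gene/mRNA feature
    or bare CDS features carrying a gene_id attribute.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    groups: dict[str, list] = {}
    strands: dict[str, str] = {}
    chroms: dict[str, str] = {}
    for cds in db.features_of_type("CDS"):
        if "gene_id" in cds.attributes:
            gid = cds.attributes["gene_id"][0]
        elif "Parent" in cds.attributes:
            parent = cds.attributes["Parent"][0]
            # walk up mRNA -> gene if needed
            try:
                pfeat = db[parent]
                while "Parent" in pfeat.attributes:
                    pfeat = db[pfeat.attributes["Parent"][0]]
                gid = pfeat.id
            except gffutils.FeatureNotFoundError:
                gid = parent
        else:
            raise ValueError(f"{path}: CDS feature without gene_id or Parent")
        groups.setdefault(gid, []).append(cds)
        strands[gid] = cds.strand
        chroms[gid] = cds.seqid
    genes = []
    for gid, feats in groups.items():
        exons = tuple(
            GenomicInterval(chroms[gid], f.start, f.end)
            for f in sorted(feats, key=lambda f: f.start)
        )
        genes.append(GeneModel(gid, chroms[gid], strands[gid], exons))
    genes.sort(key=lambda g: (g.chrom, g.span.start))
    return genes


def write_gene_models(genes: list[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            span = g.span
            fh.write(
                f"{g.chrom}\ttoy\tgene\t{span.start}\t{span.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, e in enumerate(g.cds_exons, start=1):
                # phase computed in transcription order
                prior = sum(
                    x.length_bp
                    for x in (g.cds_exons[:i - 1] if g.strand == "+" else g.cds_exons[i:])
                )
                phase = (3 - prior % 3) % 3
                fh.write(
                    f"{g.chrom}\ttoy\tCDS\t{e.start}\t{e.end}\t.\t{g.strand}\t{phase}\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id};gene_id={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# BED intervals (0-based half-open on disk, 1-based inclusive in memory)


def write_bed(intervals: list[GenomicInterval], path: str | os.PathLike,
              names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"interval_{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{name}\n")


def load_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append(GenomicInterval(chrom, int(start) + 1, int(end)))
    return out


# ---------------------------------------------------------------------------
# Restriction-site utilities


def fragment_lengths(site_positions: list[int], chrom_length: int) -> list[int]:
    """Lengths of the pieces a molecule falls into when cut at the given positions.

    Positions are abstract 1-based cut coordinates: cutting at position p
    separates bases [.., p] from [p+1, ..].  The internal fragment between two
    adjacent sites therefore has length equal to the difference of their
    positions, which reproduces printed restriction-design arithmetic
    (sites 6,376,867 and 6,381,509 release a 4,642 bp = 4.64 kb fragment).
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be > 0")
    sites = list(site_positions)
    if sites != sorted(sites):
        raise ValueError("cut positions must be sorted ascending")
    for p in sites:
        if not 1 <= p <= chrom_length:
            raise ValueError(f"cut position {p} outside [1, {chrom_length}]")
    if not sites:
        return [chrom_length]
    bounds = [0] + sites + [chrom_length]
    return [b - a for a, b in zip(bounds, bounds[1:]) if b > a]


def find_sites(sequence: str, motif: str) -> list[int]:
    """1-based start positions of all exact (possibly overlapping) motif matches."""
    if not motif:
        raise ValueError("motif must be non-empty")
    pattern = re.compile(f"(?={re.escape(motif)})")
    return [m.start() + 1 for m in pattern.finditer(sequence)]
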