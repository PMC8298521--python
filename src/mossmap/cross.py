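"""Synthetic haploid Gd(mutant) x Vx cross.

Simulates the generative process behind a bulked-segregant mapping
experiment in a haploid moss: meiotic recombination under a
no-interference (Poisson crossover) model, Mendelian 1:1 segregation of
the causal allele, phenotype scoring with configurable penetrance,
selection of a downward-growing bulk, and pooled short-read allele depths
at every marker.

Crossovers are drawn Poisson(genetic length in Morgans) with breakpoints
uniform on the genetic map, converted to physical coordinates by
piecewise-linear interpolation through the marker (cM, bp) pairs.  Under
this model the discordance between two loci d Morgans apart is the
Haldane recombination fraction r = (1 - exp(-2d))/2, which is exactly the
map function :mod:`mossmap.linkage` inverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import Marker, MarkerMap, ToyGenome

GD = "G"
VX = "V"

DEPTH_COLUMNS = ["chrom", "pos_bp", "id", "gd_depth", "vx_depth"]


@dataclass(frozen=True)
class CrossConfig:
    """Study conditions of the simulated cross.

    Defaults mirror the pooled-mapping design: a 48-member bulk of
    downward-growing segregants sequenced to a mean of 50 reads per marker,
    with a 1% per-read allele-flip error and fully penetrant phenotype.
    """

    genome: ToyGenome
    markers: MarkerMap
    causal_locus: tuple[str, int]
    n_progeny: int = 192
    n_bulk: int = 48
    coverage: float = 50.0
    error_rate: float = 0.01
    penetrance: float = 1.0
    undetermined_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bulk > self.n_progeny:
            raise ValueError("n_bulk cannot exceed n_progeny")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if not 0.0 <= self.undetermined_rate <= 1.0:
            raise ValueError("undetermined_rate must be in [0, 1]")
        if not 0.0 < self.penetrance <= 1.0:
            raise ValueError("penetrance must be in (0, 1]")
        chrom, pos = self.causal_locus
        try:
            length = self.genome.length(chrom)
        except KeyError as exc:
            raise ValueError(f"causal locus chromosome {chrom!r} not in genome") from exc
        if not 1 <= pos <= length:
            raise ValueError(f"causal locus {chrom}:{pos} outside the genome")


class GeneticMap:
    """Per-chromosome cM <-> bp conversion.

    Piecewise-linear interpolation through the marker (pos_cM, pos_bp)
    pairs, constant extrapolation beyond the terminal markers.
    """

    def __init__(self, markers: MarkerMap):
        self._bp: dict[str, np.ndarray] = {}
        self._cM: dict[str, np.ndarray] = {}
        for m in markers:
            self._bp.setdefault(m.chrom, [])
            self._bp[m.chrom].append(m.pos_bp)
            self._cM.setdefault(m.chrom, [])
            self._cM[m.chrom].append(m.pos_cM)
        for chrom in self._bp:
            bp = np.asarray(self._bp[chrom], dtype=float)
            cM = np.asarray(self._cM[chrom], dtype=float)
            self._bp[chrom], self._cM[chrom] = bp, cM

    @property
    def chromosomes(self) -> list[str]:
        return list(self._bp)

    def genetic_length_cM(self, chrom: str) -> float:
        return float(self._cM[chrom][-1] - self._cM[chrom][0])

    def cM_to_bp(self, chrom: str, cM) -> np.ndarray:
        return np.interp(np.asarray(cM, dtype=float),
                         self._cM[chrom], self._bp[chrom])

    def bp_to_cM(self, chrom: str, bp) -> np.ndarray:
        return np.interp(np.asarray(bp, dtype=float),
                         self._bp[chrom], self._cM[chrom])


@dataclass(frozen=True)
class Haplotype:
    """One haploid meiotic product.

    ``segments[chrom]`` is ``(breakpoints, first_origin)``: a sorted array of
    1-based positions where the parental origin switches (each breakpoint is
    the first base of the new segment), and the origin of the first segment.
    Segments tile [1, chrom_length] exactly and alternate origins.
    """

    segments: dict[str, tuple[np.ndarray, str]]

    def origin_at(self, chrom: str, pos_bp: int) -> str:
        breakpoints, first = self.segments[chrom]
        flips = int(np.searchsorted(breakpoints, pos_bp, side="right"))
        if flips % 2 == 0:
            return first
        return VX if first == GD else GD

    def origins_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vector of origins (GD/VX) at many positions on one chromosome."""
        breakpoints, first = self.segments[chrom]
        flips = np.searchsorted(breakpoints, positions, side="right")
        other = VX if first == GD else GD
        return np.where(flips % 2 == 0, first, other)

    def n_crossovers(self, chrom: str) -> int:
        return len(self.segments[chrom][0])


@dataclass(frozen=True)
class Segregant:
    id: str
    haplotype: Haplotype
    phenotype: str  # "down" | "up" | "undetermined"


def simulate_meiosis(
    genetic_length_cM: float,
    chrom_length_bp: int,
    cM_to_bp,
    rng: np.random.Generator,
    cM_offset: float = 0.0,
) -> tuple[np.ndarray, str]:
    """One chromosome of one meiotic product: (breakpoints_bp, first_origin).

    Crossover count ~ Poisson(genetic length in Morgans); breakpoint genetic
    positions uniform on the map; physical positions via the supplied
    cM -> bp callable.  Breakpoints that collapse onto chromosome ends or
    onto each other (constant extrapolation beyond terminal markers) are
    dropped pairwise so that no zero-length segment survives.
    """
    if genetic_length_cM < 0:
        raise ValueError("genetic length must be >= 0")
    first = GD if rng.random() < 0.5 else VX
    n_xo = rng.poisson(genetic_length_cM / 100.0)
    if n_xo == 0:
        return np.empty(0, dtype=float), first
    cM = rng.uniform(cM_offset, cM_offset + genetic_length_cM, size=n_xo)
    bp = np.floor(np.asarray(cM_to_bp(cM), dtype=float)).astype(np.int64) + 1
    bp = bp[(bp > 1) & (bp <= chrom_length_bp)]
    bp.sort()
    # two crossovers mapped to the same base cancel (even number of flips)
    uniq, counts = np.unique(bp, return_counts=True)
    keep = uniq[counts % 2 == 1]
    return keep.astype(float), first


def _simulate_haplotype(genome: ToyGenome, gmap: GeneticMap,
                        rng: np.random.Generator) -> Haplotype:
    segs: dict[str, tuple[np.ndarray, str]] = {}
    for chrom in genome.chromosomes:
        if chrom.name in gmap.chromosomes:
            length_cM = gmap.genetic_length_cM(chrom.name)
            offset = float(gmap.bp_to_cM(chrom.name, 1))
            bp, first = simulate_meiosis(
                length_cM, chrom.length,
                lambda c, _n=chrom.name: gmap.cM_to_bp(_n, c),
                rng, cM_offset=offset)
        else:  # no markers: chromosome segregates as a single block
            bp, first = simulate_meiosis(0.0, chrom.length, lambda c: c, rng)
        segs[chrom.name] = (bp, first)
    return Haplotype(segs)


def simulate_cross(config: CrossConfig) -> list[Segregant]:
    """Simulate the full progeny set of the cross.

    Carriers of the Gd origin at the causal locus are scored "down" with
    probability ``penetrance``, every other segregant "up"; each progeny is
    then independently relabeled "undetermined" with ``undetermined_rate``.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    gmap = GeneticMap(config.markers)
    chrom_c, pos_c = config.causal_locus
    out: list[Segregant] = []
    for i in range(config.n_progeny):
        hap = _simulate_haplotype(config.genome, gmap, rng)
        carrier = hap.origin_at(chrom_c, pos_c) == GD
        if carrier and rng.random() < config.penetrance:
            phen = "down"
        else:
            phen = "up"
        if rng.random() < config.undetermined_rate:
            phen = "undetermined"
        out.append(Segregant(f"seg{i + 1:04d}", hap, phen))
    return out


def make_bulk(segregants: list[Segregant], phenotype: str = "down",
              n_bulk: int = 48) -> list[Segregant]:
    """First n_bulk segregants with the requested phenotype (deterministic)."""
    if phenotype == "undetermined":
        raise ValueError("undetermined segregants never enter a bulk")
    matching = [s for s in segregants if s.phenotype == phenotype]
    if len(matching) < n_bulk:
        raise ValueError(
            f"need {n_bulk} {phenotype!r} segregants but only "
            f"{len(matching)} available"
        )
    return matching[:n_bulk]


def simulate_pool_depths(
    bulk: list[Segregant],
    markers: MarkerMap,
    coverage: float = 50.0,
    error_rate: float = 0.01,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pooled allele depths at every marker: columns chrom,pos_bp,id,gd_depth,vx_depth.

    Per marker the total depth is Poisson(coverage); each read comes from a
    uniformly chosen bulk member's origin allele and is flipped to the other
    parental allele with probability ``error_rate``.  The per-read draws are
    realised through their exact binomial marginals, which is distributionally
    identical and vectorises over markers.
    """
    if not bulk:
        raise ValueError("bulk is empty")
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    by_chrom: dict[str, list[Marker]] = {}
    for m in markers:
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom, ms in by_chrom.items():
        positions = np.asarray([m.pos_bp for m in ms], dtype=float)
        # pool composition: fraction of bulk members carrying Gd at each marker
        gd_members = np.zeros(len(ms), dtype=np.int64)
        for seg in bulk:
            gd_members += seg.haplotype.origins_at(chrom, positions) == GD
        p_gd_template = gd_members / len(bulk)
        total = rng.poisson(coverage, size=len(ms))
        gd_templates = rng.binomial(total, p_gd_template)
        # sequencing error flips reads between the two parental alleles
        gd_kept = rng.binomial(gd_templates, 1.0 - error_rate)
        vx_flipped = rng.binomial(total - gd_templates, error_rate)
        gd_depth = gd_kept + vx_flipped
        for m, t, g in zip(ms, total, gd_depth):
            rows.append((m.chrom, m.pos_bp, m.id, int(g), int(t - g)))
    df = pd.DataFrame(rows, columns=DEPTH_COLUMNS)
    return df.sort_values(["chrom", "pos_bp"], ignore_index=True)


# ---------------------------------------------------------------------------
# Genotype/phenotype tables


def genotype_table(segregants: list[Segregant], markers: MarkerMap,
                   missing_rate: float = 0.0,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Individual genotypes: one row per segregant, one G/V column per marker,
    plus a phenotype column.  ``missing_rate`` blanks calls at random (NA)."""
    if missing_rate and rng is None:
        rng = np.random.default_rng()
    by_chrom: dict[str, list[Marker]] = {}
    for m in markers:
        by_chrom.setdefault(m.chrom, []).append(m)
    columns: dict[str, object] = {
        "segregant": [s.id for s in segregants],
        "phenotype": [s.phenotype for s in segregants],
    }
    for chrom, ms in by_chrom.items():
        positions = np.asarray([m.pos_bp for m in ms], dtype=float)
        calls = np.stack([s.haplotype.origins_at(chrom, positions)
                          for s in segregants])
        for j, m in enumerate(ms):
            columns[m.id] = calls[:, j]
    df = pd.DataFrame(columns)
    if missing_rate:
        marker_cols = [m.id for m in markers]
        mask = rng.random((len(segregants), len(marker_cols))) < missing_rate
        block = df[marker_cols].astype("object")
        block = block.mask(pd.DataFrame(mask, columns=marker_cols,
                                        index=df.index), pd.NA)
        df[marker_cols] = block
    return df


def write_genotype_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_genotype_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_depth_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_depth_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DEPTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing depth columns {sorted(missing)}")
    return df
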