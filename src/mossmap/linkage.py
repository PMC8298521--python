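"""Two-point linkage in individually genotyped haploid segregants.

In a haploid cross the phenotype of a fully penetrant mutant is a perfect
surrogate for the causal genotype: a downward-growing segregant carries the
Gd-derived causal allele, an upward-growing one the Vx allele.  A marker is
recombinant in a segregant when its parental origin disagrees with the
origin the phenotype implies, so the recombination fraction with the causal
locus is estimated by direct counting, with no phase ambiguity.

Map distances use the Haldane function (no crossover interference),
d = -50 * ln(1 - 2r) cM, the closed form matching the Poisson-crossover
simulator in :mod:`mossmap.cross`.  Kosambi is provided as an alternative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomicInterval, ToyGenome

LINKAGE_COLUMNS = ["id", "chrom", "pos_bp", "n_informative", "n_recombinant",
                   "r_hat", "d_cM"]

# phenotype -> implied parental origin at the causal locus
_PHENOTYPE_ORIGIN = {"down": "G", "up": "V"}


def haldane_cM(r: float) -> float:
    """Haldane map distance in cM; defined for 0 <= r < 0.5."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction {r} not in [0, 0.5): unlinked")
    return -50.0 * math.log(1.0 - 2.0 * r)


def haldane_r(d_cM: float) -> float:
    """Inverse Haldane: recombination fraction at map distance d_cM."""
    if d_cM < 0:
        raise ValueError("map distance must be >= 0")
    return 0.5 * (1.0 - math.exp(-d_cM / 50.0))


def kosambi_cM(r: float) -> float:
    """Kosambi map distance in cM (interference-adjusted alternative)."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombination fraction {r} not in [0, 0.5): unlinked")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def recombination_fraction(genotypes, phenotypes) -> tuple[int, int, float]:
    """Count recombinants between one marker and the phenotype.

    ``genotypes`` holds per-segregant parental origins ("G"/"V", missing
    allowed as None/NA), ``phenotypes`` the matching "down"/"up"/
    "undetermined" calls.  Undetermined phenotypes and missing genotypes are
    dropped, not counted as informative.

    Returns (n_informative, n_recombinant, r_hat).
    """
    genotypes = list(genotypes)
    phenotypes = list(phenotypes)
    if len(genotypes) != len(phenotypes):
        raise ValueError("genotype and phenotype vectors differ in length")
    n_inf = 0
    n_rec = 0
    for g, p in zip(genotypes, phenotypes):
        if p not in _PHENOTYPE_ORIGIN:
            continue
        if g is None or (isinstance(g, float) and math.isnan(g)) or g is pd.NA:
            continue
        g = str(g)
        if g not in {"G", "V"}:
            raise ValueError(f"genotype call {g!r} is not G/V")
        n_inf += 1
        if g != _PHENOTYPE_ORIGIN[p]:
            n_rec += 1
    if n_inf == 0:
        raise ValueError("no informative segregants")
    return n_inf, n_rec, n_rec / n_inf


def linkage_table(genotype_df: pd.DataFrame, marker_positions: pd.DataFrame,
                  map_function=haldane_cM) -> pd.DataFrame:
    """Per-marker two-point linkage with the phenotype.

    ``genotype_df`` is the segregant table from :func:`mossmap.cross.genotype_table`
    (one G/V column per marker id plus a phenotype column); ``marker_positions``
    supplies chrom,pos_bp,id for each marker column present.  d_cM is NaN for
    markers with r_hat >= 0.5 (unlinked under the map function).
    """
    pheno = genotype_df["phenotype"]
    rows = []
    pos = marker_positions.set_index("id")
    for marker_id in pos.index:
        if marker_id not in genotype_df.columns:
            continue
        n_inf, n_rec, r_hat = recombination_fraction(genotype_df[marker_id], pheno)
        d = map_function(r_hat) if r_hat < 0.5 else math.nan
        rows.append((marker_id, pos.loc[marker_id, "chrom"],
                     int(pos.loc[marker_id, "pos_bp"]), n_inf, n_rec, r_hat, d))
    df = pd.DataFrame(rows, columns=LINKAGE_COLUMNS)
    return df.sort_values(["chrom", "pos_bp"], ignore_index=True)


def refine_interval(linkage: pd.DataFrame,
                    chrom_length: int | None = None) -> GenomicInterval:
    """Interval bounded by the nearest recombinant markers flanking the
    fully cosegregating block.

    ``linkage`` must cover a single chromosome, ordered by pos_bp, with
    n_recombinant per marker.  The interval runs from the closest marker
    left of the zero-recombinant block that shows >= 1 recombinant to the
    closest such marker on the right; a side with no recombinant marker
    extends to the chromosome end (with a warning).
    """
    chroms = linkage["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("refine_interval expects markers from one chromosome")
    chrom = str(chroms[0])
    sub = linkage.sort_values("pos_bp").reset_index(drop=True)
    zero = sub.index[sub["n_recombinant"] == 0]
    if len(zero) == 0:
        raise ValueError("locus not in the genotyped region: "
                         "no fully cosegregating marker")
    first_zero, last_zero = int(zero[0]), int(zero[-1])
    left = sub.loc[: first_zero - 1]
    left = left[left["n_recombinant"] >= 1]
    right = sub.loc[last_zero + 1 :]
    right = right[right["n_recombinant"] >= 1]
    if len(left):
        start = int(left.iloc[-1]["pos_bp"])
    else:
        warnings.warn("no recombinant marker left of the cosegregating block; "
                      "interval extended to the chromosome start", stacklevel=2)
        start = 1
    if len(right):
        end = int(right.iloc[0]["pos_bp"])
    else:
        warnings.warn("no recombinant marker right of the cosegregating block; "
                      "interval extended to the chromosome end", stacklevel=2)
        end = chrom_length if chrom_length is not None else int(sub["pos_bp"].max())
    return GenomicInterval(chrom, start, end)


def two_round_refine(
    genotype_df: pd.DataFrame,
    markers_df: pd.DataFrame,
    chrom: str,
    chrom_length: int,
    coarse_every: int = 20,
    map_function=haldane_cM,
) -> tuple[GenomicInterval, pd.DataFrame]:
    """Two mapping rounds: a sparse genome-spanning panel, then every marker
    inside the round-one interval.  Returns the refined interval and the
    round-two linkage table."""
    on_chrom = markers_df[markers_df["chrom"] == chrom].sort_values("pos_bp")
    sparse = on_chrom.iloc[::coarse_every]
    coarse_link = linkage_table(genotype_df, sparse, map_function)
    coarse = refine_interval(coarse_link, chrom_length)
    dense = on_chrom[(on_chrom["pos_bp"] >= coarse.start)
                     & (on_chrom["pos_bp"] <= coarse.end)]
    fine_link = linkage_table(genotype_df, dense, map_function)
    return refine_interval(fine_link, chrom_length), fine_link
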