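"""Bulked-segregant mapping statistic: per-SNP Gd depth fraction, sliding
windows, and peak detection.

The per-marker "Gd/Vx ratio" is implemented as the Gd allele-depth fraction
gd/(gd+vx): 0.5 at loci unlinked to the selected phenotype, approaching 1.0
at the causal locus in a bulk selected for the Gd-derived phenotype.  (The
literal depth quotient gd/vx would be ~1 at unlinked loci and divergent at
the causal locus, which is incompatible with a peak criterion of "ratio
near 1"; the fraction is the form with that behaviour.)

Windows are bp-anchored and half-open, [k*S, k*S + W) for k = 0, 1, ... on
each chromosome — the one departure from the package's 1-based inclusive
convention.  Defaults W = 500 kb and S = 250 kb.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomicInterval, ToyGenome

DEFAULT_WINDOW = 500_000
DEFAULT_STEP = 250_000
DEFAULT_MIN_MARKERS = 5
DEFAULT_THRESHOLD = 0.9

WINDOW_COLUMNS = ["chrom", "win_start", "win_end", "mean_ratio", "n_markers"]


def snp_ratio(gd_depth: int, vx_depth: int) -> float:
    """Gd depth fraction gd/(gd+vx); NaN when both depths are zero."""
    if gd_depth < 0 or vx_depth < 0:
        raise ValueError("depths must be >= 0")
    total = gd_depth + vx_depth
    if total == 0:
        return math.nan
    return gd_depth / total


def ratio_track(depths: pd.DataFrame) -> pd.DataFrame:
    """Per-marker ratios from a depth table (chrom,pos_bp,id,gd_depth,vx_depth).

    Markers with zero total depth are dropped (ratio undefined).
    """
    if (depths["gd_depth"] < 0).any() or (depths["vx_depth"] < 0).any():
        raise ValueError("depths must be >= 0")
    total = depths["gd_depth"] + depths["vx_depth"]
    out = depths.loc[total > 0, ["chrom", "pos_bp", "id"]].copy()
    out["ratio"] = (depths.loc[total > 0, "gd_depth"] / total[total > 0]).astype(float)
    return out.sort_values(["chrom", "pos_bp"], ignore_index=True)


def window_means(
    ratios: pd.DataFrame,
    chrom_lengths: dict[str, int] | ToyGenome,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_markers: int = DEFAULT_MIN_MARKERS,
) -> pd.DataFrame:
    """Sliding-window unweighted means of per-marker ratios.

    Windows with fewer than ``min_markers`` markers are reported with a
    missing (NaN) mean, never as zero.  ``win_start``/``win_end`` are the
    half-open window bounds in bp.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be > 0")
    if step > window:
        raise ValueError("step must be <= window")
    if isinstance(chrom_lengths, ToyGenome):
        chrom_lengths = {c.name: c.length for c in chrom_lengths}
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = ratios[ratios["chrom"] == chrom]
        pos = sub["pos_bp"].to_numpy(dtype=float)
        val = sub["ratio"].to_numpy(dtype=float)
        order = np.argsort(pos)
        pos, val = pos[order], val[order]
        csum = np.concatenate([[0.0], np.cumsum(val)])
        k = 0
        while k * step < length:
            lo, hi = k * step, k * step + window
            i = int(np.searchsorted(pos, lo, side="left"))
            j = int(np.searchsorted(pos, hi, side="left"))
            n = j - i
            mean = (csum[j] - csum[i]) / n if n >= min_markers else math.nan
            rows.append((chrom, lo, hi, mean, n))
            k += 1
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


@dataclass(frozen=True)
class MappingPeak:
    """A run of contiguous above-threshold windows around a local maximum."""

    interval: GenomicInterval
    peak_value: float
    peak_window: tuple[int, int]  # half-open bp bounds of the maximal window

    def contains(self, chrom: str, pos_bp: int) -> bool:
        return self.interval.contains(chrom, pos_bp)


def detect_peaks(
    windows: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    min_run: int = 1,
) -> list[MappingPeak]:
    """Maximal runs of >= min_run contiguous unmasked windows with mean >= threshold.

    Each run yields one peak whose interval spans the run and whose
    peak_window is the run's maximum (leftmost on ties); peaks are returned
    sorted by peak_value descending (position as tie-break).
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    peaks: list[MappingPeak] = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        sub = sub.sort_values("win_start")
        means = sub["mean_ratio"].to_numpy(dtype=float)
        starts = sub["win_start"].to_numpy(dtype=np.int64)
        ends = sub["win_end"].to_numpy(dtype=np.int64)
        above = ~np.isnan(means) & (means >= threshold)
        i = 0
        while i < len(above):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                run = slice(i, j + 1)
                best = i + int(np.argmax(means[run]))  # argmax is leftmost on ties
                # half-open [lo, hi) holds 1-based positions max(lo,1)..hi-1
                interval = GenomicInterval(
                    chrom, int(max(starts[i], 1)), int(ends[j]) - 1)
                peaks.append(MappingPeak(
                    interval=interval,
                    peak_value=float(means[best]),
                    peak_window=(int(starts[best]), int(ends[best])),
                ))
            i = j + 1
    peaks.sort(key=lambda p: (-p.peak_value, p.interval))
    return peaks


def write_windows(windows: pd.DataFrame, path) -> None:
    windows.to_csv(path, sep="\t", index=False, na_rep="NA")


def load_windows(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
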