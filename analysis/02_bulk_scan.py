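#!/usr/bin/env python
"""Pooled-mapping scan of the downward bulk.

Computes the per-marker Gd depth fraction from the step-01 bulk, smooths
it with 0.5 Mb windows advanced by 0.25 Mb, and reports every window run
whose mean approaches 1 (threshold 0.9).  The top peak is the candidate
interval passed to annotation.
"""

from pathlib import Path

from mossmap.bsa import detect_peaks, ratio_track, window_means, write_windows
from mossmap.cross import load_depth_table
from mossmap.genome import write_bed

OUT = Path("results/analysis")
CHROM_LENGTH = 20_000_000


def main() -> None:
    depths = load_depth_table(OUT / "bulk_depths.tsv")
    ratios = ratio_track(depths)
    windows = window_means(ratios, {"chr1": CHROM_LENGTH})
    peaks = detect_peaks(windows)

    ratios.to_csv(OUT / "ratios.tsv", sep="\t", index=False)
    write_windows(windows, OUT / "windows.tsv")
    write_bed([p.interval for p in peaks], OUT / "peaks.bed",
              [f"peak_{i + 1}" for i in range(len(peaks))])

    print(f"{len(ratios)} informative markers; "
          f"{windows.mean_ratio.notna().sum()} windows with >= 5 markers")
    for i, p in enumerate(peaks, 1):
        iv = p.interval
        print(f"peak_{i}: {iv.chrom}:{iv.start:,}-{iv.end:,} "
              f"({iv.length_kb} kb), max window mean {p.peak_value:.3f}")
    if peaks:
        print("the top peak is the bulked-segregant candidate interval")


if __name__ == "__main__":
    main()
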