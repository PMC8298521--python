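"""Circular summaries of protonema bending angles.

Bending is measured relative to the original growth axis, reported in
[0, 360) degrees (0 = unbent).  The circular mean is the direction of the
mean unit vector and the mean resultant length R-bar its magnitude; when
R-bar is ~0 (e.g. antipodal angles) the mean direction is undefined and
reported as NaN.  Kinetic time-courses are summarised with the ordinary
arithmetic mean +/- sample s.d. per timepoint, appropriate while angles
stay well within a single cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_R_UNDEFINED = 1e-9


@dataclass(frozen=True)
class AngleSample:
    """Bending angles in degrees, reduced modulo 360."""

    angles: np.ndarray
    group: str = ""
    times_h: np.ndarray | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.angles, dtype=float) % 360.0
        if arr.size < 1:
            raise ValueError("an angle sample needs at least one angle")
        object.__setattr__(self, "angles", arr)


@dataclass(frozen=True)
class CircularSummary:
    counts: np.ndarray
    bin_edges: np.ndarray
    mean_deg: float  # NaN when the resultant length vanishes
    resultant_length: float
    n: int


def circular_summary(sample: AngleSample, bin_width: float = 30.0) -> CircularSummary:
    """Histogram counts over [0, 360), circular mean and resultant length."""
    if bin_width <= 0 or not math.isclose(360.0 % bin_width, 0.0, abs_tol=1e-9):
        raise ValueError("bin_width must divide 360")
    a = sample.angles
    edges = np.arange(0.0, 360.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(a, bins=edges)
    rad = np.deg2rad(a)
    c, s = np.mean(np.cos(rad)), np.mean(np.sin(rad))
    r_bar = math.hypot(c, s)
    if r_bar < _R_UNDEFINED:
        mean_deg = math.nan
    else:
        mean_deg = math.degrees(math.atan2(s, c)) % 360.0
    return CircularSummary(counts, edges, mean_deg, r_bar, a.size)


def kinetic_summary(series: list[pd.Series] | pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint mean, sample s.d. and n over filament angle time-courses.

    ``series`` is a list of per-filament Series indexed by time (or an
    equivalent wide DataFrame, one column per filament).  Missing values are
    skipped; s.d. is NaN when only one filament is present at a timepoint.
    """
    if isinstance(series, pd.DataFrame):
        wide = series
    else:
        if not series:
            raise ValueError("at least one series required")
        wide = pd.concat(series, axis=1)
    out = pd.DataFrame({
        "mean": wide.mean(axis=1, skipna=True),
        "sd": wide.std(axis=1, ddof=1, skipna=True),
        "n": wide.notna().sum(axis=1),
    })
    out.index.name = "time_h"
    return out


def load_angle_table(path, angle_col: str = "angle_deg",
                     group_col: str = "group") -> list[AngleSample]:
    """Angle samples from a TSV with columns angle_deg and optional group."""
    df = pd.read_csv(path, sep="\t")
    if angle_col not in df.columns:
        raise ValueError(f"{path}: missing column {angle_col!r}")
    if group_col in df.columns:
        return [AngleSample(sub[angle_col].to_numpy(), group=str(g))
                for g, sub in df.groupby(group_col, sort=True)]
    return [AngleSample(df[angle_col].to_numpy())]
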