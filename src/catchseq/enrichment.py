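"""Feature enrichment of peaks across a threshold sweep, with a randomized
positional null, and comparison of interaction gene sets between conditions.

The null model relocates each called peak independently to a uniform random
start position on the chromosome, preserving widths and heights; the
adjacency fraction of relocated peaks estimates the overlap expected "at
random".  Uniform relocation is the minimal positional null and is exactly
checkable: the expected null fraction equals the measure of eligible start
positions (those landing within the adjacency window of a feature) divided
by all valid start positions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotate import CatchGeneList, feature_adjacency
from .core import CoverageTrack, FeatureSet, GenomicInterval, Peak
from .signal import call_peaks

__all__ = [
    "OverlapCurvePoint",
    "OverlapCurve",
    "ConditionComparison",
    "shuffle_peaks",
    "threshold_sweep",
    "compare_conditions",
]


@dataclass(frozen=True)
class OverlapCurvePoint:
    threshold: float
    n_peaks: int
    n_adjacent: int
    fraction: float
    null_mean_fraction: float
    null_sd_fraction: float
    n_shuffles: int


@dataclass
class OverlapCurve:
    """Observed and null feature-adjacency fractions across thresholds."""

    points: list[OverlapCurvePoint] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "threshold": p.threshold,
                    "n_peaks": p.n_peaks,
                    "n_adjacent": p.n_adjacent,
                    "fraction": p.fraction,
                    "null_mean_fraction": p.null_mean_fraction,
                    "null_sd_fraction": p.null_sd_fraction,
                    "n_shuffles": p.n_shuffles,
                }
                for p in self.points
            ]
        )


@dataclass
class ConditionComparison:
    """Set algebra between two condition gene lists (e.g. vehicle vs E2)."""

    shared: set[str]
    lost: set[str]
    gained: set[str]
    overlap_percent: int

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [{"gene_id": g, "category": "shared"} for g in sorted(self.shared)]
            + [{"gene_id": g, "category": "lost"} for g in sorted(self.lost)]
            + [{"gene_id": g, "category": "gained"} for g in sorted(self.gained)]
        )
        return pd.DataFrame(rows, columns=["gene_id", "category"])


def shuffle_peaks(
    peaks: Sequence[Peak],
    chrom_length: int,
    seed: int | np.random.Generator | None = None,
) -> list[Peak]:
    """Relocate each peak to a uniform random start in [0, chrom_length - width),
    preserving width, height, and summit offset within the peak."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[Peak] = []
    for peak in peaks:
        width = peak.interval.width
        if width > chrom_length:
            raise ValueError(
                f"peak width {width} exceeds chrom_length {chrom_length}"
            )
        new_start = int(rng.integers(0, chrom_length - width))
        shift = new_start - peak.interval.start
        out.append(
            Peak(
                interval=GenomicInterval(
                    peak.chrom, new_start, new_start + width, peak.interval.strand
                ),
                height=peak.height,
                summit=peak.summit + shift,
            )
        )
    return out


def threshold_sweep(
    track: CoverageTrack,
    features: FeatureSet,
    thresholds: Sequence[float] = tuple(range(100, 501, 50)),
    window: int = 2000,
    n_shuffles: int = 100,
    seed: int | np.random.Generator | None = None,
    merge_gap: int = 0,
) -> OverlapCurve:
    """Observed vs null feature-adjacency fractions at each peak-height threshold.

    At each threshold, peaks are called, the observed adjacency fraction is
    computed, and ``n_shuffles`` random relocations of the same peaks give the
    null mean and standard deviation.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    merged = features.merged()
    points: list[OverlapCurvePoint] = []
    for t in thresholds:
        peaks = call_peaks(track, t, merge_gap=merge_gap)
        n_peaks, n_adjacent, fraction = feature_adjacency(peaks, merged, window=window)
        null_fracs = np.empty(n_shuffles, dtype=float)
        for s in range(n_shuffles):
            shuffled = shuffle_peaks(peaks, track.chrom_length, seed=rng)
            null_fracs[s] = feature_adjacency(shuffled, merged, window=window)[2]
        points.append(
            OverlapCurvePoint(
                threshold=float(t),
                n_peaks=n_peaks,
                n_adjacent=n_adjacent,
                fraction=fraction,
                null_mean_fraction=float(null_fracs.mean()),
                null_sd_fraction=float(null_fracs.std(ddof=0)),
                n_shuffles=n_shuffles,
            )
        )
    return OverlapCurve(points=points)


def compare_conditions(
    genes_a: CatchGeneList, genes_b: CatchGeneList
) -> ConditionComparison:
    """Shared / lost / gained gene sets between two conditions.

    ``overlap_percent`` is 100 * |A intersect B| / |A union B|, rounded to the
    nearest integer (half away from zero).
    """
    a, b = set(genes_a.gene_ids), set(genes_b.gene_ids)
    if not a and not b:
        raise ValueError("both gene lists are empty; overlap percentage undefined")
    shared = a & b
    union = a | b
    pct = 100.0 * len(shared) / len(union)
    return ConditionComparison(
        shared=shared,
        lost=a - b,
        gained=b - a,
        overlap_percent=int(math.floor(pct + 0.5)),
    )
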