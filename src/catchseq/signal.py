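"""Background subtraction and threshold-based peak calling on coverage tracks.

The capture protocol's unfixed control (same oligo, no crosslinking) measures
non-interaction background; subtracting it leaves the interaction signal.
Peaks are then defined purely by a signal-strength threshold: a peak is a
maximal run of bins at or above the threshold, optionally bridging short
sub-threshold gaps.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np

from .core import CoverageTrack, GenomicInterval, Peak

__all__ = ["subtract_background", "call_peaks", "peak_count_curve"]


def subtract_background(
    treatment: CoverageTrack,
    control: CoverageTrack,
    scale_mode: str = "match_totals",
) -> CoverageTrack:
    """Per-bin subtraction of a control track from a treatment track.

    With ``scale_mode="match_totals"`` (default) the control is first scaled
    by total_signal(treatment) / total_signal(control), approximating
    sequencing-depth normalisation; ``"none"`` subtracts raw values.
    Negative differences are clamped to zero, so the result is a valid
    non-negative track with total_signal <= the treatment's.
    """
    if scale_mode not in ("match_totals", "none"):
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    if (
        treatment.chrom != control.chrom
        or treatment.chrom_length != control.chrom_length
        or treatment.bin_size != control.bin_size
    ):
        raise ValueError("treatment and control tracks have mismatched binning")
    ctrl = control.values
    if scale_mode == "match_totals":
        ctrl_total = control.total_signal
        if ctrl_total == 0:
            warnings.warn(
                "control track has zero total signal; falling back to "
                "scale_mode='none'",
                stacklevel=2,
            )
        else:
            ctrl = ctrl * (treatment.total_signal / ctrl_total)
    diff = np.clip(treatment.values - ctrl, 0.0, None)
    return CoverageTrack(
        chrom=treatment.chrom,
        chrom_length=treatment.chrom_length,
        bin_size=treatment.bin_size,
        values=diff,
    )


def call_peaks(
    track: CoverageTrack, threshold: float, merge_gap: int = 0
) -> list[Peak]:
    """Maximal runs of bins with value >= threshold, as bp-coordinate peaks.

    Sub-threshold gaps of at most ``merge_gap`` bins between above-threshold
    runs are bridged into one peak.  A peak's height is the maximum bin value
    in its run; its summit is the midpoint of the leftmost bin attaining that
    maximum.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if merge_gap < 0:
        raise ValueError("merge_gap must be non-negative")
    above = np.flatnonzero(track.values >= threshold)
    if above.size == 0:
        return []
    # Split above-threshold bin indices wherever the gap exceeds merge_gap.
    breaks = np.flatnonzero(np.diff(above) > merge_gap + 1) + 1
    peaks: list[Peak] = []
    for run in np.split(above, breaks):
        i0, i1 = int(run[0]), int(run[-1])
        segment = track.values[i0 : i1 + 1]
        rel_argmax = int(np.argmax(segment))  # leftmost maximal bin
        height = float(segment[rel_argmax])
        summit_bin = i0 + rel_argmax
        peaks.append(
            Peak(
                interval=GenomicInterval(
                    track.chrom, track.bin_start(i0), track.bin_end(i1)
                ),
                height=height,
                summit=track.bin_mid(summit_bin),
            )
        )
    return peaks


def peak_count_curve(
    track: CoverageTrack, thresholds: Sequence[float], merge_gap: int = 0
) -> list[tuple[float, int]]:
    """Number of called peaks at each threshold.

    Not guaranteed monotone: raising the threshold can split one bridged run
    into several peaks.
    """
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    return [
        (float(t), len(call_peaks(track, t, merge_gap=merge_gap))) for t in thresholds
    ]
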