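"""Genomic primitives: intervals, coverage tracks, genes, and BED/bedGraph IO.

Coordinate conventions
----------------------
All coordinates are 0-based half-open (the BED convention): an interval
[start, end) covers bases start .. end-1.  Two half-open intervals that
abut ([a, b) and [b, c)) share no base — their overlap is 0 bp — but the
gap between them is also 0 bp, so their *distance* is 0.  The distinction
matters downstream: enhancer definition demands a >= 1 bp overlap, while
"within 2 kb" adjacency tests use distance.

A minus-strand gene's TSS is the last covered base of its body,
``body.end - 1``; with half-open intervals this is the only position that
lies inside the body.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "CoverageTrack",
    "Peak",
    "GeneAnnotation",
    "FeatureSet",
    "interval_distance",
    "merge_intervals",
    "read_bed",
    "write_bed",
    "read_genes_bed",
    "write_genes_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_chrom_sizes",
]

_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return self.chrom == other.chrom and max(self.start, other.start) < min(
            self.end, other.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base-pair gap between two intervals on the same chromosome.

    0 if they overlap or abut; otherwise the number of bases strictly
    between the nearest ends.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"intervals on different chromosomes: {a.chrom} vs {b.chrom}")
    if a.overlaps(b):
        return 0
    if a.start >= b.end:
        return a.start - b.end
    return b.start - a.end


@dataclass
class CoverageTrack:
    """Fixed-bin signal values over one chromosome.

    ``values[i]`` is the mean signal over bin i, which spans
    [i * bin_size, min((i+1) * bin_size, chrom_length)); the last bin may be
    partial.  Values are non-negative: the background-subtraction step clamps
    negative differences to zero before a track is constructed.
    """

    chrom: str
    chrom_length: int
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        self.values = np.asarray(self.values, dtype=float)
        expected = self.n_bins
        if self.values.shape != (expected,):
            raise ValueError(
                f"expected {expected} bins for chrom_length {self.chrom_length} "
                f"at bin_size {self.bin_size}, got shape {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")

    @property
    def n_bins(self) -> int:
        return -(-self.chrom_length // self.bin_size)

    @property
    def total_signal(self) -> float:
        return float(self.values.sum())

    def bin_start(self, i: int) -> int:
        return i * self.bin_size

    def bin_end(self, i: int) -> int:
        return min((i + 1) * self.bin_size, self.chrom_length)

    def bin_mid(self, i: int) -> int:
        return (self.bin_start(i) + self.bin_end(i)) // 2


@dataclass(frozen=True)
class Peak:
    """A maximal above-threshold signal run: a putative DNA-DNA interaction site."""

    interval: GenomicInterval
    height: float
    summit: int

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start},{self.interval.end})"
            )
        if self.height < 0:
            raise ValueError("peak height must be non-negative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene body with a strand-aware transcription start site."""

    gene_id: str
    chrom: str
    strand: str
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("gene strand must be '+' or '-'")
        if self.body.chrom != self.chrom:
            raise ValueError("body chromosome disagrees with gene chromosome")

    @property
    def tss(self) -> int:
        # Last covered base for minus-strand genes under half-open coordinates.
        return self.body.start if self.strand == "+" else self.body.end - 1


@dataclass
class FeatureSet:
    """A named collection of genomic intervals (histone marks, ER/CTCF sites...).

    Intervals preserve input order as read; call :meth:`merged` (or
    :func:`merge_intervals`) to obtain the sorted, disjoint form required by
    the enhancer and adjacency operations.
    """

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def on_chrom(self, chrom: str) -> list[GenomicInterval]:
        return sorted(
            (iv for iv in self.intervals if iv.chrom == chrom),
            key=lambda iv: (iv.start, iv.end),
        )

    def merged(self, gap: int = 0) -> "FeatureSet":
        return merge_intervals(self, gap=gap)

    def is_sorted_disjoint(self) -> bool:
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        if ivs != self.intervals:
            return False
        for a, b in zip(ivs, ivs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                return False
        return True


def merge_intervals(features: FeatureSet, gap: int = 0) -> FeatureSet:
    """Union intervals that overlap by >= 1 bp, or that are separated by <= gap bp.

    With gap=0, abutting half-open intervals ([a,b) and [b,c)) are NOT merged:
    they overlap by 0 bp.  Any gap > 0 bridges abutment (separation 0) as well
    as true gaps up to ``gap`` bases.  Output is sorted by (chrom, start) and
    disjoint up to abutment; the operation is idempotent.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in features.intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            separation = iv.start - cur_end
            if separation < 0 or (gap > 0 and separation <= gap):
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return FeatureSet(name=features.name, intervals=out)


# ---------------------------------------------------------------------------
# Readers / writers.  BED and bedGraph are tiny dialects but the error
# contracts here (line-numbered messages, strict non-overlapping bedGraph)
# are part of the interface, so parsing is done explicitly.
# ---------------------------------------------------------------------------


def _parse_bed_line(line: str, lineno: int, path: str) -> tuple[list[str], int, int]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start >= end:
        raise ValueError(
            f"{path}:{lineno}: empty or inverted interval [{start},{end})"
        )
    if start < 0:
        raise ValueError(f"{path}:{lineno}: negative start coordinate")
    return fields, start, end


def read_bed(path: str | Path, name: str | None = None) -> FeatureSet:
    """Read a BED3/BED6 file into a FeatureSet (input order preserved, no merge)."""
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields, start, end = _parse_bed_line(line, lineno, str(path))
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            intervals.append(GenomicInterval(fields[0], start, end, strand))
    return FeatureSet(name=name or path.stem, intervals=intervals)


def write_bed(features: FeatureSet, path: str | Path) -> None:
    """Write a FeatureSet as BED3 (BED6 when any interval is stranded)."""
    stranded = any(iv.strand != "." for iv in features.intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(features.intervals):
            if stranded:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{features.name}_{i}\t0\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_genes_bed(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED6 gene table: gene_id in column 4, strand in column 6."""
    path = Path(path)
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields, start, end = _parse_bed_line(line, lineno, str(path))
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: gene records need 6 columns (BED6)"
                )
            gene_id, strand = fields[3], fields[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: gene strand must be + or -")
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    chrom=fields[0],
                    strand=strand,
                    body=GenomicInterval(fields[0], start, end, strand),
                )
            )
    return genes


def write_genes_bed(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.body.start}\t{g.body.end}\t{g.gene_id}\t0\t{g.strand}\n"
            )


def read_bedgraph(
    path: str | Path, chrom_length: int, bin_size: int
) -> CoverageTrack:
    """Bin a bedGraph file into a fixed-bin CoverageTrack.

    Each bin's value is the coverage-weighted mean of the spans overlapping
    it; uncovered bases contribute zero.  The dialect is strict: spans must
    be sorted, non-overlapping, on a single chromosome, and lie within
    ``chrom_length``.
    """
    path = Path(path)
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    n_bins = -(-chrom_length // bin_size)
    sums = np.zeros(n_bins, dtype=float)
    chrom: str | None = None
    prev_end = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed span") from exc
            if chrom is None:
                chrom = fields[0]
            elif fields[0] != chrom:
                raise ValueError(
                    f"{path}:{lineno}: multiple chromosomes in one track "
                    f"({chrom!r} then {fields[0]!r})"
                )
            if start >= end or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid span [{start},{end})")
            if end > chrom_length:
                raise ValueError(
                    f"{path}:{lineno}: span end {end} exceeds chrom_length {chrom_length}"
                )
            if start < prev_end:
                raise ValueError(
                    f"{path}:{lineno}: overlapping or unsorted bedGraph spans"
                )
            prev_end = end
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative coverage value")
            first = start // bin_size
            last = (end - 1) // bin_size
            for b in range(first, last + 1):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size)
                sums[b] += value * (hi - lo)
    widths = np.minimum(
        (np.arange(n_bins) + 1) * bin_size, chrom_length
    ) - np.arange(n_bins) * bin_size
    return CoverageTrack(
        chrom=chrom or "chrNA",
        chrom_length=chrom_length,
        bin_size=bin_size,
        values=sums / widths,
    )


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write non-zero bins as bedGraph spans, merging runs of equal value."""
    with open(path, "w") as fh:
        run_start: int | None = None
        run_value = 0.0
        for i in range(track.n_bins):
            v = track.values[i]
            if run_start is not None and v != run_value:
                fh.write(
                    f"{track.chrom}\t{run_start}\t{track.bin_start(i)}\t{run_value:g}\n"
                )
                run_start = None
            if run_start is None and v != 0.0:
                run_start, run_value = track.bin_start(i), v
        if run_start is not None:
            fh.write(
                f"{track.chrom}\t{run_start}\t{track.chrom_length}\t{run_value:g}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV of chromosome name and length."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            sizes[fields[0]] = int(fields[1])
    return sizes
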