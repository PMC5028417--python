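"""Peak-to-promoter assignment, ranked gene lists, enhancer definition, and
the TSS-relative summit-density profile.

Promoter assignment is interval-based: a peak is assigned to a gene when the
peak interval overlaps the window [tss - w, tss + w) around the gene's TSS
(the window always includes the TSS base itself, so w = 0 degenerates to
"peaks covering the TSS").  Offsets, by contrast, are summit-based and
strand-aware: positive means downstream of the TSS in the gene's
transcriptional direction.

Enhancers are operationally defined as regions where an H3K4me1 peak and an
H3K27ac peak overlap by at least 1 bp; each qualifying pair contributes the
union span of the two peaks, and the spans are then merged.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import (
    FeatureSet,
    GeneAnnotation,
    GenomicInterval,
    Peak,
    interval_distance,
    merge_intervals,
)

__all__ = [
    "PromoterHit",
    "CatchGeneList",
    "DensityProfile",
    "assign_peaks_to_tss",
    "strongest_hit_per_gene",
    "top_n_genes",
    "define_enhancers",
    "feature_adjacency",
    "tss_density_profile",
    "offset_density",
]


@dataclass(frozen=True)
class PromoterHit:
    """A peak assigned to a gene promoter.

    ``signed_offset`` is summit minus TSS for plus-strand genes and TSS minus
    summit for minus-strand genes, so positive always means downstream in the
    transcriptional direction.
    """

    gene_id: str
    peak: Peak
    signed_offset: int

    @property
    def height(self) -> float:
        return self.peak.height


@dataclass
class CatchGeneList:
    """Genes ranked by their strongest promoter-proximal peak height."""

    entries: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene_id in CatchGeneList")
        heights = [h for _, h in self.entries]
        if any(a < b for a, b in zip(heights, heights[1:])):
            raise ValueError("CatchGeneList heights must be non-increasing")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_id: object) -> bool:
        return any(g == gene_id for g, _ in self.entries)


@dataclass
class DensityProfile:
    """Kernel-density estimate of summit offsets around the TSS."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    @property
    def mode_offset(self) -> int:
        # np.argmax returns the first (leftmost) maximum.
        return int(self.grid[int(np.argmax(self.density))])


def assign_peaks_to_tss(
    peaks: Sequence[Peak],
    genes: Sequence[GeneAnnotation],
    window: int = 2000,
) -> list[PromoterHit]:
    """Emit a hit for every (gene, peak) pair whose peak interval overlaps the
    +/- window around the gene's TSS."""
    if window < 0:
        raise ValueError("window must be non-negative")
    hits: list[PromoterHit] = []
    for gene in genes:
        win_start = max(0, gene.tss - window)
        win_end = max(gene.tss + window, gene.tss + 1)
        for peak in peaks:
            if peak.chrom != gene.chrom:
                continue
            if max(peak.interval.start, win_start) < min(peak.interval.end, win_end):
                offset = (
                    peak.summit - gene.tss
                    if gene.strand == "+"
                    else gene.tss - peak.summit
                )
                hits.append(
                    PromoterHit(gene_id=gene.gene_id, peak=peak, signed_offset=offset)
                )
    return hits


def strongest_hit_per_gene(hits: Sequence[PromoterHit]) -> list[PromoterHit]:
    """Keep, per gene, the hit of greatest peak height.

    Ties go to the smaller absolute offset, then the leftmost summit.
    """
    best: dict[str, PromoterHit] = {}
    for hit in hits:
        cur = best.get(hit.gene_id)
        if cur is None:
            best[hit.gene_id] = hit
            continue
        key_new = (-hit.height, abs(hit.signed_offset), hit.peak.summit)
        key_cur = (-cur.height, abs(cur.signed_offset), cur.peak.summit)
        if key_new < key_cur:
            best[hit.gene_id] = hit
    return [best[g] for g in sorted(best)]


def top_n_genes(hits: Sequence[PromoterHit], n: int = 500) -> CatchGeneList:
    """The n genes of greatest best-peak height (all genes if fewer exist).

    Requires one hit per gene (apply :func:`strongest_hit_per_gene` first);
    equal heights are ordered by gene_id so the ranking is deterministic and
    top-n is always a prefix of top-(n+1).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    ids = [h.gene_id for h in hits]
    if len(ids) != len(set(ids)):
        raise ValueError("hits must be deduplicated per gene (strongest_hit_per_gene)")
    ranked = sorted(hits, key=lambda h: (-h.height, h.gene_id))
    return CatchGeneList(entries=[(h.gene_id, h.height) for h in ranked[:n]])


def define_enhancers(me1: FeatureSet, ac: FeatureSet) -> FeatureSet:
    """Enhancers: union spans of H3K4me1/H3K27ac peak pairs overlapping >= 1 bp,
    merged into disjoint intervals."""
    me1 = me1.merged()
    ac = ac.merged()
    spans: list[GenomicInterval] = []
    for chrom in me1.chroms():
        a_list = me1.on_chrom(chrom)
        b_list = ac.on_chrom(chrom)
        j = 0
        for a in a_list:
            # advance past b intervals entirely left of a
            while j < len(b_list) and b_list[j].end <= a.start:
                j += 1
            k = j
            while k < len(b_list) and b_list[k].start < a.end:
                b = b_list[k]
                spans.append(
                    GenomicInterval(chrom, min(a.start, b.start), max(a.end, b.end))
                )
                k += 1
    return merge_intervals(FeatureSet(name="Enhancer", intervals=spans), gap=0)


def feature_adjacency(
    peaks: Sequence[Peak],
    features: FeatureSet,
    window: int = 2000,
) -> tuple[int, int, float]:
    """Count peaks within ``window`` bp of (or overlapping) any feature.

    Returns (n_peaks, n_adjacent, fraction); fraction is 0 when there are no
    peaks.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for chrom in features.chroms():
        by_chrom[chrom] = features.on_chrom(chrom)
    n_adjacent = 0
    for peak in peaks:
        ivs = by_chrom.get(peak.chrom, [])
        for iv in ivs:
            if interval_distance(peak.interval, iv) <= window:
                n_adjacent += 1
                break
    n_peaks = len(peaks)
    fraction = n_adjacent / n_peaks if n_peaks else 0.0
    return n_peaks, n_adjacent, fraction


def _silverman_bandwidth(offsets: np.ndarray) -> float:
    """0.9 * min(sd, IQR/1.34) * n^(-1/5), with the usual zero-IQR fallbacks."""
    n = offsets.size
    sd = float(np.std(offsets, ddof=1))
    q75, q25 = np.percentile(offsets, [75, 25])
    iqr = float(q75 - q25)
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        raise ValueError("offsets have zero spread; need >= 2 distinct values")
    return 0.9 * scale * n ** (-1 / 5)


def offset_density(
    offsets: Sequence[int] | np.ndarray,
    weights: Sequence[float] | np.ndarray | None = None,
    window: int = 2000,
) -> DensityProfile:
    """Gaussian KDE of signed TSS offsets on a 1-bp grid over [-window, window].

    Bandwidth is Silverman's rule-of-thumb computed from the unweighted
    offsets (matching the R ``density`` default the weights do not enter).
    """
    x = np.asarray(offsets, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct offsets for a density estimate")
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != x.shape:
            raise ValueError("weights must match offsets in length")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    h = _silverman_bandwidth(x)
    grid = np.arange(-window, window + 1, dtype=float)
    z = (grid[:, None] - x[None, :]) / h
    kern = np.exp(-0.5 * z * z)
    density = (kern * w[None, :]).sum(axis=1) / (
        w.sum() * h * np.sqrt(2.0 * np.pi)
    )
    return DensityProfile(grid=grid.astype(int), density=density, bandwidth=h)


def tss_density_profile(
    hits: Sequence[PromoterHit],
    window: int = 2000,
    weight_by_height: bool = True,
) -> DensityProfile:
    """Density of promoter-hit summit offsets around the TSS.

    Height-weighting (default) emphasises strong interactions, mirroring the
    use of signal strength in the underlying assay readout.
    """
    if len(hits) < 2:
        raise ValueError("need at least 2 promoter hits")
    offsets = np.array([h.signed_offset for h in hits], dtype=float)
    weights = (
        np.array([h.height for h in hits], dtype=float) if weight_by_height else None
    )
    return offset_density(offsets, weights=weights, window=window)
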