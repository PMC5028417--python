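"""The capture-to-coexpression prediction test.

Given the ranked list of genes physically interacting with the bait (the
capture gene list), three "seed" genes nearest the capture site are fed to a
coexpression ranking (a stand-in for a compendium-search engine: genes are
scored by their mean pairwise coexpression with the seeds).  The top K
coexpressed genes on the bait's chromosome form the coexpression list, and
the test asks whether the capture list overlaps it more than chance.

The null permutes the coexpression ranking of the chromosome's gene universe
uniformly at random, keeping list lengths fixed; the observed overlap is
converted to a one-sided P value through a Student t distribution on the
permutation mean and standard deviation.

Seed genes are excluded from the ranking, the coexpression list, and the
overlap count: they come from the capture list by construction, so counting
them would inflate the statistic circularly.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import (
    CatchGeneList,
    PromoterHit,
    assign_peaks_to_tss,
    strongest_hit_per_gene,
    top_n_genes,
)
from .core import CoverageTrack, GeneAnnotation, GenomicInterval, interval_distance
from .signal import call_peaks

__all__ = [
    "CoexpressionDB",
    "SeekList",
    "PredictionResult",
    "ResolutionCurve",
    "select_seed_genes",
    "build_seek_ranking",
    "make_seek_list",
    "predict_overlap",
    "permutation_test",
    "resolution_curve",
]


@dataclass
class CoexpressionDB:
    """Symmetric pairwise gene coexpression scores in [0, 1] with unit diagonal.

    ``chrom_of`` maps every gene in the universe to its chromosome label.
    """

    scores: pd.DataFrame
    chrom_of: dict[str, str]

    def __post_init__(self) -> None:
        ids = list(self.scores.index)
        if ids != list(self.scores.columns):
            raise ValueError("score matrix index and columns must match")
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids in score matrix")
        vals = self.scores.to_numpy(dtype=float)
        if vals.shape[0] != vals.shape[1]:
            raise ValueError("score matrix must be square")
        if not np.allclose(vals, vals.T, atol=1e-9):
            raise ValueError("score matrix must be symmetric")
        if not np.allclose(np.diag(vals), 1.0, atol=1e-9):
            raise ValueError("score matrix diagonal must be 1")
        if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
            raise ValueError("scores must lie in [0, 1]")
        missing = [g for g in ids if g not in self.chrom_of]
        if missing:
            raise ValueError(f"genes missing chromosome labels: {missing[:5]}...")

    @property
    def genes(self) -> list[str]:
        return list(self.scores.index)

    @property
    def n_genes(self) -> int:
        return len(self.scores.index)

    def genes_on(self, chrom: str) -> list[str]:
        return [g for g in self.genes if self.chrom_of[g] == chrom]

    @classmethod
    def from_files(cls, matrix_path: str, gene_map_path: str) -> "CoexpressionDB":
        scores = pd.read_csv(matrix_path, sep="\t", index_col=0)
        scores.index = scores.index.astype(str)
        scores.columns = scores.columns.astype(str)
        gmap = pd.read_csv(gene_map_path, sep="\t", dtype=str)
        chrom_of = dict(zip(gmap.iloc[:, 0], gmap.iloc[:, 1]))
        return cls(scores=scores, chrom_of=chrom_of)

    def to_files(self, matrix_path: str, gene_map_path: str) -> None:
        self.scores.to_csv(matrix_path, sep="\t")
        pd.DataFrame(
            {"gene_id": self.genes, "chrom": [self.chrom_of[g] for g in self.genes]}
        ).to_csv(gene_map_path, sep="\t", index=False)


@dataclass
class SeekList:
    """Top-K coexpressed genes restricted to one chromosome, seeds excluded."""

    genes: list[str]
    chrom: str
    K: int

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate genes in coexpression list")
        if len(self.genes) > self.K:
            raise ValueError("list longer than its stated depth K")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PredictionResult:
    """Observed capture/coexpression overlap against its permutation null."""

    k_obs: int
    K: int
    m: int
    n_chr: int
    null_mean: float
    null_sd: float
    n_perm: int
    p_value: float

    def summary(self) -> str:
        lines = [
            "Capture -> coexpression prediction test",
            "=" * 44,
            f"observed overlap (k_obs)     {self.k_obs:>10d}",
            f"coexpression depth (K)       {self.K:>10d}",
            f"capture gene-list size (m)   {self.m:>10d}",
            f"chromosome universe (N_chr)  {self.n_chr:>10d}",
            f"null mean                    {self.null_mean:>10.3f}",
            f"null sd                      {self.null_sd:>10.3f}",
            f"permutations                 {self.n_perm:>10d}",
            f"one-sided P (t dist.)        {self.p_value:>10.3g}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "k_obs": self.k_obs,
                    "K": self.K,
                    "m": self.m,
                    "n_chr": self.n_chr,
                    "null_mean": self.null_mean,
                    "null_sd": self.null_sd,
                    "n_perm": self.n_perm,
                    "p_value": self.p_value,
                }
            ]
        )


@dataclass
class ResolutionCurve:
    """-log10 P of the prediction test versus the number of capture genes,
    across a sweep of peak-height thresholds."""

    entries: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries,
            columns=["threshold", "m", "k_obs", "p_value", "neg_log10_p"],
        )


def select_seed_genes(
    hits: Sequence[PromoterHit],
    bait: GenomicInterval,
    gene_list: CatchGeneList,
    genes: Sequence[GeneAnnotation],
    exclude: Iterable[str] = (),
    n_seeds: int = 3,
) -> list[str]:
    """The n_seeds eligible genes whose TSS lies nearest the capture site.

    Eligibility: the gene has a promoter-proximal peak (appears in ``hits``),
    ranks in the capture gene list, and is not excluded (the bait's primary
    target gene is excluded by convention).  Ties in distance break
    lexicographically by gene_id.
    """
    excluded = set(exclude)
    hit_ids = {h.gene_id for h in hits}
    listed = set(gene_list.gene_ids)
    by_id = {g.gene_id: g for g in genes}
    candidates: list[tuple[int, str]] = []
    for gid in sorted(hit_ids & listed - excluded):
        gene = by_id.get(gid)
        if gene is None or gene.chrom != bait.chrom:
            continue
        tss_iv = GenomicInterval(gene.chrom, gene.tss, gene.tss + 1)
        candidates.append((interval_distance(tss_iv, bait), gid))
    candidates.sort()
    if len(candidates) < n_seeds:
        raise ValueError(
            f"only {len(candidates)} eligible seed genes; need {n_seeds}"
        )
    return [gid for _, gid in candidates[:n_seeds]]


def build_seek_ranking(db: CoexpressionDB, seeds: Sequence[str]) -> list[str]:
    """Rank all non-seed genes by mean pairwise coexpression with the seeds,
    descending; ties break by gene_id."""
    if len(seeds) == 0:
        raise ValueError("need at least one seed gene")
    missing = [s for s in seeds if s not in db.scores.index]
    if missing:
        raise ValueError(f"seed genes not in coexpression universe: {missing}")
    agg = db.scores.loc[:, list(seeds)].mean(axis=1)
    agg = agg.drop(index=list(seeds))
    order = sorted(agg.index, key=lambda g: (-agg[g], g))
    return order


def make_seek_list(
    ranking: Sequence[str], db: CoexpressionDB, chrom: str, K: int
) -> SeekList:
    """Filter the ranking to one chromosome, then truncate to depth K.

    Filter-then-truncate (not the reverse): the list must contain the K best
    genes *on the chromosome*, however deep they sit in the global ranking.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    on_chrom = [g for g in ranking if db.chrom_of.get(g) == chrom]
    if len(on_chrom) < K:
        warnings.warn(
            f"only {len(on_chrom)} genes on {chrom}; returning all of them "
            f"(requested K={K})",
            stacklevel=2,
        )
    return SeekList(genes=on_chrom[:K], chrom=chrom, K=K)


def predict_overlap(catch_genes: CatchGeneList, seek: SeekList) -> int:
    """Size of the intersection between the capture and coexpression lists."""
    return len(set(catch_genes.gene_ids) & set(seek.genes))


def permutation_test(
    catch_genes: CatchGeneList,
    ranking: Sequence[str],
    db: CoexpressionDB,
    chrom: str,
    K: int,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    restrict: str = "chromosome",
) -> PredictionResult:
    """Permutation null for the capture/coexpression overlap.

    The observed overlap k_obs comes from the true ranking's chromosome-
    restricted top K.  Each null draw permutes the ranking uniformly at
    random (by default over the chromosome-restricted universe; with
    ``restrict="global"`` over the full ranking before chromosome filtering),
    takes the top K, and intersects with the capture list.  The one-sided
    upper-tail P value uses Student's t with n_perm - 1 degrees of freedom on
    the standardized observed overlap.
    """
    if restrict not in ("chromosome", "global"):
        raise ValueError(f"unknown restrict mode {restrict!r}")
    if len(catch_genes) == 0:
        raise ValueError("capture gene list is empty")
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    universe = [g for g in ranking if db.chrom_of.get(g) == chrom]
    n_chr = len(universe)
    if K > n_chr:
        raise ValueError(f"K={K} exceeds chromosome universe size {n_chr}")

    seek = make_seek_list(ranking, db, chrom, K)
    k_obs = predict_overlap(catch_genes, seek)

    catch_set = set(catch_genes.gene_ids)
    if restrict == "chromosome":
        mask = np.array([g in catch_set for g in universe], dtype=bool)
        n_pool = n_chr
    else:
        mask = np.array([g in catch_set for g in ranking], dtype=bool)
        chrom_mask = np.array(
            [db.chrom_of.get(g) == chrom for g in ranking], dtype=bool
        )
        n_pool = len(ranking)

    draws = np.empty(n_perm, dtype=float)
    for i in range(n_perm):
        perm = rng.permutation(n_pool)
        if restrict == "chromosome":
            top = perm[:K]
            draws[i] = mask[top].sum()
        else:
            on_chrom = perm[chrom_mask[perm]][:K]
            draws[i] = mask[on_chrom].sum()

    null_mean = float(draws.mean())
    null_sd = float(draws.std(ddof=1))
    if null_sd == 0.0:
        p_value = 1.0 if k_obs <= null_mean else 1.0 / (n_perm + 1)
    else:
        t_stat = (k_obs - null_mean) / null_sd
        p_value = float(stats.t.sf(t_stat, df=n_perm - 1))
        p_value = min(max(p_value, np.nextafter(0, 1)), 1.0)
    return PredictionResult(
        k_obs=k_obs,
        K=K,
        m=len(catch_genes),
        n_chr=n_chr,
        null_mean=null_mean,
        null_sd=null_sd,
        n_perm=n_perm,
        p_value=p_value,
    )


def resolution_curve(
    track: CoverageTrack,
    genes: Sequence[GeneAnnotation],
    db: CoexpressionDB,
    bait: GenomicInterval,
    chrom: str,
    K: int,
    thresholds: Sequence[float],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    window: int = 2000,
    top_n: int = 500,
    exclude: Iterable[str] = (),
    n_seeds: int = 3,
    merge_gap: int = 0,
) -> ResolutionCurve:
    """Prediction-test P value as a function of the capture gene count.

    Each threshold is run through the full chain (peak calling, promoter
    annotation, top-N list, seed selection, coexpression ranking, permutation
    test); thresholds yielding no genes, or too few eligible seeds, are
    skipped with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    curve = ResolutionCurve()
    for t in thresholds:
        peaks = call_peaks(track, t, merge_gap=merge_gap)
        hits = strongest_hit_per_gene(
            assign_peaks_to_tss(peaks, genes, window=window)
        )
        if not hits:
            warnings.warn(f"threshold {t}: no capture genes; skipped", stacklevel=2)
            continue
        gene_list = top_n_genes(hits, n=top_n)
        try:
            seeds = select_seed_genes(
                hits, bait, gene_list, genes, exclude=exclude, n_seeds=n_seeds
            )
        except ValueError as exc:
            warnings.warn(f"threshold {t}: {exc}; skipped", stacklevel=2)
            continue
        ranking = build_seek_ranking(db, seeds)
        result = permutation_test(
            gene_list, ranking, db, chrom, K, n_perm=n_perm, seed=rng
        )
        curve.entries.append(
            {
                "threshold": float(t),
                "m": result.m,
                "k_obs": result.k_obs,
                "p_value": result.p_value,
                "neg_log10_p": -math.log10(result.p_value),
            }
        )
    return curve
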