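"""End-to-end orchestration of the analysis stages.

Every stage draws its randomness from a named substream derived from the
single pipeline seed, so stages are independently reproducible and changing
one stage's replicate count (e.g. the number of shuffles) cannot perturb any
other stage.
"""
from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import annotate, coexpression, enrichment, signal
from .core import (
    FeatureSet,
    GenomicInterval,
    read_bed,
    read_bedgraph,
    read_chrom_sizes,
    read_genes_bed,
    write_bed,
    write_bedgraph,
)

__all__ = ["PipelineConfig", "run_pipeline", "stage_rng"]

logger = logging.getLogger("catchseq")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named per-stage substream: deterministic in (seed, stage), independent
    across stage names."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(stage.encode())])
    )


@dataclass
class PipelineConfig:
    """Paths and parameters for one full run.

    ``treatment_b``/``control_b`` enable the two-condition comparison stage;
    coexpression inputs enable the prediction test.  All defaults mirror the
    canonical analysis: 2 kb windows, top 500 genes, threshold sweep
    100..500 step 50, coexpression depth 100.
    """

    treatment: str = ""
    control: str = ""
    genes: str = ""
    h3k4me1: str = ""
    h3k27ac: str = ""
    chrom_sizes: str = ""
    outdir: str = "catch_out"
    # optional inputs
    er_sites: str = ""
    ctcf_sites: str = ""
    treatment_b: str = ""
    control_b: str = ""
    coexpression: str = ""
    gene_map: str = ""
    bait_chrom: str = ""
    bait_start: int = -1
    bait_end: int = -1
    exclude_genes: tuple[str, ...] = ()
    # parameters
    bin_size: int = 50
    window: int = 2000
    top_n: int = 500
    threshold: float = 100.0
    thresholds: tuple[float, ...] = tuple(float(t) for t in range(100, 501, 50))
    merge_gap: int = 0
    K: int = 100
    n_perm: int = 1000
    n_shuffles: int = 100
    n_seeds: int = 3
    rng_seed: int = 0
    scale_mode: str = "match_totals"

    def __post_init__(self) -> None:
        for name in ("bin_size", "window", "top_n", "K", "n_perm", "n_shuffles"):
            if getattr(self, name) < (0 if name == "window" else 1):
                raise ValueError(f"{name} must be positive")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    @classmethod
    def from_flat_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs: dict = {}
        fields_ = cls.__dataclass_fields__
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in fields_:
                    raise ValueError(f"unknown config key {key!r}")
                ftype = str(fields_[key].type)
                if key in ("thresholds", "exclude_genes"):
                    items = [v for v in value.split(",") if v]
                    kwargs[key] = (
                        tuple(float(v) for v in items)
                        if key == "thresholds"
                        else tuple(items)
                    )
                elif "int" in ftype:
                    kwargs[key] = int(value)
                elif "float" in ftype:
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _annotate_condition(
    treatment_path: str,
    control_path: str,
    cfg: PipelineConfig,
    chrom_length: int,
    genes,
    outdir: Path,
    tag: str,
) -> tuple:
    """Subtract, call, annotate, rank for one condition; returns the pieces."""
    for path, stage in ((treatment_path, "treatment"), (control_path, "control")):
        if not Path(path).exists():
            raise FileNotFoundError(f"stage subtract[{tag}]: missing {stage} file {path}")
    treatment = read_bedgraph(treatment_path, chrom_length, cfg.bin_size)
    control = read_bedgraph(control_path, chrom_length, cfg.bin_size)
    subtracted = signal.subtract_background(treatment, control, cfg.scale_mode)
    peaks = signal.call_peaks(subtracted, cfg.threshold, merge_gap=cfg.merge_gap)
    hits = annotate.strongest_hit_per_gene(
        annotate.assign_peaks_to_tss(peaks, genes, window=cfg.window)
    )
    gene_list = annotate.top_n_genes(hits, n=cfg.top_n) if hits else annotate.CatchGeneList()
    logger.info(
        "condition %s: %d peaks at threshold %g, %d promoter genes",
        tag, len(peaks), cfg.threshold, len(hits),
    )
    write_bedgraph(subtracted, outdir / f"subtracted_{tag}.bedgraph")
    peak_fs = FeatureSet(f"peaks_{tag}", [p.interval for p in peaks])
    with open(outdir / f"peaks_{tag}.bed", "w") as fh:
        for i, p in enumerate(peaks):
            fh.write(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"peak_{tag}_{i}\t{p.height:g}\t.\n"
            )
    pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "chrom": h.peak.chrom,
                "summit": h.peak.summit,
                "signed_offset": h.signed_offset,
                "height": h.height,
            }
            for h in hits
        ],
        columns=["gene_id", "chrom", "summit", "signed_offset", "height"],
    ).to_csv(outdir / f"promoter_hits_{tag}.tsv", sep="\t", index=False)
    pd.DataFrame(
        gene_list.entries, columns=["gene_id", "best_height"]
    ).to_csv(outdir / f"gene_list_{tag}.tsv", sep="\t", index=False)
    return subtracted, peaks, hits, gene_list


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns a bundle of in-memory results.

    Outputs are written to ``cfg.outdir`` as TSV/BED/bedGraph, alongside a
    machine-readable run manifest with parameters and output digests.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for path, stage in (
        (cfg.genes, "annotate:genes"),
        (cfg.chrom_sizes, "io:chrom_sizes"),
        (cfg.h3k4me1, "enhancers:h3k4me1"),
        (cfg.h3k27ac, "enhancers:h3k27ac"),
    ):
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"stage {stage}: missing input file {path!r}")

    sizes = read_chrom_sizes(cfg.chrom_sizes)
    genes = read_genes_bed(cfg.genes)
    chroms = {g.chrom for g in genes}
    if len(chroms) != 1:
        raise ValueError("pipeline runs per-chromosome; gene table spans several")
    chrom = chroms.pop()
    chrom_length = sizes[chrom]

    subtracted, peaks, hits, gene_list = _annotate_condition(
        cfg.treatment, cfg.control, cfg, chrom_length, genes, outdir, "a"
    )

    enhancers = annotate.define_enhancers(
        read_bed(cfg.h3k4me1, "H3K4me1"), read_bed(cfg.h3k27ac, "H3K27ac")
    )
    write_bed(enhancers, outdir / "enhancers.bed")

    if len(hits) >= 2:
        profile = annotate.tss_density_profile(hits, window=cfg.window)
        pd.DataFrame({"offset": profile.grid, "density": profile.density}).to_csv(
            outdir / "tss_density.tsv", sep="\t", index=False
        )
    else:
        profile = None

    curve = enrichment.threshold_sweep(
        subtracted,
        enhancers,
        thresholds=cfg.thresholds,
        window=cfg.window,
        n_shuffles=cfg.n_shuffles,
        seed=stage_rng(cfg.rng_seed, "enrich"),
        merge_gap=cfg.merge_gap,
    )
    curve.to_frame().to_csv(outdir / "overlap_curve.tsv", sep="\t", index=False)

    results: dict = {
        "subtracted": subtracted,
        "peaks": peaks,
        "hits": hits,
        "gene_list": gene_list,
        "enhancers": enhancers,
        "density": profile,
        "overlap_curve": curve,
        "comparison": None,
        "prediction": None,
    }

    if cfg.treatment_b:
        _, _, _, gene_list_b = _annotate_condition(
            cfg.treatment_b, cfg.control_b, cfg, chrom_length, genes, outdir, "b"
        )
        comparison = enrichment.compare_conditions(gene_list, gene_list_b)
        comparison.to_frame().to_csv(outdir / "comparison.tsv", sep="\t", index=False)
        results["comparison"] = comparison

    if cfg.coexpression:
        db = coexpression.CoexpressionDB.from_files(cfg.coexpression, cfg.gene_map)
        bait = GenomicInterval(cfg.bait_chrom or chrom, cfg.bait_start, cfg.bait_end)
        seeds = coexpression.select_seed_genes(
            hits, bait, gene_list, genes,
            exclude=cfg.exclude_genes, n_seeds=cfg.n_seeds,
        )
        ranking = coexpression.build_seek_ranking(db, seeds)
        prediction = coexpression.permutation_test(
            gene_list, ranking, db, chrom, cfg.K,
            n_perm=cfg.n_perm, seed=stage_rng(cfg.rng_seed, "coexpress"),
        )
        prediction.to_frame().to_csv(outdir / "prediction.tsv", sep="\t", index=False)
        results["seeds"] = seeds
        results["prediction"] = prediction
        logger.info("prediction test: %s", prediction.summary().replace("\n", " | "))

    manifest = {
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "outputs": {
            p.name: _digest(p) for p in sorted(outdir.iterdir()) if p.is_file()
            and p.name != "run_manifest.json"
        },
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return results
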