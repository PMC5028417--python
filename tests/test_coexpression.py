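"""Seed selection, coexpression ranking, chromosome-restricted top-K lists,
and the permutation test with its hypergeometric null."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from catchseq.annotate import CatchGeneList, PromoterHit
from catchseq.coexpression import (
    CoexpressionDB,
    build_seek_ranking,
    make_seek_list,
    permutation_test,
    predict_overlap,
    resolution_curve,
    select_seed_genes,
)
from catchseq.core import GeneAnnotation, GenomicInterval, Peak


def make_db(ids, chroms=None, scores=None, rng=None):
    n = len(ids)
    if scores is None:
        rng = rng or np.random.default_rng(0)
        m = rng.uniform(0, 1, size=(n, n))
        scores = (m + m.T) / 2
        np.fill_diagonal(scores, 1.0)
    chrom_of = dict(zip(ids, chroms or ["chr1"] * n))
    return CoexpressionDB(
        scores=pd.DataFrame(scores, index=ids, columns=ids), chrom_of=chrom_of
    )


def gene(gid, tss, chrom="chr1"):
    return GeneAnnotation(gid, chrom, "+", GenomicInterval(chrom, tss, tss + 100, "+"))


def hit(gid, summit):
    return PromoterHit(
        gid,
        Peak(GenomicInterval("chr1", summit - 10, summit + 10), 100.0, summit),
        0,
    )


def gl(ids):
    return CatchGeneList(entries=[(g, 100.0) for g in sorted(ids)])


class TestCoexpressionDB:
    def test_rejects_asymmetric(self):
        s = np.array([[1.0, 0.2], [0.3, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            make_db(["A", "B"], scores=s)

    def test_rejects_bad_diagonal(self):
        s = np.array([[0.5, 0.2], [0.2, 1.0]])
        with pytest.raises(ValueError, match="diagonal"):
            make_db(["A", "B"], scores=s)

    def test_file_roundtrip(self, tmp_path):
        db = make_db(["A", "B", "C"], chroms=["chr1", "chr1", "chr2"])
        db.to_files(str(tmp_path / "m.tsv"), str(tmp_path / "g.tsv"))
        back = CoexpressionDB.from_files(str(tmp_path / "m.tsv"),
                                         str(tmp_path / "g.tsv"))
        pd.testing.assert_frame_equal(back.scores, db.scores)
        assert back.chrom_of == db.chrom_of


class TestSelectSeedGenes:
    genes = [gene("A", 11_000), gene("B", 13_000), gene("C", 20_000),
             gene("D", 60_000), gene("E", 2_010_000)]
    bait = GenomicInterval("chr1", 10_000, 10_100)

    def test_nearest_three(self):
        hits = [hit(g.gene_id, g.tss + 50) for g in self.genes]
        seeds = select_seed_genes(hits, self.bait, gl("ABCDE"), self.genes)
        assert seeds == ["A", "B", "C"]

    def test_primary_target_excluded(self):
        hits = [hit(g.gene_id, g.tss + 50) for g in self.genes]
        seeds = select_seed_genes(hits, self.bait, gl("ABCDE"), self.genes,
                                  exclude=["A"])
        assert seeds == ["B", "C", "D"]

    def test_must_be_in_gene_list_and_hits(self):
        hits = [hit(g.gene_id, g.tss + 50) for g in self.genes if g.gene_id != "B"]
        seeds = select_seed_genes(hits, self.bait, gl("ACDE"), self.genes)
        assert seeds == ["A", "C", "D"]

    def test_equidistant_tie_lexicographic(self):
        genes = [gene("Z", 9_000), gene("Y", 11_099)]
        # Z tss 9000: gap 10_000-9_001 = 999; Y tss 11_099: gap 999
        hits = [hit("Z", 9_000), hit("Y", 11_099)]
        seeds = select_seed_genes(hits, self.bait, gl("ZY"), genes, n_seeds=2)
        assert seeds == ["Y", "Z"]

    def test_too_few_eligible_errors(self):
        hits = [hit("A", 11_050)]
        with pytest.raises(ValueError, match="eligible seed"):
            select_seed_genes(hits, self.bait, gl("A"), self.genes)


class TestSeekRanking:
    def test_single_seed_ranks_by_its_column(self):
        s = np.array([
            [1.0, 0.9, 0.1, 0.5],
            [0.9, 1.0, 0.3, 0.2],
            [0.1, 0.3, 1.0, 0.8],
            [0.5, 0.2, 0.8, 1.0],
        ])
        db = make_db(["S", "A", "B", "C"], scores=s)
        assert build_seek_ranking(db, ["S"]) == ["A", "C", "B"]

    def test_mean_aggregation_over_two_seeds(self):
        s = np.full((4, 4), 0.4)
        s[0, 2] = s[2, 0] = 0.9   # S1-A
        s[1, 2] = s[2, 1] = 0.1   # S2-A
        s[0, 3] = s[3, 0] = 0.6   # S1-B
        s[1, 3] = s[3, 1] = 0.6   # S2-B
        np.fill_diagonal(s, 1.0)
        db = make_db(["S1", "S2", "A", "B"], scores=s)
        # A: (0.9+0.1)/2 = 0.5 < B: 0.6
        assert build_seek_ranking(db, ["S1", "S2"]) == ["B", "A"]

    def test_all_equal_lexicographic(self):
        s = np.full((4, 4), 0.5)
        np.fill_diagonal(s, 1.0)
        db = make_db(["S", "C", "A", "B"], scores=s)
        assert build_seek_ranking(db, ["S"]) == ["A", "B", "C"]

    def test_empty_seeds_rejected(self):
        with pytest.raises(ValueError):
            build_seek_ranking(make_db(["A", "B"]), [])

    def test_seeds_never_in_list(self):
        rng = np.random.default_rng(2)
        ids = [f"G{i}" for i in range(30)]
        db = make_db(ids, rng=rng)
        ranking = build_seek_ranking(db, ["G3", "G7"])
        seek = make_seek_list(ranking, db, "chr1", K=10)
        assert "G3" not in seek.genes and "G7" not in seek.genes
        assert "G3" not in ranking and "G7" not in ranking


class TestMakeSeekList:
    def test_undersized_chromosome_warns(self):
        db = make_db(["A", "B", "C"], chroms=["chr1", "chr1", "chr2"])
        ranking = ["A", "C", "B"]
        with pytest.warns(UserWarning, match="returning all"):
            seek = make_seek_list(ranking, db, "chr1", K=5)
        assert seek.genes == ["A", "B"]

    def test_k_one(self):
        db = make_db(["A", "B"], chroms=["chr1", "chr1"])
        assert make_seek_list(["B", "A"], db, "chr1", K=1).genes == ["B"]

    def test_filter_then_truncate_order(self):
        # 6-gene toy: filter-then-truncate differs from truncate-then-filter
        ids = ["A", "B", "C", "D", "E", "F"]
        chroms = ["chr2", "chr2", "chr1", "chr2", "chr1", "chr1"]
        db = make_db(ids, chroms=chroms)
        ranking = ["A", "B", "C", "D", "E", "F"]
        seek = make_seek_list(ranking, db, "chr1", K=2)
        assert seek.genes == ["C", "E"]
        truncate_first = [g for g in ranking[:2] if db.chrom_of[g] == "chr1"]
        assert truncate_first != seek.genes


class TestPredictOverlap:
    def test_superset(self):
        from catchseq.coexpression import SeekList
        seek = SeekList(["A", "B"], "chr1", 2)
        assert predict_overlap(gl(["A", "B", "C"]), seek) == 2

    def test_disjoint_and_partial(self):
        from catchseq.coexpression import SeekList
        assert predict_overlap(gl(["A"]), SeekList(["B"], "chr1", 1)) == 0
        assert predict_overlap(gl(["A", "B", "C"]),
                               SeekList(["B", "C", "D"], "chr1", 3)) == 2


class TestPermutationTest:
    def test_null_mean_matches_enumeration_small_universe(self):
        """Exact check: over all 6! orderings of a 6-gene universe the mean
        top-3 overlap with a 2-gene capture list is m*K/N = 1.0."""
        ids = [f"G{i}" for i in range(6)]
        db = make_db(ids)
        catch = {"G0", "G1"}
        overlaps = [
            len(set(perm[:3]) & catch) for perm in itertools.permutations(ids)
        ]
        exact_mean = sum(overlaps) / len(overlaps)
        assert exact_mean == pytest.approx(2 * 3 / 6)
        res = permutation_test(gl(catch), ids, db, "chr1", K=3,
                               n_perm=2000, seed=3)
        se = res.null_sd / math.sqrt(res.n_perm)
        assert abs(res.null_mean - exact_mean) <= 3 * se

    def test_null_mean_matches_hypergeometric_large(self):
        ids = [f"G{i:03d}" for i in range(500)]
        db = make_db(ids, rng=np.random.default_rng(5))
        catch = gl(ids[:50])
        res = permutation_test(catch, ids, db, "chr1", K=100,
                               n_perm=2000, seed=4)
        expected = 50 * 100 / 500
        se = res.null_sd / math.sqrt(res.n_perm)
        assert abs(res.null_mean - expected) <= 3 * se

    def test_k_exceeding_universe_rejected(self):
        ids = ["A", "B", "C"]
        db = make_db(ids)
        with pytest.raises(ValueError, match="exceeds"):
            permutation_test(gl(["A"]), ids, db, "chr1", K=5, n_perm=10, seed=0)

    def test_deterministic_given_seed(self):
        ids = [f"G{i}" for i in range(40)]
        db = make_db(ids, rng=np.random.default_rng(6))
        a = permutation_test(gl(ids[:10]), ids, db, "chr1", K=8, n_perm=200, seed=9)
        b = permutation_test(gl(ids[:10]), ids, db, "chr1", K=8, n_perm=200, seed=9)
        assert a == b

    def test_planted_signal_significant(self, small_config):
        """Capture list equal to the coexpressed block -> tiny P."""
        from catchseq import generate_dataset
        ds = generate_dataset(small_config)
        inter = sorted(ds.manifest.interactor_gene_ids)
        seeds = inter[:3]
        ranking = build_seek_ranking(ds.coexpression, seeds)
        res = permutation_test(gl(inter), ranking, ds.coexpression,
                               small_config.chrom, K=20, n_perm=500, seed=1)
        assert res.k_obs > res.null_mean + 3 * res.null_sd
        assert res.p_value < 0.05

    def test_p_half_when_observation_equals_null_mean(self):
        """t = 0 at k_obs == null_mean must give one-sided P = 0.5; checked by
        construction on a symmetric toy universe."""
        ids = [f"G{i}" for i in range(8)]
        db = make_db(ids)
        # K=4 of 8 with all 8 in the capture list -> overlap always 4 == mean
        res = permutation_test(gl(ids), ids, db, "chr1", K=4, n_perm=100, seed=0)
        assert res.null_sd == 0.0 and res.k_obs == 4
        assert res.p_value == 1.0  # degenerate null: k_obs <= null_mean
        # non-degenerate: interleave the ranking so k_obs hits the
        # hypergeometric mean m*K/N = 4*4/8 = 2 exactly -> t ~ 0 -> P ~ 0.5
        ranking = ["G0", "G4", "G1", "G5", "G2", "G6", "G3", "G7"]
        res2 = permutation_test(gl(["G0", "G1", "G2", "G3"]), ranking, db,
                                "chr1", K=4, n_perm=4000, seed=2)
        assert res2.k_obs == 2
        assert 0.4 < res2.p_value < 0.6

    def test_global_restriction_mode_runs(self):
        ids = [f"G{i}" for i in range(20)]
        chroms = ["chr1" if i % 2 else "chr2" for i in range(20)]
        db = make_db(ids, chroms=chroms)
        res = permutation_test(gl([g for g, c in zip(ids, chroms) if c == "chr1"][:5]),
                               ids, db, "chr1", K=5, n_perm=200, seed=0,
                               restrict="global")
        assert 0 < res.p_value <= 1


class TestResolutionCurve:
    def test_single_threshold_matches_direct_call(self, small_config):
        import dataclasses
        from catchseq import generate_dataset, subtract_background
        from catchseq.annotate import (assign_peaks_to_tss,
                                       strongest_hit_per_gene, top_n_genes)
        from catchseq.signal import call_peaks
        ds = generate_dataset(small_config)
        sub = subtract_background(ds.treatment, ds.control)
        curve = resolution_curve(
            sub, ds.genes, ds.coexpression, ds.bait, small_config.chrom,
            K=20, thresholds=[100.0], n_perm=300, seed=13,
        )
        assert len(curve.entries) == 1
        peaks = call_peaks(sub, 100.0)
        hits = strongest_hit_per_gene(assign_peaks_to_tss(peaks, ds.genes))
        gene_list = top_n_genes(hits)
        seeds = select_seed_genes(hits, ds.bait, gene_list, ds.genes)
        ranking = build_seek_ranking(ds.coexpression, seeds)
        direct = permutation_test(gene_list, ranking, ds.coexpression,
                                  small_config.chrom, K=20, n_perm=300,
                                  seed=np.random.default_rng(13))
        entry = curve.entries[0]
        assert entry["m"] == direct.m
        assert entry["k_obs"] == direct.k_obs
        assert entry["p_value"] == pytest.approx(direct.p_value)

    def test_impossible_threshold_skipped_with_warning(self, small_config):
        from catchseq import generate_dataset, subtract_background
        ds = generate_dataset(small_config)
        sub = subtract_background(ds.treatment, ds.control)
        with pytest.warns(UserWarning, match="skipped"):
            curve = resolution_curve(
                sub, ds.genes, ds.coexpression, ds.bait, small_config.chrom,
                K=20, thresholds=[100.0, 1e9], n_perm=100, seed=0,
            )
        assert [e["threshold"] for e in curve.entries] == [100.0]

    def test_planted_curve_significant_at_moderate_thresholds(self, small_config):
        from catchseq import generate_dataset, subtract_background
        ds = generate_dataset(small_config)
        sub = subtract_background(ds.treatment, ds.control)
        curve = resolution_curve(
            sub, ds.genes, ds.coexpression, ds.bait, small_config.chrom,
            K=20, thresholds=[100.0, 200.0], n_perm=500, seed=21,
        )
        assert all(e["neg_log10_p"] > -math.log10(0.05) for e in curve.entries)
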