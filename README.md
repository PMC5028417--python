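# catchseq

Downstream analysis of chromatin-interaction capture sequencing
(CATCH-seq–style assays), in which a single genomic locus — the *bait* — is
captured together with every locus physically looped to it, and interacting
regions appear as coverage peaks along the chromosome.

The package takes per-chromosome coverage tracks for a capture experiment
and its unfixed (no-crosslink) control and carries the analysis through to a
statistical statement about transcriptional coordination:

1. **Background subtraction** — the unfixed control measures
   non-interaction background; it is depth-scaled and subtracted per bin,
   with negative differences clamped to zero.
2. **Peak calling** — interaction peaks are maximal runs of bins with
   subtracted signal ≥ a height threshold (the canonical sweep is 100–500).
3. **Promoter annotation** — peaks within 2 kb of a gene TSS become
   promoter hits; per gene only the strongest peak counts, and the top 500
   genes by peak height form the *capture gene list*. The strand-aware
   summit-to-TSS offsets are summarised by a kernel-density profile whose
   mode locates the typical interaction point (≈100–200 bp downstream of
   the TSS).
4. **Enhancer enrichment** — enhancers are defined as ≥1 bp overlaps of
   H3K4me1 and H3K27ac peaks (union span, merged). Observed peak–enhancer
   adjacency (within 2 kb) across the threshold sweep is compared against a
   uniform peak-relocation null.
5. **Condition comparison** — shared / lost / gained genes between two
   conditions, with the overlap percentage defined on the union.
6. **Coexpression prediction** — the three capture-identified genes nearest
   the bait (excluding the bait's primary target) seed a coexpression
   ranking; the top *K* coexpressed genes on the bait's chromosome are
   intersected with the capture list. Significance comes from permuting the
   chromosome's ranking: with observed overlap k, null mean μ̂ and sd σ̂
   over n permutations, the one-sided P value is
   P(T > (k − μ̂)/σ̂) under Student's t with n − 1 degrees of freedom.
   Under a uniform permutation the null mean is the hypergeometric
   expectation mK/N_chr, which the test suite verifies by enumeration.

A synthetic-data generator (`catchseq.simulate`) produces complete
experiments — genes, treatment/control tracks with planted peaks, histone
mark / ER / CTCF BED files, and a coexpression matrix with a correlated
interactor block — together with a truth manifest, so the whole pipeline is
testable end to end with known ground truth.

## Worked example

```python
import catchseq as cs

ds = cs.generate_dataset(cs.SyntheticConfig(rng_seed=1))
sub = cs.subtract_background(ds.treatment, ds.control)
peaks = cs.call_peaks(sub, threshold=100)
hits = cs.strongest_hit_per_gene(cs.assign_peaks_to_tss(peaks, ds.genes, window=2000))
genes = cs.top_n_genes(hits, n=500)
print("peaks:", len(peaks), "| promoter genes:", len(genes))
print("precision/recall vs truth:", cs.truth_recall(genes.gene_ids, ds.manifest))

prof = cs.tss_density_profile(hits)
print("TSS density mode: %+d bp" % prof.mode_offset)

enh = cs.define_enhancers(ds.h3k4me1, ds.h3k27ac)
n, adj, frac = cs.feature_adjacency(peaks, enh)
print("enhancer adjacency: %d/%d peaks (%.0f%%)" % (adj, n, 100 * frac))

seeds = cs.select_seed_genes(hits, ds.bait, genes, ds.genes)
rank = cs.build_seek_ranking(ds.coexpression, seeds)
res = cs.permutation_test(genes, rank, ds.coexpression, ds.config.chrom,
                          K=100, n_perm=1000, seed=0)
print(res.summary())
```

prints

```
peaks: 40 | promoter genes: 40
precision/recall vs truth: (1.0, 1.0)
TSS density mode: +103 bp
enhancer adjacency: 34/40 peaks (85%)
Capture -> coexpression prediction test
============================================
observed overlap (k_obs)             37
coexpression depth (K)              100
capture gene-list size (m)           40
chromosome universe (N_chr)         197
null mean                        18.778
null sd                           2.810
permutations                       1000
one-sided P (t dist.)          6.99e-11
```

All 40 planted interactor genes are recovered with no false positives; the
density mode sits near the planted +112 bp downstream offset; 85 % of peaks
lie at enhancers (the generator's enhancer fraction); and the capture list
overlaps the coexpression list far beyond the permutation null mean of
mK/N_chr = 40·100/197 ≈ 20.

The same stages are available from the shell via the `catch` console
script: `catch sim`, `catch call`, `catch annotate`, `catch enrich`,
`catch compare`, `catch coexpress`, and `catch run` for a whole configured
pipeline.

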