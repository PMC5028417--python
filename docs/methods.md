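# Methods

## The analysis model

A capture experiment hybridises a biotinylated oligo to one genomic locus
(the bait) after formaldehyde crosslinking, so sequencing coverage
accumulates both at the bait and at loci physically looped to it. An
identical capture without fixation recovers only hybridisation and
shearing background. The analysis model is therefore additive: treatment
coverage = interaction signal + background, with the unfixed control an
independent realisation of the background alone.

**Subtraction.** Tracks are binned (default 50 bp; the bin value is the
coverage-weighted mean of overlapping bedGraph spans, uncovered bases
counting zero). By default the control is scaled by the ratio of total
signals before per-bin subtraction (`scale_mode="match_totals"`),
approximating sequencing-depth normalisation; `"none"` gives raw
subtraction. Negative differences are clamped to zero: downstream
thresholding uses only positive signal, and clamping keeps every track a
valid non-negative object. If the control has zero total signal the scaled
mode falls back to raw subtraction with a warning.

**Peak calling.** A peak is a maximal run of bins with subtracted value ≥
threshold, after bridging sub-threshold gaps of ≤ `merge_gap` bins
(default 0). Height is the maximum bin value in the run; the summit is the
midpoint of the leftmost maximal bin (leftmost is the deterministic
tie-break throughout). Peak counts need not fall monotonically with the
threshold — a rising threshold can split one bridged run in two — so the
sweep recomputes calls per threshold rather than nesting them.

**Promoter annotation.** Coordinates are 0-based half-open everywhere; a
minus-strand gene's TSS is `body.end − 1`. A peak is assigned to a gene
when its interval overlaps the promoter window `[tss − w, tss + w)`
(default w = 2000); the window always includes the TSS base so w = 0
degenerates to "peaks covering the TSS". Offsets are summit-based and
strand-aware (positive = downstream in the transcriptional direction);
assignment is deliberately the more permissive interval-overlap reading,
while the offset statistic uses the summit. Per gene only the strongest
peak is kept (tie: smaller |offset|, then leftmost summit), and the top N
(default 500) genes by height form the capture gene list, with
lexicographic gene-id order on ties so top-n is a prefix of top-(n+1).

**Density profile.** The summit-offset density is a Gaussian KDE on a 1-bp
grid over [−w, w], height-weighted by default, with Silverman's
rule-of-thumb bandwidth 0.9·min(sd, IQR/1.34)·n^(−1/5) computed from the
unweighted offsets (the R `density` default, which the weights do not
enter). The reported mode is the leftmost grid argmax. Whether the profile
should use every above-background bin or only called peaks is ambiguous in
principle; this implementation profiles called-peak summits, which is the
quantity the rest of the pipeline reasons about.

**Enhancers and adjacency.** An enhancer is the union span of an H3K4me1
peak and an H3K27ac peak overlapping by ≥ 1 bp, all spans then merged
(gap 0). Under half-open coordinates abutting intervals share no base, so
abutment does not qualify — and `merge_intervals` at gap 0 likewise leaves
abutting intervals unmerged, while any positive gap bridges them. A peak is
adjacent to a feature set when its interval distance (0 for overlap or
abutment) to the nearest feature is ≤ 2 kb.

**Enrichment null.** Each peak is independently relocated to a uniform
random start in `[0, chrom_length − width)`, preserving width and height.
The null adjacency fraction has a closed geometric form — the fraction of
eligible start positions — which the tests compute by exact enumeration on
toy chromosomes and compare against the empirical null. The observed
fraction is reported with the null mean and sd over `n_shuffles` (default
100) relocations per threshold. Nulls are per-chromosome; no GC or
mappability matching is attempted.

**Condition comparison.** Shared/lost/gained sets are plain set algebra on
gene ids; the overlap percentage is 100·|A∩B|/|A∪B| rounded half away from
zero. The union denominator is the convention that makes the reported
percentage consistent with the shared/lost/gained counts it accompanies.

**Coexpression prediction.** Seeds are the `n_seeds` = 3 eligible genes
whose TSS is nearest the bait, where eligible means: has a promoter hit, is
in the capture gene list, and is not excluded (the bait's primary target
gene is excluded by convention; distance ties break lexicographically).
The coexpression ranking scores every non-seed gene by its mean pairwise
score with the seeds — a deliberately simple, monotone aggregator standing
in for compendium-search engines whose dataset weighting is out of scope.
The chromosome-restricted top K (filter, then truncate) is the
coexpression list; seeds are excluded from the ranking, the list, and the
overlap count, since they are drawn from the capture list by construction
and would inflate the statistic circularly. The null permutes the
chromosome-restricted universe uniformly (a flag permutes the global
ranking first instead), takes the top K, and intersects with the capture
list; the P value is the upper tail of Student's t with n_perm − 1 df on
the standardized observed overlap. A degenerate null (sd 0) reports P = 1
when k_obs ≤ null mean and 1/(n_perm + 1) otherwise. Under uniform
permutation the null mean is the hypergeometric expectation m·K/N_chr,
verified exactly by enumeration at N ≤ 7 and by closed form at larger N.
The resolution curve repeats the full chain per threshold and reports
(m, P, −log10 P), skipping thresholds that yield no genes or too few
eligible seeds.

## The synthetic generator

`generate_dataset` emulates a single-chromosome experiment: genes placed
on a jittered uniform grid with a minimum TSS spacing (collision-free by
construction); a subset of `n_interactors` genes receives one planted peak
whose summit offset from the TSS is Normal(`peak_offset_mean`,
`peak_offset_sd`) in the strand-aware downstream direction; peak heights
are lognormal; background is per-bin i.i.d. Gamma (shape 2) with mean
`background_rate` in both treatment and control. Peak shape is a
rectangular footprint at 80 % of peak height with a triangular apex rising
to the full height at the summit bin, so the argmax is unique; summits are
snapped to bin midpoints so the caller recovers them exactly. A configured
fraction of planted peaks receives an overlapping H3K4me1 + H3K27ac pair
covering the summit (plus single-mark decoys that never form enhancers),
and a fraction receives an ER-site interval; CTCF sites are placed
uniformly at random, unrelated to the signal. The coexpression matrix is
symmetric with unit diagonal: each pair's score is the mean of
`n_coexpr_datasets` Beta(2, 8) draws, shifted up by `block_correlation`
for interactor–interactor pairs and clipped to [0, 1].

Defaults (chosen once as the study conditions): 2 Mb chromosome, 200
genes, 40 interactors, 50 bp bins, offset Normal(112, 20) bp — the
reported downstream interaction offset — 500 bp peak width, lognormal
heights with median 300 and log-sd 0.5 so the canonical 100–500 threshold
sweep spans the height distribution, background mean 5, enhancer fraction
0.85 (matching the >80 % enhancer overlap seen at high thresholds), ER
fraction 0.7, 20 pseudo-datasets, block correlation 0.35.

What the generator does **not** model: read-level noise and alignment
artefacts, fragment-size effects, copy-number variation and aneuploidy,
locus-dependent background (mappability, GC), correlated noise between
treatment and control, and any coexpression structure beyond a single
planted block. Passing the planted-recovery tests therefore shows the
pipeline is correct and well calibrated under the additive model above; it
does not certify performance on real sequencing data, whose
signal-to-noise ratio is unknown.

## Numerical and design choices

- All randomness flows through numpy Generators; pipeline stages draw from
  named substreams `SeedSequence([seed, crc32(stage)])`, so stages are
  independently reproducible and changing one stage's replicate count
  cannot perturb another stage.
- bedGraph ingestion is strict: spans must be sorted, non-overlapping,
  single-chromosome, within the stated length; violations are
  line-numbered errors rather than silent summation.
- Thresholds are expressed in subtracted-track units; whether they apply
  to depth-normalised or raw units is a user choice via `scale_mode`.
- Tie-breaks are lexicographic/leftmost everywhere (gene order, summit,
  density mode, seed distance) for determinism.
- The acceptance script plants 500 offsets at the default downstream
  offset and recovers the density mode; problem sizes throughout the test
  suite (50–200 genes, 0.4–2 Mb chromosomes, 100 null datasets, 500–2000
  permutations/shuffles) were chosen as the smallest at which the checked
  distributional statements have comfortable Monte-Carlo margins.

## Known limitations

- Peak calling is purely threshold-based by design; no local-background
  (lambda) model, replicate handling, or FDR control.
- Promoter assignment is proximity-only; distal peak-to-gene assignment
  via 3D models is out of scope.
- The coexpression aggregator is a mean of pairwise scores; on the
  synthetic block model any monotone aggregator yields the same ranking,
  but real compendium-search rankings weight datasets adaptively and can
  differ.
- The t-based P value treats the permutation draws as a normal sample;
  for very small n_perm or extremely discrete overlap distributions the
  empirical tail (k+1)/(n+1) would be the more conservative choice.
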