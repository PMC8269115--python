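# Methods

`lipodriver` implements the computational core of an integrated
genomic/transcriptomic analysis of well-differentiated (WD) and
dedifferentiated (DD) liposarcoma: copy-number calling from paired
tumor/normal exome coverage, somatic SNV candidate ranking, scoring of
the replication-dependent histone (RD-HIST) expression signature that
splits DDLPS into HIST+ and HIST− subgroups, and a transcription-factor
(TF) screen that nominates an amplified upstream regulator of the
signature (an HMGA2-like driver). Because matched patient data of this
kind are rarely shareable, the package is built around a synthetic
cohort generator whose planted ground truth makes every stage testable
by parameter recovery.

## Synthetic cohorts (`simdata`)

One `SimConfig` drives four generators (copy number, expression, somatic
reads, phenotypes) orchestrated by `simulate_cohort`. A single master
seed is split into named substreams (`SeedSequence([seed, crc32(name)])`),
so adding a generator never perturbs the others and a fixed seed yields a
bit-identical cohort.

**Genome and annotation.** Four autosomes of 240 bins × 250 kb (60 Mb
each). A chr12-like amplified interval (4 Mb, 16 bins) carries the
driver TF plus 24 passenger genes; the central 6 bins around the TF can
be amplified further. The nested sub-segment is kept at 6 of 16 bins
deliberately: a permutation test inside the locus node cannot
distinguish a real nested event from a chance-contiguous arrangement of
its bins, and that chance is ~1% for a 4-bin event in a 14-bin node
(at the p < 0.01 acceptance threshold) but ~0.1% for 6 in 16 — nested
events much narrower than this sit below the resolution limit of
permutation-based change-point testing at these defaults. The 66 RD-HIST genes tile a copy-neutral
6p22.2-like cluster on chr6, split into the five canonical families
H1:6, H2A:16, H2B:18, H3:15, H4:11 (the family proportions of the human
cluster; only the total is externally constrained, so the split is a
package choice, rescaled by largest remainder for other totals).
Remaining TFs (99 of 100) and filler genes are scattered elsewhere.

**Copy number.** Every tumor amplifies the driver interval; extra copies
are log-normal (log-SD `amp_log_sd` = 0.15) around mean totals of 11.8
(WD) and 15.5 (DD) copies. HIST+DD tumors additionally boost the TF
sub-segment to `2 + (15.5 − 2) × driver_boost_histpos` (default 2.5 →
~36 extra copies). Random passenger amplifications (mean 6 copies, 4–10
bins) occur at Poisson rates growing with subtype severity (1.0 / 2.0 /
3.5 events for WD / HIST−DD / HIST+DD), which is what makes genome-wide
SCNA burden co-vary with the histone signature. Binned read depth is
Poisson(`depth_mean` · copies/2) for tumors and Poisson(`depth_mean`)
for matched normals; `depth_mean` = 150 reads/bin (typical exome
coverage; values below 10 are rejected as ratio estimates become
meaningless).

**Expression.** Per-gene log2 baselines ~ N(5, 1.5). The driver TF
follows `baseline + cn_expr_slope·(copies − 2)` with
`cn_expr_slope` = 0.16 log2/extra copy; each histone gene follows
`baseline + beta_tf_hist·(TF − baseline)` with `beta_tf_hist` = 1.13;
amplified passengers get **no** copy-number term when
`passenger_decouple` is on (emulating epigenetic silencing of
co-amplified passengers, which empirically keeps the gene-level
CN–expression correlation in the amplified interval below ~0.3).
Counts are Poisson around the log-normal mean with a log-normal
library-size factor (log-SD 0.15). The slope and beta defaults were
calibrated — first by closed-form mixture arithmetic over the three
tumor groups, then refined against a 30-seed Monte-Carlo estimate
(the closed form ignores the Jensen inflation that the log-normal
amplitude spread adds to arithmetic group means) — so that the emergent
cohort-level fold changes match the regime the signature analysis
operates in: RD-HIST set DD/WD ≈ 10.6, driver TF DD/WD ≈ 7.3 on
average. Single-cohort fold changes are heavy-tailed (SD ≈ 5 across
seeds) because arithmetic group means are dominated by the most
amplified HIST+ tumors.

**Somatic reads.** True somatic SNV counts per tumor are Poisson with
means 14.1 (WD) and 23.5 (DD). True sites draw a tumor variant-allele
fraction from Beta(12, 28) (mean 0.3); normal alt reads, and both
alleles at the 200 decoy sites per tumor, follow the sequencing error
rate 0.002.

**Phenotypes.** Mitotic index (per 10 HPF) and Ki67 (%) are affine in
the planted per-sample histone drive plus Gaussian noise (defaults:
mitotic = 2 + 1.5·h ± 1.0, Ki67 = 5 + 8·h ± 4, clipped to [0, 100]);
normals sit at baseline. The noise magnitudes are package choices — no
external value exists for them — set so that a 24-tumor cohort shows a
clear but imperfect proliferation correlation (R ≈ 0.9).

**What the generator does not emulate**: read-level data (FASTQ/BAM),
sequence content, GC/mappability bias, purity/stromal admixture,
deletions and copy-neutral LOH, batch effects, and negative-binomial
overdispersion (noise is log-normal-Poisson, which is simpler and
adequate for recovery testing). Recovery results on synthetic cohorts
therefore demonstrate correctness of the algorithms under the stated
model, not robustness to every artifact of real tumor data.

## Copy number (`cnv`)

Per-bin copies are `2 · (t/median t) / (n/median n)` with medians over
autosomal bins (sex chromosomes excluded; no purity/ploidy correction).
Bins with zero normal depth are masked, never zeroed.

Segmentation is a recursive change-point search. Each node is scanned
for the **window** `[i, j)` maximizing the standardized statistic
`|mean_in − mean_out| · sqrt(L(n−L)/n)`; the window is accepted when a
permutation test (default 1000 shuffles of the node's bins, threshold
p < 0.01) on the same statistic is significant and every resulting piece
is empty or ≥ `min_bins` (default 3) bins. Three numerical choices
matter:

* **Two change points per step, not one.** A single binary split dilutes
  a focal event into its flank and loses to permuted arrangements where
  a short prefix captures a couple of amplified bins; the windowed scan
  (the idea behind circular binary segmentation) tests the event as one
  unit and retains power.
* **Log2 scale for scanning.** Amplified bins are extreme on the copy
  scale and dominate the permutation null; scanning log2 copies
  stabilizes variance. Reported segment means remain plain means of the
  member bins on the copy scale, so means conserve the per-chromosome
  bin average exactly.
* **Window-length grid and early rejection.** Candidate window lengths
  are enumerated exhaustively up to 20 bins and geometrically (ratio
  1.2) beyond; the identical grid is applied to the observed profile
  and to every permutation, so the test stays valid, and the recursion
  refines any boundary the coarse tail of the grid misses. The dense
  short-length range matters: a focal event whose exact width is absent
  from the grid gets truncated by a bin or two, and the stray extreme
  bins then contaminate the permutation null of the child nodes,
  masking nested events.
  Permutations run in 250-shuffle chunks and stop as soon as the
  exceedance count already forces p ≥ 0.01 (the accept/reject decision
  is unchanged; only wasted shuffles are skipped). Ties in the scan
  break to the leftmost, shortest window.

Focal amplification calls require extra copies > 2 (the ">two-copy"
convention) and length ≤ 20 Mb; the focality cap is a documented,
configurable default — no external definition of "focal" exists. SCNA
burden counts segments deviating from diploid by ≥ 1 copy over ≥ 3
bins. The interval CN–expression correlation is gene-level Pearson
between mean overlapping-segment copies and mean log2(normalized + 1)
expression; fewer than 3 usable genes or a constant vector raises an
error rather than returning NaN.

## Somatic candidates (`somatic`)

Each site is the 2×2 table rows = (ref, alt) × columns = (tumor,
normal) — the orientation is fixed because the filters, unlike the
p-value, depend on it. `fisher_two_tailed` uses the classical
minimum-likelihood two-tail definition, computed on exact integer
numerators over the shared hypergeometric denominator; table inclusion
involves no floating-point comparison and the result is exact to the
final rounding (any-zero-margin tables return p = 1 by convention).
Candidates pass at p < 0.01 with ≥ 4 tumor alt reads and ≤ 1 normal alt
read — package defaults, since no external filter values exist — and are
ranked by raw p with deterministic (chrom, pos) tie-breaks; BH q-values
are reported alongside but never used for ranking. Mutation burden is
the number of passing calls. Note the normal-alt filter removes a few
percent of true sites at error rate 0.002 and depth 150, so recovered
group burdens sit ~3% below the planted 14.1/23.5 means.

## Expression statistics (`exprstats`)

* **Normalization**: median-of-ratios size factors (genes containing any
  zero are excluded from the reference); factors are rescaled to
  geometric mean 1 — a global scale with no effect on any ratio — which
  makes refitting on a normalized matrix return exactly unit factors.
* **Differential expression**: two-sided Wilcoxon rank-sum on
  log2(normalized + 1), exact null when both groups have ≤ 10 samples
  and the pooled values are tie-free, otherwise the normal approximation
  with mid-rank tie correction and continuity correction; all-tied genes
  get p = 1. log2 fold change uses group means of normalized values with
  a +1 pseudocount, so it is antisymmetric under group swap. This is
  deliberately a rank-based estimator, not a negative-binomial GLM;
  results carry a method tag. Because no single significance cutoff is
  canonical, downstream reports count DE genes at several cutoffs rather
  than asserting one.
* **Multiple testing**: hand-rolled BH step-up and Bonferroni (monotone,
  capped at 1), cross-checked against statsmodels in the test suite.
* **Gene-set statistics**: upper-tail hypergeometric overrepresentation
  with BH across sets; the set-shift test compares per-sample mean log2
  set expression between groups by Wilcoxon with Bonferroni across sets.
* **Embedding/clustering**: genes are log2(x+1)-transformed and z-scored
  (zero-variance genes dropped with a warning); PCA by covariance
  eigendecomposition with components sorted by variance and signs fixed
  so each component's largest-magnitude loading is positive; Ward
  linkage on Euclidean distances, cut at k. Ward/Euclidean is a
  documented default, exposed in the API.

## Histone signature (`histone`)

The RD-HIST score of a sample is the mean log2(normalized + 1) over the
catalog genes; per-family scores use the family subsets, so the overall
score is the size-weighted family mean by construction. DD tumors are
classified by a k = 2 Ward cut on the catalog genes restricted to DD
samples (≥ 4 required); the cluster with the higher mean score is
HIST+DD, which makes labels deterministic. WD samples are never labelled
HIST+ — the signature is treated as DD-internal — but
`wd_score_outliers` reports any WD sample whose score reaches the
HIST+ range (a potential histone-high sub-clone) without changing
labels. The set fold change is the mean over detected genes of
`(mean_B + 1)/(mean_A + 1)`; the detection filter (mean normalized value
≥ 1 in at least one group) and the resulting subset size are reported,
since published histone fold changes are computed on the detected subset
of the cluster rather than all 66 genes. Phenotype correlations are
Pearson with t-based two-sided p, normals excluded, pairwise-complete,
and at least 3 pairs required.

The shipped catalog (`data/rd_hist.gmt`) contains 66 placeholder ids
with family tags matching the simulator's annotation; users supply a GMT
with real gene ids for their own annotation.

## Driver screen (`screen`)

Four filters, applied in order, with funnel counts emitted at each
stage: (1) expressed — mean normalized count over tumor samples ≥ 1
(the published "expressed" rule is unstated; this floor is a documented
default); (2) co-expressed — Pearson R above 0.6 against the mean log2
profile of *each* of the five histone families, computed over DD samples
only by default. Family aggregates are the default because per-family
correlation profiles are what the screen's distributional evidence is
drawn over and single-gene correlations at n ≈ 13 are noise-dominated; a
strict per-gene mode (`per_gene_mode`) is available. (3) DD-specific
amplification — the TF's interval overlaps a passing focal call in ≥ 1
DD sample *and* mean DD extra copies at the locus exceed the WD mean.
The second clause is the central interpretive decision: an HMGA2-like
gene sits in an interval amplified in both subtypes, just more strongly
in DD, so "DD-specific" is implemented as a DD-vs-WD amplitude contrast
rather than DD-exclusivity. (4) Passers are ranked by maximum observed
extra copies, then minimum family R, then gene id. Undefined
(zero-variance) correlations are flagged and excluded, never coerced to
zero.

## Pipeline (`cli`)

`lipodriver run` executes simulate → cnv → somatic → normalize → histone
→ screen → phenotype associations under one YAML config with a single
master seed; unknown config keys are rejected by name. All outputs are
TSV/BED (tab separator, UTF-8, `.` decimal, fixed column order; BED
0-based half-open, site files 1-based, each carrying a `#coords=`
header), so reruns under the same seed and config are byte-identical;
the run manifest records the seed, config hash, and per-stage wall
times (the only non-reproducible field). A failing stage aborts with
the stage name and leaves a `<stage>.partial` marker.

## Verification problem sizes

The recovery experiments in `scripts/acceptance.py` use the package's
default study design (11 WD / 8 HIST−DD / 5 HIST+DD / 3 normal; 1200
genes; 960 bins): 20 cohorts for copy-number recovery, 20 seeds for
subtype recovery, 50 seeds each for the driver screen and its β = 0
null, 50 tumors/group for amplitude recovery, 30 tumors/group for
burden recovery, and a 10,000-gene null for the DE type-I check — sizes
chosen to bound Monte-Carlo error on each reported proportion at a few
percent while keeping a full verification run in minutes.

## Known limitations

* Absolute copies assume a diploid-dominated autosomal background; high
  aneuploidy or low purity would bias the median anchor.
* The permutation segmentation tests each node at p < 0.01 without a
  hierarchical multiplicity correction; per-chromosome false-split rates
  are controlled empirically (≥ 95% of null chromosomes yield one
  segment) rather than analytically.
* The rank-based DE stage is less powerful than count-model estimators
  for small samples and is not a reimplementation of any specific GLM
  tool.
* The screen establishes co-occurrence (co-expression + amplification),
  not causality; knockdown/overexpression follow-up is outside scope.
* Classification with only 4–5 samples in a subgroup is near the
  stability limit of Ward clustering; singleton clusters are flagged.
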