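# Methods

This note documents the models, conventions, parameters and design choices
behind `ggaa_switch`, and what the synthetic study does and does not
establish about real data.

## Repeat scanning and classification

A GGAA block is a maximal tandem run of the exact 4-mer unit: it cannot be
extended by one unit on either side on its strand, and `end − start =
4 × unit_count`. Matching is case-insensitive over IUPAC sequence; ambiguity
codes (including N) never match; degenerate or interrupted repeats (e.g.
GGAA·GGGAA) are not matched — only exact unit runs count. Two runs separated
by even a single base are distinct "disconnected" blocks and are never merged
under any gap distance; a peak's profile therefore reports both the largest
single run (`max_run`) and the number/total of disconnected blocks, since
long elements often carry several multimeric blocks whose combined repeat
content matters.

Scanning defaults to the plus strand (the literal protocol of matching the
GGAA string against the reference); `strands="both"` additionally reports
maximal TTCC runs as minus-strand GGAA blocks with plus-reference
coordinates. Since GGAA is not palindromic the two modes genuinely differ;
both are exposed because the underlying convention is ambiguous in practice.

Repeat classes are assigned from `max_run` alone against inclusive bins —
default 0x / 1–4x / 5–9x / ≥10x, with a second 1x-vs-10x two-class scheme —
and a block partially overlapping the evaluation window contributes its full
unit count (unit counts are biologically atomic; no pro-rating). The
evaluation window is the full peak by default; a ± w bp center window is
available because "within peak centers" conventions vary.

## Interval operations

All coordinates are 0-based half-open. `sort_merge` with distance 0 merges
only genuinely overlapping intervals (abutting half-open intervals stay
separate, as in bedtools); `slop` clips to chromosome bounds; `intersect`
reports all pairs with ≥ `min_overlap` bp (default 1). Fisher's exact test
for co-binding uses the analyzed peak set itself as the universe (not genome
bins): the 2×2 table is built from two boolean hit vectors over the same
regions, the two-sided p sums hypergeometric probabilities of tables at most
as probable as the observed one (relative tie tolerance 1e−7, the R/scipy
convention), and the reported odds ratio is the conditional MLE. A zero
margin yields p = 1 and an undefined (NaN) odds ratio with a warning.

## Differential peak signal

Counts are scaled per sample to a common depth (default 16 M reads):
`count × target/library_size`. Fold changes are always log2 with a
pseudocount (default 1 on the normalized scale) on condition means:
`log2((mean_T + c)/(mean_C + c))`. Two lost/gained threshold presets are
kept, never silently mixed: `figure` (lost < −2, gained > 1.25) for broad
cistrome partitions and `methods` (lost < −1, gained > 0.5) for the
signature rules; published threshold pairs of this shape are sometimes
stated ambiguously between linear and log scales, so both presets are
interpreted on the log2 scale and the choice is a named parameter. "Lost" by
fold change is distinct from "lost" by peak presence/absence
(`venn_partition`); both modes are exposed.

The surrogate DE test (per-gene Welch t on log2(normalized + 1) with BH
correction) exists to produce DE-table *inputs* from synthetic counts under
the no-download contract. It is deliberately simple; it does not shrink
dispersions and is less powerful than count-model DE fits at small n, which
is why the synthetic model systems use 8 replicates per arm (below).

## Loops and enhancer→gene assignment

Loops are bedPE-like records with ordered, non-overlapping, intra-chromosomal
anchors; trans rows are dropped (and counted) at ingestion. A loop is
*consensus* when a loop in the other replicate matches both anchors once each
anchor is widened by tolerance/2 (equivalently, anchor gaps up to the
tolerance match). Matching is greedy 1-to-1 in descending score so the
consensus cardinality is well defined; merged anchors are coordinate
averages of the matched pair, making the construction symmetric in replicate
order. The default tolerance is 10 kb (typical loop-call resolution); the
synthetic pipeline uses 1 kb to match its compact genome. One observed
property worth knowing: if two distinct loops share one anchor and their
other anchors lie within the tolerance of each other, windowed matching can
cross-pair them between replicates and the averaged anchors may represent
neither — callers should keep distinct loops separated by more than the
tolerance or lower the tolerance accordingly.

Promoters are the 1.5 kb strictly upstream of the TSS (the TSS base itself
excluded; a `downstream` flag extends past it). Enhancer→gene maps are
loop-defined only: a gene is assigned when some consensus loop has a
qualifying peak on one anchor and the gene's promoter on the other, in
either orientation; a qualifying loop whose far anchor holds no promoter
contributes nothing (no nearest-gene fallback).

## Signatures

* `10x_promoter`: genes whose promoter overlaps a peak with `max_run ≥ 10`
  and log2FC > 0.5. No FLI1-dependence filter is applied by default (the
  multimeric rules are defined purely cistromically); an optional flag adds
  it.
* `1x_promoter`: promoter peaks with `max_run == 1` and log2FC < −1,
  intersected with genes significantly down-regulated upon FLI1 knockdown
  (logFC < 0, adjusted p < 0.05).
* `10x_enhancer` / `1x_enhancer`: the same peak rules applied through the
  consensus-loop enhancer→gene map; the 1x rule again requires
  FLI1-dependence. "Multimeric" is `max_run ≥ 10` by default, consistent
  with the signature's name; a ≥5 interpretation is available by parameter.
* `prognostic_10x`: the union of the two 10x signatures restricted to genes
  with a positive univariate Cox coefficient for overall survival. No p
  threshold or multiplicity correction is applied by default — the rule
  filters on sign only (a p threshold is available).
* `stag2_inactivation`: genes significant (adjusted p < 0.05) with
  concordant fold-change sign in every supplied STAG2-perturbation DE table
  (≥ 2 model systems).

Full-peak overlap (not summit-only) decides promoter membership. Every
signature carries provenance (rule parameters + input digests) sufficient to
re-derive it; rebuilding on identical inputs yields identical digests.

The Cox screen fits one proportional-hazards coefficient per gene by
Newton–Raphson on the partial likelihood with Efron tie handling, on
per-gene z-scored expression (so coefficients are per SD of expression and
comparable across genes). Constant genes are excluded with a warning;
non-convergence is flagged. The score statistic at β = 0 is also returned:
on two-group data without ties it equals the log-rank chi-square, which the
test suite verifies numerically against lifelines to 1e−6.

## Scoring and stratification

ssGSEA ranks each sample's genes by expression (descending, ties broken by
gene id so scores are invariant to input order) and sums, over all rank
positions, the difference between the weighted in-set ECDF and the uniform
out-of-set ECDF. Weights are the expression *rank values* raised to α (top
gene weight N^α): α = 0.25 by default, following the original ssGSEA
convention, with α = 0 giving a purely rank-based score; scores are
range-normalized across samples by default. The input should be log-scale
expression; `log_transform_counts` (log2 of depth-normalized counts + 1) is
the package's stand-in for a variance-stabilizing transform.

Cohorts are stratified into signature-high/low groups as the top and bottom
`floor(n × 0.25)` samples (deterministic tie-break by sample id, remainder
to mid), a fraction chosen to mirror the ~25% expected prevalence of STAG2
alterations; only high and low enter two-group comparisons.

Preranked GSEA uses the classic weighted Kolmogorov–Smirnov running sum
(weight |statistic|^p, p = 1) with a gene-label permutation null (preranked
input has no sample structure to permute): NES = ES / mean |null ES| of the
matching sign and p = (1 + #{same-sign nulls ≥ |ES|})/(1 + #same-sign).
With `n_perm=0` only the deterministic ES is returned.

## Survival

Kaplan–Meier estimation and log-rank testing delegate to lifelines; median
survival is reported as undefined (None) when the curve never reaches 0.5
rather than as a number. Log-rank uses the standard hypergeometric-variance
statistic with df = groups − 1.

## Synthetic study design

The generator emulates the study's statistical structure, not its biology:

* **Genome**: i.i.d. uniform A/C/G/T background (removing GC-structure
  confounds from scanner tests) with exact planted tandem runs; windows
  around each run are regenerated until no accidental ≥2-unit run lies
  within the clean radius (default 50 bp; the full study uses 250 bp so
  whole peaks are clean) and no background unit can extend a planted run —
  planted blocks are therefore maximal with their exact unit counts. Same
  seed ⇒ byte-identical FASTA.
* **Peaks/counts**: fixed-width (400 bp) peaks centered on planted repeats
  plus random background peaks; negative-binomial counts (var = μ + φμ²,
  shared φ = 0.1, Poisson in the φ→0 limit) with class effects −1.5 / −0.5 /
  +0.5 / +1.0 log2 units (1x / 2–4x / 5–9x / ≥10x) and 2 replicates per
  condition at 16 M reads.
* **Support level**: each planted signature gene carries three qualifying
  peaks (promoter classes) or three loop-connected enhancer peaks — echoing
  the multi-block, multi-loop support of real microsatellite target genes.
  Under φ = 0.1 and n = 2 the per-peak probability of missing a fold-change
  threshold is ≈ 0.16–0.20, so one peak per gene would misclassify ~18% of
  genes, two ~3–4%, and three < 1%; only the last supports reliable
  signature recovery (Jaccard ≥ 0.9) across seeds.
* **Loops**: anchors (1 kb) centered on peak and promoter midpoints; each
  replicate independently drops loops with the configured probability and
  jitters anchors with rounded Gaussian noise, plus per-replicate decoys.
  Loops of one gene are spaced > tolerance apart (see the cross-matching
  caveat above).
* **Expression/survival**: a latent per-sample STAG2-loss factor in [0, 1],
  bimodal with a 25% high subpopulation (matching the prevalence the
  quartile stratification is keyed to). Planted signature genes shift by
  `effect_log2 × factor` in their planted direction (10x up, 1x down upon
  STAG2 loss; default effect 2 log2 units), the STAG2 transcript itself
  shifts down, and all signature genes are FLI1-dependent in the siFLI1
  contrast (dedicated decoy genes are not). Survival is exponential with
  log-hazard `hazard_beta × z(burden)` where burden is the z-scored latent
  factor (z-scoring makes hazard_beta = 1 a well-identified, recoverable
  effect at n = 200); censoring is independent exponential with its rate set
  so the expected censored fraction at baseline hazard equals `censor_rate`
  (default 20%), baseline median survival 36 months. Model-system contrasts
  (two STAG2-knockdown systems and one FLI1 knockdown) use 8 replicates per
  arm so the per-gene Welch surrogate DE reaches the near-complete power
  that pooled-dispersion count models attain at much smaller n.
* **Scale**: the default study plans ~185 genes (105 signature, 80 decoy/
  activity) on a ~3 Mb three-chromosome genome with ~840 peaks, ~250
  replicate loops, a 200-sample cohort and 600 filler genes; the demo runs
  end to end in a few seconds on one CPU. These sizes were chosen as the
  smallest at which class means, signature recovery and survival separation
  are statistically stable.

**What passing tests show — and don't.** Recovery on this generator
validates the pipeline's logic (rules, joins, conventions, calibration of
the tests) under a faithful but idealized error model. Real data add
GC-dependent background, imperfect/polymorphic repeats, peak-calling and
loop-calling artifacts, correlated replicates, batch structure and
non-proportional hazards, none of which are simulated; numerical results on
real cohorts should be expected to degrade accordingly.

## Numerical conventions and degenerate inputs

Ties: ssGSEA and stratification break ties by gene/sample id; survival ties
are handled by the product-limit convention (deaths before censorings) and
Efron's method in the Cox screen. Degenerate cases are errors, not silent
results: empty signature∩matrix, zero-variance correlation inputs, single
survival stratum or zero events, n too small for the requested strata,
unknown chromosomes, malformed loop rows. A 2×2 table with a zero margin
returns p = 1 with a NaN odds ratio and a warning. All stochastic operations
take explicit seeds; pipeline reruns with the same configuration are
bit-identical, and provenance JSON (parameter echo + SHA-256 input digests +
per-stage counts) makes the peaks → qualifying peaks → genes funnel
auditable.

## Known limitations

Only the exact GGAA unit is scanned (no general tandem-repeat discovery or
degenerate motifs); intersection is not strand-aware; the consensus matcher
is greedy rather than optimal-assignment; the surrogate DE is not a
count-model fit; preranked GSEA uses plain permutation p-values (no
adaptive refinement); no multivariable survival models, competing risks or
interval censoring; published signature gene lists cannot be reproduced
verbatim without the original deposited data — the package reproduces the
procedure, not those exact memberships.
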