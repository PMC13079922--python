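# ggaa-switch

Analysis toolkit for the **GGAA microsatellite enhancer-class switch** in
Ewing sarcoma: how loss of the cohesin subunit STAG2 redistributes the
EWS-FLI1 fusion transcription factor away from short (1–4×) GGAA elements
toward long, multimeric (≥5×/≥10×) GGAA microsatellite enhancers, and how the
resulting repeat-length–specific transcriptional programs stratify patient
risk.

It is written for computational biologists who have peak intervals, per-peak
signal counts, chromatin-loop calls, expression matrices and survival tables
in hand (read alignment, peak calling and loop detection are upstream of this
package) and want a tested, reproducible implementation of the downstream
analysis — plus a synthetic-data generator with planted ground truth so that
every stage can be validated end to end without any external download.

## What it computes

- **Repeat scanning** (`ggaa_switch.repeats`): every *maximal* tandem run of
  the GGAA unit in a genome ("n×GGAA" blocks; TTCC runs reported as
  minus-strand blocks on request), per-peak repeat profiles (largest run
  `max_run`, counts of disconnected blocks ≥ k units, total units), and
  repeat-class labels (0x, 1–4x, 5–9x, ≥10x; or the two-class 1x vs 10x
  scheme).
- **Interval algebra** (`ggaa_switch.intervals`): sort/merge, ±flank slop,
  intersection, and Fisher's exact test for co-binding enrichment over a
  declared peak universe (two-sided p by hypergeometric-tail summation).
- **Differential peak signal** (`ggaa_switch.peaks`): depth normalization to
  a common 16 M-read scale, per-peak `log2FC = log2((mean_T + c)/(mean_C + c))`,
  lost/retained/gained partitions under two named threshold presets
  (`figure`: lost < −2 / gained > 1.25; `methods`: lost < −1 / gained > 0.5,
  both on the log2 scale), status × repeat-class contingency tables,
  anchored signal-profile matrices, fold-change correlations, and a
  surrogate DE test (Welch t on log2 normalized counts, Benjamini–Hochberg).
- **Loop integration** (`ggaa_switch.loops`): bedPE ingestion,
  replicate-consensus loops (greedy 1-to-1 anchor matching within a
  tolerance), anchor annotation with peaks and promoters (promoter = 1.5 kb
  strictly upstream of the TSS), and loop-defined enhancer→gene maps for any
  peak predicate (no nearest-gene fallback).
- **Signature derivation** (`ggaa_switch.signatures`): the four
  repeat-length–specific EWS-FLI1 signatures (10x/1x × promoter/enhancer;
  the 1x rules additionally require significant down-regulation upon FLI1
  knockdown), a univariate Cox proportional-hazards screen (Newton–Raphson on
  the Efron partial likelihood, z-scored expression) with prognostic
  refinement by positive coefficient, and a STAG2-inactivation activity
  signature from concordant DE across ≥2 model systems.
- **Enrichment scoring** (`ggaa_switch.scoring`): ssGSEA per-sample scores
  (rank-weighted running sum, exponent α = 0.25), top/bottom-quartile
  stratification (matching the ~25% prevalence of STAG2 alterations),
  preranked GSEA with gene-label permutation NES/p, and score–gene
  correlations.
- **Survival analysis** (`ggaa_switch.survival`): Kaplan–Meier curves and
  medians, log-rank tests, and the stratified high-vs-low survival report
  (the mid stratum is excluded from the two-group test).
- **Synthetic data** (`ggaa_switch.synthetic`): genomes with planted GGAA
  runs, two-condition negative-binomial peak counts with repeat-class effects
  (1x −1.5, 2–4x −0.5, 5–9x +0.5, ≥10x +1.0 log2 units), jittered replicate
  loop calls, signature-structured expression, and hazard-coupled survival —
  all recorded in a `TruthManifest`.

## Worked example

```python
from ggaa_switch import peaks as pk, repeats, synthetic

data = synthetic.simulate_study(seed=3)          # genome + peaks + counts + ...
blocks = repeats.scan_fasta(data.genome_path)    # maximal GGAA runs
profiles = repeats.profile_peaks(data.peaks, blocks)
diff = pk.differential_peaks(data.signal, "control", "stag2_kd",
                             preset="methods", profiles=profiles)
print(pk.stratify_by_class(diff)["log2fc_summary"])
```

prints (seed 3):

```
repeat_class  count      mean    median      std
          0x     30 -0.029111  0.015931 0.427749
        1–4x    476 -0.974816 -1.110430 0.820213
        5–9x     94  0.572619  0.556934 0.443907
        ≥10x    215  1.012779  1.033986 0.487540
```

i.e. upon STAG2 knockdown, peaks over short (1–4×) GGAA elements lose
binding signal (mean log2FC ≈ −1) while peaks over multimeric ≥10× repeats
gain it (≈ +1) — the enhancer-class switch. The `examples/` directory has one
short script per capability (scanning, differential peaks, loop-based
enhancer→gene maps, ssGSEA + survival, and the one-call demo); the same demo
is available from the shell:

```bash
ggaa-switch demo --seed 0
```

which generates a full synthetic study, runs every stage from the files, and
prints planted-vs-recovered Jaccard indices, per-class fold-change recovery,
signature score shifts, and the high-vs-low survival comparison (exit status
is non-zero if any recovery property falls below threshold).

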