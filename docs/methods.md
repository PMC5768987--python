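# Methods

## Scope and data model

`teomics` analyses aligned-data derivatives, not reads: a TE annotation
(RepeatMasker `.out` or BED with `subfamily:family:class[:id]` names), a
minimal GTF of genes and exons, integer count tables for RNA (TE + gene
features) and ATAC peak regions with a sample sheet (condition Ctrl/KO,
state primed/naive), ChIP and ATAC peak BEDs, bedGraph signal tracks,
per-CpG methylation calls (chrom, 0-based pos, strand, methylated count,
unmethylated count), and an ICR panel BED with parent-of-origin labels.
Coordinates are 0-based half-open everywhere inside the package; 1-based
inclusive coordinates appear only at RepeatMasker ingest (strand `C` maps
to `-`).

Conventions that the underlying study leaves open, fixed here and recorded
in output metadata:

* **Promoter**: TSS −2000/+500 bp, strand aware.
* **Bound / overlap calls**: 1 bp minimum overlap, configurable (`min_bp`).
* **Nearest-feature ties**: smaller start, then lexicographic id.
* **Expressed filter**: raw counts (not RPKM), strictly greater than 10 in
  at least one library; configurable.
* **Methylation percent**: coverage-weighted (`100·Σmeth/Σcov`), not
  mean-of-CpG-fractions; CpGs are strand-resolved (no dyad merging).

## The negative-binomial differential test

Counts `k_ij ~ NB(q_i s_j, α)` with feature mean `q_i`, sample size factor
`s_j` (median of ratios to the geometric-mean reference; library-size
ratios as fallback when no feature is observed in all samples), and a
common dispersion `α` per feature class (TE / gene / peak region).

**Dispersion.** A per-feature moment estimate of `α` from 2-vs-2 designs is
so noisy that the plain median across features is biased low, which both
inflates the null type-I error and distorts downstream calls. The common
`α` is therefore quantile-matched: with `z_ij = k_ij/s_j`, overall mean
`q_i`, and the pooled within-group variance `w_i` on `df` degrees of
freedom (within-group, so real condition effects do not inflate it), `α`
solves

```
median_i [ w_i / (q_i · mean(1/s_j) + α q_i²) ] = median(χ²_df)/df ,
```

by bisection, floored at 1e-4. On 2,000 simulated null features with true
α = 0.1 this recovers α̂ ≈ 0.097–0.101 and a raw-p type-I error of
0.042–0.055 at nominal 0.05 across seeds.

**Test.** For groups A and B, condition on the pooled total `K = K_A + K_B`
of raw group sums. Each group sum is modelled as NB matched to its mean
`q·Σs_j` and variance `q·Σs_j + α q² Σs_j²` (Poisson when the variance
collapses to the mean); the two-sided p-value sums the probabilities of all
splits `(a, K−a)` whose probability does not exceed the observed one. The
enumeration is exact; totals at desk scale (hundreds to thousands) keep it
fast.

**Fold change.** `log2((m_KO + 0.5)/(m_Ctrl + 0.5))` on size-factor
normalized condition means. The single always-on 0.5 pseudocount is
zero-safe and continuous; its price is that log2FC is invariant to a global
rescaling of all counts only up to O(0.5/mean) (statuses are unaffected in
practice), and the conditional p-value shifts minutely because the
conditioning total changes — both inherent to zero-safe exact conditional
testing, not defects. Status: `up` iff log2FC ≥ 1 and BH FDR < 0.05;
`down` symmetric; else `unchanged`. BH is implemented as the standard
step-up procedure and cross-checked against
`statsmodels.stats.multitest.multipletests` in the tests.

**ATAC significance** reuses the same machinery on peak-region counts with
the double threshold fold change ≥ 8 **and raw p < 0.05** (no FDR), per the
convention for accessibility changes; both thresholds are strict in the
stated direction (a 7.9-fold region with p = 0.001 is not significant).

## Enrichment and integration statistics

* **Subfamily enrichment** reports two numbers side by side because "fold
  enrichment" is ambiguous: `expr_fold`, the log2 ratio of pseudocounted
  mean KO/Ctrl RPKM over the subfamily's differentially expressed members,
  and `representation_p`, the hypergeometric upper tail of the subfamily's
  DETE count given its share of the expressed-TE universe, BH-corrected
  across subfamilies.
* **Neighbor correlation** pairs each differentially expressed TE with its
  single nearest differentially expressed gene within the window (one pair
  per TE, no double counting) and reports the Pearson r of the signed log2
  fold changes per window (5/10/20 kb) and per TE-class subset. Pearson
  (not Spearman) because r is computed on fold changes; fewer than 3 pairs
  gives NA.
* **ZNF 3′-exon enrichment**: observed statistic is the mean ChIP signal
  over each DE-ZNF's 3′-most exon (strand-aware last exon in transcription
  order); the null re-draws size-matched sets from ZNFs with
  |log2FC| < 0.1; `p = (1 + #{null ≥ obs})/(N + 1)` never returns 0. The
  estimator is calibrated when the DE set is small relative to the control
  pool; at DE-set sizes comparable to the pool the finite-population
  variance mismatch makes it anti-conservative, which the uniformity test
  documents by construction.

## DMRs and the ICR report

DMRs are called on fixed non-overlapping windows (default 1,000 bp) over
the common CpGs of the two pooled conditions: pooled 2×2 (meth, unmeth)
tables, two-sided Fisher exact test, BH across windows, and a DMR call
requiring FDR < 0.05 **and** |Δ| ≥ 20 percentage points; adjacent
same-direction windows merge (coverage-weighted delta, minimum p). Windows
need ≥ 4 covered CpGs. Defaults are package conventions (the study reports
no DMR definition), so absolute DMR counts are not comparable across
parameterizations — direction patterns and planted-region recovery are.

The ICR report computes coverage-weighted percent methylation per panel
entry per sample, maternal/paternal group means, and flags entries whose
KO − Ctrl delta falls below −30 points (configurable) as demethylated.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions, and every planted effect is returned as `GroundTruth`.

* **Genome and annotation.** Two 12 Mb chromosomes. 4,000 TEs — 1,400
  HERVH (with 81 bound, the study's expressed/bound HERVH counts), 500
  HERVK (169 bound), 700 SVA (293 bound), 300 LTR7, 600 L1, 500 Alu —
  1,100 genes (400 of them a ZNF universe), and 29 maternal + 2 paternal
  ICRs, placed without overlap and with a ≥ 400 bp gap so peak geometry
  never bleeds across features. 180,000 CpG sites (~7.5/kb) are fixed at
  annotation time and shared by all samples.
* **RNA counts.** NB with dispersion 0.04 (BCV 0.2, the canonical value
  for isogenic cell-line replicates), two replicates per condition
  matching the study design, per-feature lognormal baselines (floored for
  the focal families so the "expressed" universe is stable). Planted
  log2FC ~ Normal(effect, 0.75) truncated at ≥ 1 on bound elements of the
  mode's affected families: primed HERVH/SVA up (+2), LTR7 +1.5, HERVK
  exactly null; naive HERVK/SVA/LTR7 up, HERVH null. Genes within 20 kb of
  a planted TE receive `lfc_TE · exp(−d/7 kb) + N(0, 0.3)`; ZNF genes are
  kept out of this coupling so the ZNF enrichment module has an
  uncontaminated control pool, and 50 ZNFs get an independent planted
  upregulation plus 2× ChIP signal on their 3′ exon.
* **ChIP geometry.** HERVH/L1: one 5′-anchored peak (±300 bp); HERVK:
  peaks at both ends; SVA/LTR7: body-wide; paternal ICRs bound, maternal
  ICRs never.
* **ATAC.** 2,000 shared background peaks; 50 KO-gained regions at bound
  TEs whose signal bump (width 400 bp) is centred 2,000 bp upstream of the
  TE 5′ anchor, strand aware, with a low shoulder reaching the binding
  site so the gained region overlaps the TRIM28 site while the signal
  maximum sits at −2 kb; 150 background gains, 50 background losses, and
  promoter switches (121 closed, 40 opened) whose methylation moves
  10% ↔ 80%. Planted fold change at gains/losses is 16 (NB dispersion
  0.05). Collisions between planted peaks are dropped greedily and the
  ground truth is synced to what was actually planted.
* **Methylome.** Beta-binomial per CpG (overdispersion ρ = 0.05), Poisson
  coverage mean 15 (zero-coverage sites omitted). Region overrides:
  maternal ICRs 50% in all samples (one methylated and one unmethylated
  allele, balanced sampling); paternal ICRs 80% → 20% in KO; 30 planted
  1 kb hypomethylation windows (80% → 40%) at bound HERVK chosen on the
  DMR window grid where ≥ 6 CpG sites exist; promoter switches as above.
  The background level is then solved so the genome-wide expectation
  equals the state target (primed 80%/80%; naive 42% Ctrl, 50% KO,
  mirroring the reported naive-state hypomethylation and its partial
  retention in the knockout).

Determinism: every stage draws from `default_rng([seed, stage])`, so
outputs are byte-identical across reruns and independent of stage order.

**What the generator does not emulate** — and hence what passing recovery
tests do not show about real data: multi-mapping read ambiguity (counts are
taken as provided, one count per element), TE nesting/fragmentation,
sequence-driven binding specificity, correlated local methylation beyond
the region model, chromatin contact structure beyond linear distance, and
replicate-level batch effects. Headline genome-wide counts from the study
(e.g. 10,949 primed DETEs; 2,224 gained peaks; 528,773 common CpGs) are
properties of the unreleased sequencing data and are treated as structural
expectations, not numeric targets, at this desk scale.

## Problem sizes and runtime choices

The default generator scale (24 Mb, 4,000 TEs, 1,100 genes, 180k CpGs) is
large enough for stable statistics and small enough that a full pipeline
run takes well under a minute. The end-to-end reproducibility tests use a
reduced configuration (2×3 Mb, same structure) because byte-identity is
scale-free; statistical recovery tests (type-I calibration, DETE recovery,
DMR sensitivity/precision, ICR means, metaprofile offset) run at the
default scale with fixed seeds.

## Known limitations

* The exact conditional NB test enumerates the split distribution; for
  totals far beyond desk scale (~10⁵ reads per feature) a normal
  approximation would be preferable.
* Fisher-exact DMR windows ignore the beta-binomial overdispersion within
  windows; the 20-point minimum delta and BH correction absorb the
  resulting mild anti-conservatism at default coverage, which the planted
  precision test (≥ 0.9) verifies empirically.
* `percent_bound_gained` is reported per binding site, not per merged
  region; sites counted bound-gained require only a 1 bp overlap with a
  significantly gained region.
* The permutation ZNF test requires a control pool at least as large as
  the DE set and errors otherwise rather than silently resampling.
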