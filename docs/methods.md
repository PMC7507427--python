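# Methods

`lncstate` reimplements, as one tested pipeline over synthetic data, an
integrative analysis of how lncRNA transcription is controlled during
myoblast differentiation: differential expression, chromatin-state
classification of lncRNA TSS neighbourhoods from ATAC/histone/TF peak and
signal data, TF–lncRNA co-expression network inference, pre-ranked
gene-set enrichment across satellite-cell ages, and known-motif
enrichment. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data can and cannot show.

## Differential expression (`diffexpr`)

Counts for feature *f* in condition *c* are modelled as negative binomial
with mean μ and dispersion φ (variance μ + φμ²; φ = 0 recovers Poisson).
The test statistic is a Wald contrast of log2 CPM means:

- log2FC = log2((CPM̄_B + c)/(CPM̄_A + c)) with pseudocount c = 1 CPM, which
  bounds fold-changes for zero counts;
- the standard error comes from the delta method applied to the NB
  variance of the count mean, Var(log2 CPM̄) ≈ (1/μ + φ)/(n ln²2), damped
  by CPM̄/(CPM̄ + c) to reflect the pseudocount;
- φ is estimated per feature by method of moments, max(0, (s²−x̄)/x̄²),
  pooled across the two conditions with df weights;
- the statistic is referred to a t distribution with (n_A−1)+(n_B−1)
  degrees of freedom. With 3 replicates per condition this calibrates the
  type-I error at the nominal 0.05 in NB null simulations, where a normal
  reference is anticonservative (~0.08–0.14 observed in development).

A feature is called DE when **both** |log2FC| ≥ 1 **and** p < .05 (raw p;
a Benjamini–Hochberg flag exists but is off by default, matching the
study design the pipeline mirrors), then features with mean CPM < 1 in
both contrasted conditions are removed. Up/down is the sign of log2FC.

This is a deliberately transparent stand-in for an edgeR-style analysis:
TMM normalisation and exact/quasi-likelihood tests are not implemented.
One visible consequence: when ~30% of the transcriptome moves
asymmetrically (2² up vs 2⁻² down), plain CPM shifts every fold-change by
about −0.4 log2 — the classic composition bias TMM exists to remove. The
thresholds absorb it (sensitivity ≈ 0.9, FDR ≈ 0.12 on the default
synthetic study), and the planted-truth checks assert fold-change
recovery on count means, the generative scale.

## Chromatin-state classification (`chromstate`)

All interval arithmetic is 0-based half-open, and merge/extend follow
`bedtools merge -d 0` semantics (bookended intervals join). These
primitives are verified exactly against a per-base bitmap oracle.

- **TSS window**: strand-aware, 2500 bp upstream to 1500 bp downstream of
  the TSS ('upstream' means 5′ of the direction of transcription; for a
  minus-strand TSS t the window is [t−1499, t+2501)), clamped to the
  chromosome.
- **Open chromatin**: ≥ 1 bp overlap between the window and the union of
  both conditions' merged ATAC peaks. Using the union mirrors defining
  open-chromatin regions from peaks merged across conditions.
- **Categories**: ATAC peaks are extended ±1 kb and re-merged; the
  extended regions a window touches are tested for H3K4me3, then H3K4me1
  peaks, giving ATAC_H3K4me3 > ATAC_H3K4me1 > ATAC_only (closed when the
  window overlaps no raw ATAC peak, so category ≠ closed iff open).
  H3K4me3 precedence is a choice: the promoter mark is the stronger claim
  about a TSS, and the categories must be exclusive.
- **Signal**: mean per-base coverage of the bedGraph track over the
  extended regions (deeptools-style mean, not sum — region widths vary
  after merging), quantile-normalised across the two conditions
  (Bolstad's algorithm; ties receive the mean of their tied reference
  values), then log2((B+1)/(A+1)). Per-transcript values are
  width-weighted means over the touched regions.
- **Group contrast**: up vs down vs an equal-sized control sampled
  uniformly (seeded) from non-DE lncRNAs, compared by two-sided
  Mann–Whitney U (exact for small tie-free samples, normal approximation
  with tie correction otherwise). The test is unnamed in the design this
  mirrors; Mann–Whitney was chosen because the per-group fold-change
  distributions are small and heavy-tailed.

## Co-expression network (`coexpr`)

Input expression is log2(CPM+1) of the DE features over the C2C12 arm
(GM + five differentiation time points — a time course is what makes
co-expression estimable; the satellite arm is held out for enrichment
testing). Two views are built:

- **Weighted network**: unsigned adjacency a_ij = |r_ij|^β. The default
  β = 6 is the standard unsigned choice; the scale-free criterion
  (smallest β with R² ≥ 0.8 of the log p(k) ~ log k fit, else argmax R²)
  is implemented and available via `--power auto`, but block-structured
  module data is not scale-free, and on such data the criterion runs to
  extreme powers that crush the adjacency — so it is not the default.
  Edge weight is the topological overlap
  TOM_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij), verified exactly
  against an O(n³) triple loop. Modules come from average-linkage
  clustering of 1 − TOM with a **static** height cut (deterministic and
  desk-scale, unlike dynamic tree cut): default cut height 0.9, minimum
  module size 20, labels WGCNA-colour-style by descending size, "grey"
  unassigned. TOM dissimilarities concentrate near 1, so a static cut
  must sit high; the familiar 0.25 is an eigengene merge height and
  would leave every feature unassigned here.
- **Pearson edges**: r with the closed-form two-sided p from
  t = r√((n−2)/(1−r²)), df = n−2; significant at p < .05.

The TF–lncRNA network keeps TF×lncRNA edges with TOM weight > 0.05 and
p < .01 (the interpretation of "weight" as the exported TOM edge weight
is a documented choice; |r|^β is available as a flag in the library).
The two views are compared as |weighted ∩ Pearson|/|weighted| plus Venn
counts.

## Pre-ranked GSEA (`gsea`)

Features (lncRNAs by default) are ranked by log2((CPM̄_B+1)/(CPM̄_A+1)),
descending, ties broken lexicographically. The enrichment score is the
signed extremum of the weighted Kolmogorov–Smirnov running sum: hits add
|metric|^p / Σ_hits |metric|^p, misses subtract 1/(N−N_hits); p = 1 by
default, p = 0 reduces to the classical KS statistic. Significance uses a
gene-set permutation null (random same-size sets), the appropriate null
for pre-ranked input where no per-sample phenotype labels exist:
p = (1 + #{|ES_null| ≥ |ES|, same sign})/(1 + #same-sign), and
NES = ES / mean |same-sign null ES|. The implementation is checked
against a brute-force recomputation of the running sum and for null
p-value uniformity (KS calibration over 500 seeded runs).

## Motif enrichment (`motifenr`)

Known-motif enrichment stands in for de novo discovery. Each PWM (columns
sum to 1 after a 0.01 pseudocount) is scanned over both strands with the
log-odds score Σ_j log2(pwm[j, w_j]/bg[w_j]) in bits against a uniform
background; windows containing N are skipped; a region is positive when
any window reaches 60% of the PWM's maximum achievable score. The
threshold is sharp enough that a single mismatch of a 6-mer consensus
fails it with the bundled matrices. Foreground (open-chromatin regions of
DE lncRNAs) vs background (same for non-DE lncRNAs, mirroring the control
design) is tested per motif by one-sided Fisher exact on the 2×2
region-hit table, with Haldane (+0.5) odds ratios when a cell is zero.
The bundled library (MyoD, MyoG, CTCF, Runx, AP-1, ATF3) contains
simplified consensus-derived matrices written for this package — adequate
for planted-consensus detection, not a substitute for curated motif
databases.

## Synthetic study (`synthio`)

The generator emulates the statistical structure the pipeline assumes,
with every planted fact recorded in a truth table that is cross-validated
against the emitted files on every run.

**Design.** Two chromosomes × 5 Mb; 300 lncRNAs + 1500 protein-coding
genes (12 of them named TFs) on a ≥ 5 kb grid so windows, extended
regions and motif regions of neighbours never collide. Conditions: C2C12
arm GM, DM12–DM96 (the differentiation time course; a 2-condition design
cannot support network inference) and satellite ages W2–W12, 3 replicates
each, 36 samples.

**Counts.** NB(μ, φ = 0.1) with log2 μ = base + planted effects:

- base ~ U(5, 9) log2 counts;
- DE: 30% of features at log2FC exactly ±2 between GM and DM60, carried
  by a fixed mean trajectory anchored at 0 (GM) and 1 (DM60) with
  intermediate time points at 0.5;
- modules: five 50-feature modules (2 TFs + 15 lncRNAs + 33 genes each;
  directions +,+,−,−,0; MyoD/MyoG and Mef2c/Heyl hub the two up
  modules). Module profiles live in the condition subspace orthogonal to
  the DE anchor and form a regular simplex (pairwise correlation exactly
  −1/4, orientation seeded) — this guarantees, rather than hopes, that no
  two planted modules collide into one unsigned-network cluster. Profile
  variances are solved per module so the expected within-module Pearson r
  of log2 expression hits the 0.8 target given each member's NB noise;
- satellite arm: DE lncRNAs follow a rise-then-fall age profile
  (log2 offsets 0, +1.5, +2, +0.5, −1, −2 across W2→W12, mirrored for the
  down set, per-feature jitter σ = 0.3), so the up set is enriched in the
  rapid-growth contrast and depleted by W12; the four core TFs follow the
  same shape.

**Chromatin.** Every open-category lncRNA receives an ATAC peak
(width 300–600 bp) over its TSS in both conditions; DM signal is
GM × 2^(±2) for up/down lncRNAs (lognormal peak heights, base 2⁶,
spread 1.5 log2, noise 0.2 log2); marked categories get an
H3K4me1/H3K4me3 peak within 1 kb of the ATAC peak; closed lncRNAs get
nothing. TF peaks land on marked lncRNAs' ATAC peaks — MyoD/MyoG jointly
(both 0.70, each alone 0.08), other TFs at 0.30. Category proportions
(0.28/0.25/0.11/0.36) were chosen so roughly 64% of lncRNAs are open and
~83% of open ones carry a mark, the regime the pipeline is meant to
classify.

**Motif regions.** 400 bp regions on each open lncRNA's ATAC peak; DE
regions are foreground, non-DE background; MyoD consensus spliced into
foreground at rate 0.6 (MyoG at 0.7× that) and into background at 0.05.

**Determinism.** One global seed; each stage draws from
`default_rng([seed, stage_index])`; identical config + seed give
byte-identical files.

**What passing tests do and do not show.** The generator plants exactly
the structure each stage is built to detect, under clean geometry
(non-overlapping genes, single-isoform transcripts, peaks that respect
category boundaries, uniform-background sequence). Passing therefore
demonstrates that the implementations are correct and the planted
parameters recoverable — not that the pipeline's thresholds are optimal
for real data, where isoform overlap, unbalanced libraries, correlated
replicates, GC/mappability structure in coverage, and motif background
composition all blur these signals.

## Pipeline defaults (all exposed in the YAML config / CLI flags)

| parameter | default | role |
|---|---|---|
| alpha / lfc / cpm_min | 0.05 / 1.0 / 1.0 | DE call and expression filter |
| upstream / downstream | 2500 / 1500 bp | TSS window |
| flank | 1000 bp | ATAC extension before mark/TF co-localisation |
| weight_min / p_max | 0.05 / 0.01 | TF–lncRNA edge thresholds |
| pearson_alpha | 0.05 | Pearson cross-check edges |
| power / cut_height / min_module_size | 6 / 0.9 / 20 | weighted network |
| nperm | 1000 | GSEA permutations |
| seed | 1 | every random draw (simulation, controls, permutations) |

Problem sizes used throughout (1800 features, 36 samples, ~540 DE
features in the network, 1000 permutations) keep a full `lncstate all`
run to a few seconds on one CPU while leaving each statistical test
comfortably powered.

## Known limitations

- CPM-only normalisation (composition bias discussed above); no TMM.
- Static tree cut and a fixed default power instead of WGCNA's dynamic
  cut and per-dataset soft threshold; module eigengenes/kME are not
  computed.
- Gene-set (not phenotype) permutation in GSEA; no FDR q-values across
  sets (two sets per contrast here).
- The motif stage does no de novo discovery and ships a minimal
  consensus-derived library.
- bedGraph is the only signal format (no bigWig), and peak calling is out
  of scope — peaks and signal are inputs.
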