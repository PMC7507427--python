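# lncstate

Integrative analysis of lncRNA transcriptional regulation during myoblast
differentiation, packaged as a reproducible pipeline over synthetic data
with known ground truth.

During C2C12 myoblast differentiation (growth medium → differentiation
medium time course) and satellite-cell maturation (2–12-week-old donors),
long non-coding RNAs are switched on and off by changes in the chromatin
around their transcription start sites: accessibility (ATAC), the
enhancer mark H3K4me1 or promoter mark H3K4me3, and binding of myogenic
transcription factors such as MyoD and MyoG. This package implements the
full chain of analyses that connects those layers:

1. **Differential expression** — NB Wald test on log2 CPM means; DE when
   |log2FC| ≥ 1 and p < .05, low-expression features (CPM < 1 in both
   conditions) removed.
2. **Chromatin-state classification** — strand-aware TSS windows (2.5 kb
   up / 1.5 kb down) vs merged ATAC peaks; peaks extended ±1 kb and
   re-merged for H3K4me1/H3K4me3 and TF co-localisation; four exclusive
   categories (ATAC+H3K4me3, ATAC+H3K4me1, ATAC-only, closed); ATAC
   signal log2FC after quantile normalisation, compared across up/down/
   control groups by Mann–Whitney U.
3. **TF–lncRNA co-expression network** — unsigned weighted network
   (a_ij = |r_ij|^β, topological-overlap edge weights, modules from a
   static cut of the TOM dendrogram) cross-checked against Pearson edges
   with the closed-form t-distribution p; TF–lncRNA edges kept at
   weight > 0.05, p < .01.
4. **Pre-ranked GSEA** — weighted Kolmogorov–Smirnov enrichment score of
   the up-/down-regulated lncRNA sets along satellite-age contrasts, with
   a gene-set permutation null.
5. **Known-motif enrichment** — log-odds PWM scanning (both strands) and
   one-sided Fisher tests of foreground vs background open-chromatin
   regions.

A synthetic-data generator (`lncstate.synthio`) produces every input the
pipeline consumes — GTF, genome FASTA, counts, peak BEDs, signal
bedGraphs, gene sets — with planted DE status, chromatin categories,
co-expression modules, TF binding and motif instances, all recorded in a
truth table. Every stage is tested against that truth and against
independent oracles (per-base bitmap interval algebra, brute-force TOM
and enrichment scores, closed-form p-values).

See [docs/methods.md](docs/methods.md) for models, parameter defaults and
limitations.

## Worked example

Run the whole study end to end (simulation → all five stages) in one
command:

```sh
lncstate all --seed 1 --outdir results
```

or stage by stage with the numbered drivers:

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_differential_expression.py
python analysis/03_chromatin_states.py
python analysis/04_coexpression_network.py
python analysis/05_satellite_gsea.py
python analysis/06_motif_enrichment.py
```

With seed 1 the drivers print:

```
lncRNA: 110 DE of 300 tested (46 up, 64 down)
protein_coding: 434 DE of 1500 tested (173 up, 261 down)

66/110 DE lncRNAs (60.0%) are open-chromatin-associated; 86.4% of those carry H3K4me1 or H3K4me3
median ATAC log2FC: up +1.76, control -0.03, down -1.67
Mann-Whitney p: up vs control 1.96e-13, down vs control 1.50e-11

soft-threshold power 6; 544 DE features clustered
196 TF-lncRNA edges (weight > 0.05, p < .01); 92.5% of weighted-network pairs confirmed by Pearson (p < .05)

up-set enrichment trajectory: W4_vs_W2: ES +0.95 -> W6_vs_W2: ES +1.00 -> W8_vs_W2: ES +0.66 -> W10_vs_W2: ES -0.89 -> W12_vs_W2: ES -0.98

2 motif(s) enriched at p < .01: MyoD, MyoG
```

Reading these numbers: the generator planted 90 DE lncRNAs and 450 DE
genes at |log2FC| = 2 — the DE stage recovers them at ~90% sensitivity
(the excess calls are false discoveries, ~12% of calls). Of the DE
lncRNAs, 60% sit in open chromatin, and ~86% of those carry an H3K4me1 or
H3K4me3 peak, matching the planted category proportions. Up-regulated
lncRNAs gained ATAC signal (median +1.76 log2, planted gain +2 with
quantile-normalisation shrinkage) while down-regulated ones lost it, both
groups differing from non-DE controls at p ≪ .05. The co-expression stage
recovers the five planted modules and links TF hubs to their module
lncRNAs; 92.5% of weighted-network pairs are confirmed by plain Pearson
correlation. Along satellite ages, the C2C12-up lncRNA set is enriched
during rapid growth (W4–W6) and reverses sign by W10–W12 — the planted
rise-then-fall profile. Finally, only the two motifs actually spliced
into foreground regions (MyoD, MyoG E-boxes) come out enriched.

Every stage is also exposed as a subcommand (`lncstate de`,
`lncstate chromstate`, `lncstate network`, `lncstate gsea`,
`lncstate motif`, `lncstate simulate`); `--help` lists each threshold.

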