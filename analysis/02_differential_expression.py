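#!/usr/bin/env python
"""Call DE lncRNAs and genes between proliferation (GM) and DM60.

NB Wald test on log2 CPM means; a feature is DE when |log2FC| >= 1 and
p < .05, then low-expression features (CPM < 1 in both conditions) are
dropped. Writes results/de.tsv and prints the DE tally by biotype.
"""

import argparse
from pathlib import Path

from lncstate import diffexpr
from lncstate.genomic_io import read_counts

parser = argparse.ArgumentParser()
parser.add_argument("--counts", type=Path, default=Path("data/counts.tsv"))
parser.add_argument("--cond-a", default="GM")
parser.add_argument("--cond-b", default="DM60")
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

matrix = read_counts(args.counts)
results = diffexpr.de_test(matrix, args.cond_a, args.cond_b, alpha=0.05, lfc_threshold=1.0)
cpm = diffexpr.compute_cpm(matrix.counts)
results = diffexpr.filter_low_expression(
    results, cpm, matrix, args.cond_a, args.cond_b, cpm_min=1.0
)
frame = diffexpr.results_to_frame(results)
frame.to_csv(args.outdir / "de.tsv", sep="\t")

de = frame[frame["status"] != "not_de"]
for biotype in ("lncRNA", "protein_coding"):
    sub = de[de["biotype"] == biotype]
    total = (frame["biotype"] == biotype).sum()
    print(
        f"{biotype}: {len(sub)} DE of {total} tested "
        f"({(sub['status'] == 'up').sum()} up, {(sub['status'] == 'down').sum()} down)"
    )
print(f"wrote {args.outdir / 'de.tsv'}")
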