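#!/usr/bin/env python
"""Known-motif enrichment in open-chromatin regions of DE lncRNAs.

Scans the bundled PWM library (MyoD, MyoG, CTCF, Runx, AP-1, ATF3) over
foreground (DE lncRNA) vs background (non-DE lncRNA) open-chromatin
regions and reports one-sided Fisher enrichment per motif.
"""

import argparse
from pathlib import Path

from lncstate import motifenr
from lncstate.genomic_io import read_bed, read_fasta

parser = argparse.ArgumentParser()
parser.add_argument("--datadir", type=Path, default=Path("data"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()
args.outdir.mkdir(parents=True, exist_ok=True)

genome = read_fasta(args.datadir / "genome.fa")
table = motifenr.enrich(
    read_bed(args.datadir / "fg.bed").intervals,
    read_bed(args.datadir / "bg.bed").intervals,
    genome,
    motifenr.default_pwms(),
)
table.to_csv(args.outdir / "motif_enrichment.tsv", sep="\t")
print(table.to_string())
enriched = table[table["p"] < 0.01]
print(
    f"\n{len(enriched)} motif(s) enriched at p < .01:",
    ", ".join(enriched.index) or "none",
)
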