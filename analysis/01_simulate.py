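#!/usr/bin/env python
"""Generate the synthetic myoblast-differentiation study under data/.

Emits annotation (GTF), genome (FASTA), counts for the C2C12 arm
(GM, DM12..DM96) and the satellite arm (W2..W12), ATAC/histone/TF peaks
with condition-dependent signal, motif regions, gene sets and the full
ground-truth table. Deterministic for a fixed seed.
"""

import argparse
from pathlib import Path

from lncstate import synthio

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("data"))
args = parser.parse_args()

config = synthio.SimulationConfig(seed=args.seed)
paths, truth = synthio.generate_study(config, args.outdir)

features = truth.features
print(f"wrote {len(paths)} files to {args.outdir}")
print(
    f"features: {config.n_lnc} lncRNAs + {config.n_pcg} protein-coding "
    f"({len(synthio.TF_NAMES)} TFs), {config.replicates} reps x "
    f"{len(config.conditions)} conditions"
)
print(
    "planted DE:",
    (features["de_status"] == "up").sum(), "up /",
    (features["de_status"] == "down").sum(), "down at |log2FC| =",
    config.de_log2fc,
)
print("planted lncRNA categories:")
print(features.loc[features["biotype"] == "lncRNA", "category"].value_counts().to_string())
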