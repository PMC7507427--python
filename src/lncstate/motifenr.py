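"""Known-motif enrichment in open-chromatin regions (PWM scan + Fisher test).

Each position weight matrix is scanned along both strands of every region
sequence with a log-odds score in bits against a background base
composition; a region counts as positive when any window reaches the score
threshold (default 60% of the PWM's maximum achievable score). Enrichment
of foreground over background regions is a one-sided Fisher exact test on
the 2x2 region-hit table, with a Haldane-corrected odds ratio.

De novo motif discovery is out of scope: the bundled library covers the
myogenic and accessory factors of interest (MyoD, MyoG, CTCF, Runx, AP-1,
ATF3) as simplified consensus-derived matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import GenomicInterval, ParseError, ValidationError

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_BACKGROUND = np.array([0.25, 0.25, 0.25, 0.25])
PWM_PSEUDOCOUNT = 0.01


@dataclass
class PWM:
    """Per-position base probabilities (columns sum to 1) plus background."""

    name: str
    matrix: np.ndarray  # shape (width, 4), order A C G T
    background: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.background is None:
            self.background = DEFAULT_BACKGROUND.copy()
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError(f"PWM {self.name}: columns must sum to 1")
        if (self.matrix <= 0).any():
            raise ValidationError(f"PWM {self.name}: zero probability after pseudocount")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    offset: int
    strand: str
    score: float


def read_jaspar(path: str | Path) -> list[PWM]:
    """Read a JASPAR-format PFM/PPM text file.

    Expected layout per motif: a ``>name`` header followed by four lines
    ``A [ ... ]`` .. ``T [ ... ]`` of counts or probabilities; counts are
    converted to probabilities with a pseudocount.
    """
    pwms = []
    name = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    for line in lines + [">__end__"]:
        if line.startswith(">"):
            if name is not None:
                if set(rows) != set(BASES):
                    raise ParseError(f"motif {name}: need one row per base ACGT")
                counts = np.array([rows[b] for b in BASES]).T  # (width, 4)
                counts = counts + PWM_PSEUDOCOUNT
                pwms.append(PWM(name=name, matrix=counts / counts.sum(axis=1, keepdims=True)))
            name = line[1:].split()[0]
            rows = {}
        else:
            base, rest = line[0].upper(), line[1:]
            values = rest.replace("[", " ").replace("]", " ").split()
            rows[base] = [float(v) for v in values]
    return pwms


def default_pwms() -> list[PWM]:
    """The bundled myogenic/accessory motif library."""
    ref = resources.files("lncstate").joinpath("data/motifs.jaspar")
    with resources.as_file(ref) as path:
        return read_jaspar(path)


def _encode(sequence: str) -> np.ndarray:
    """Sequence -> integer codes; N and anything unexpected -> 4."""
    arr = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    codes = np.full(len(arr), 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def scan_pwm(
    sequence: str,
    pwm: PWM,
    threshold_bits: float,
    region_id: str = "",
) -> list[MotifHit]:
    """All windows on either strand scoring >= threshold (bits).

    Windows containing N (or any non-ACGT character) are skipped. Offsets
    are 0-based positions of the window start on the forward sequence,
    for both strands.
    """
    w = pwm.width
    if w > len(sequence):
        return []
    hits = []
    lo = pwm.log_odds
    lo_rc = lo[::-1, ::-1]  # scan forward sequence with reverse-complement matrix
    codes = _encode(sequence)
    n_windows = len(codes) - w + 1
    idx = np.arange(n_windows)[:, None] + np.arange(w)[None, :]
    windows = codes[idx]
    valid = ~(windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows)
    pos = np.arange(w)
    fwd_scores = lo[pos, safe].sum(axis=1)
    rev_scores = lo_rc[pos, safe].sum(axis=1)
    for strand, scores in (("+", fwd_scores), ("-", rev_scores)):
        passing = np.nonzero(valid & (scores >= threshold_bits))[0]
        for off in passing:
            hits.append(
                MotifHit(region_id=region_id, offset=int(off), strand=strand,
                         score=float(scores[off]))
            )
    return sorted(hits, key=lambda h: (h.offset, h.strand))


def region_sequences(
    regions: list[GenomicInterval], genome: dict[str, str]
) -> list[str]:
    seqs = []
    for iv in regions:
        if iv.chrom not in genome:
            raise ValidationError(f"region chromosome {iv.chrom!r} absent from FASTA")
        if iv.end > len(genome[iv.chrom]):
            raise ValidationError(
                f"region {iv.chrom}:{iv.start}-{iv.end} outside sequence bounds"
            )
        seqs.append(genome[iv.chrom][iv.start : iv.end])
    return seqs


def enrich(
    fg_regions: list[GenomicInterval],
    bg_regions: list[GenomicInterval],
    genome: dict[str, str],
    pwms: list[PWM],
    threshold_fraction: float = 0.6,
) -> pd.DataFrame:
    """Per-motif Fisher enrichment of foreground vs background regions.

    The scan threshold is ``threshold_fraction`` of each PWM's maximum
    achievable score. Returns a frame indexed by motif name with hit
    counts, totals, Haldane-corrected odds ratio and one-sided p.
    """
    fg_seqs = region_sequences(fg_regions, genome)
    bg_seqs = region_sequences(bg_regions, genome)
    rows = []
    for pwm in pwms:
        thr = threshold_fraction * pwm.max_score
        fg_hit = sum(1 for s in fg_seqs if scan_pwm(s, pwm, thr))
        bg_hit = sum(1 for s in bg_seqs if scan_pwm(s, pwm, thr))
        a, b = fg_hit, len(fg_seqs) - fg_hit
        c, d = bg_hit, len(bg_seqs) - bg_hit
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        if 0 in (a, b, c, d):
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append(
            {
                "motif": pwm.name,
                "fg_hit": a,
                "fg_total": len(fg_seqs),
                "bg_hit": c,
                "bg_total": len(bg_seqs),
                "odds_ratio": orr,
                "p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("motif")
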