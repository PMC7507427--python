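"""Readers and writers for the on-disk formats the pipeline touches.

All coordinates are held internally as 0-based half-open intervals
(BED-native). GTF is 1-based inclusive on disk and is converted at this
boundary; no other module performs +1/-1 arithmetic.

Chromosome names are passed through verbatim — no "chr" normalisation.
A naming mismatch between two files is detected downstream (zero shared
chromosomes) and reported, never silently fixed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}
VALID_BIOTYPES = {"lncRNA", "protein_coding"}


class ParseError(ValueError):
    """A file violated its format contract (bad line, bad coordinates)."""


class ValidationError(ValueError):
    """Parsed content violated a semantic invariant (negative count, overlap)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive, so width is
    simply ``end - start`` and two intervals overlap iff
    ``a.start < b.end and b.start < a.end``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Transcript:
    """A transcript record; TSS is the strand-aware 5'-most transcribed base."""

    id: str
    gene_id: str
    biotype: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.biotype not in VALID_BIOTYPES:
            raise ValidationError(f"unknown biotype {self.biotype!r}")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


@dataclass
class PeakSet:
    """A named collection of intervals (one track, e.g. ATAC_GM or MyoD_DM).

    Intervals are kept sorted by (chrom, start). Strand is '.' for peaks.
    """

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}


@dataclass
class SignalTrack:
    """Per-base coverage as non-overlapping value steps (bedGraph semantics).

    Steps are stored per chromosome as parallel sorted arrays for fast
    region quantification. Bases covered by no step have value 0.
    """

    name: str
    steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )  # chrom -> (starts, ends, values)

    @classmethod
    def from_records(
        cls, name: str, records: Iterable[tuple[GenomicInterval, float]]
    ) -> "SignalTrack":
        per: dict[str, list[tuple[int, int, float]]] = {}
        for iv, value in records:
            if value < 0:
                raise ValidationError(
                    f"negative signal {value} at {iv.chrom}:{iv.start}-{iv.end}"
                )
            per.setdefault(iv.chrom, []).append((iv.start, iv.end, float(value)))
        steps = {}
        for chrom, recs in per.items():
            recs.sort()
            starts = np.array([r[0] for r in recs], dtype=np.int64)
            ends = np.array([r[1] for r in recs], dtype=np.int64)
            values = np.array([r[2] for r in recs], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.nonzero(starts[1:] < ends[:-1])[0][0])
                raise ValidationError(
                    f"overlapping steps on {chrom} near position {starts[i + 1]}"
                )
            steps[chrom] = (starts, ends, values)
        return cls(name=name, steps=steps)

    def records(self) -> list[tuple[GenomicInterval, float]]:
        out = []
        for chrom in sorted(self.steps):
            starts, ends, values = self.steps[chrom]
            for s, e, v in zip(starts, ends, values):
                out.append((GenomicInterval(chrom, int(s), int(e)), float(v)))
        return out


@dataclass
class CountMatrix:
    """Integer expression counts (features x samples) with metadata.

    ``counts`` is a DataFrame indexed by feature id with sample-id columns.
    ``biotypes`` maps feature id -> {lncRNA, protein_coding};
    ``conditions`` maps sample id -> condition label (e.g. GM, DM, W2..W12).
    Every condition has at least one replicate by construction.
    """

    counts: pd.DataFrame
    biotypes: pd.Series
    conditions: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative count in matrix")
        missing = set(self.counts.columns) - set(self.conditions.index)
        if missing:
            raise ValidationError(f"samples without condition label: {sorted(missing)}")
        missing_bt = set(self.counts.index) - set(self.biotypes.index)
        if missing_bt:
            raise ValidationError(
                f"features without biotype: {sorted(missing_bt)[:5]} ..."
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        hits = [s for s in self.counts.columns if self.conditions[s] == condition]
        if not hits:
            raise ValidationError(f"condition {condition!r} absent from matrix")
        return hits

    def features_of_biotype(self, biotype: str) -> list[str]:
        return [f for f in self.counts.index if self.biotypes[f] == biotype]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (GMT semantics): unique, nonempty member ids."""

    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_BIOTYPE_KEYS = ("gene_type", "gene_biotype")  # GENCODE, then Ensembl dialect


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path: str | Path) -> list[Transcript]:
    """Read transcript records from a GTF2.2-style file.

    1-based inclusive coordinates become 0-based half-open. Non-transcript
    feature lines are ignored; a transcript with an unrecognised biotype is
    skipped with a logged warning. A line with the wrong field count raises
    :class:`ParseError` naming the line number.
    """
    transcripts: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "transcript":
                continue
            attr = _parse_attributes(attrs)
            biotype = next(
                (attr[k] for k in _BIOTYPE_KEYS if k in attr), None
            )
            if biotype not in VALID_BIOTYPES:
                logger.warning(
                    "%s: line %d: skipping transcript %s with biotype %r",
                    path, lineno, attr.get("transcript_id", "?"), biotype,
                )
                continue
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            transcripts.append(
                Transcript(
                    id=attr["transcript_id"],
                    gene_id=attr["gene_id"],
                    biotype=biotype,
                    interval=iv,
                )
            )
    return transcripts


def write_gtf(transcripts: Sequence[Transcript], path: str | Path) -> None:
    """Write transcript records as GTF (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            iv = tx.interval
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.id}"; '
                f'gene_type "{tx.biotype}";'
            )
            fh.write(
                f"{iv.chrom}\tlncstate\ttranscript\t{iv.start + 1}\t{iv.end}"
                f"\t.\t{iv.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, name: str | None = None) -> PeakSet:
    """Read BED3/BED6 into a sorted :class:`PeakSet` (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: BED needs >= 3 columns, got {len(fields)}"
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 else "."
            if start >= end:
                raise ParseError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return PeakSet(name=name or Path(path).stem, intervals=intervals)


def write_bed(peakset: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(peakset.intervals):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{peakset.name}_{i}\t0\t{iv.strand}\n"
            )


def read_bedgraph(path: str | Path, name: str | None = None) -> SignalTrack:
    """Read a 4-column bedGraph. Overlapping steps or negative values error."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(
                    f"{path}: line {lineno}: bedGraph needs 4 columns, got {len(fields)}"
                )
            chrom, start, end, value = fields
            value = float(value)
            if value < 0:
                raise ValidationError(
                    f"{path}: line {lineno}: negative signal value {value}"
                )
            records.append((GenomicInterval(chrom, int(start), int(end)), value))
    return SignalTrack.from_records(name or Path(path).stem, records)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, value in track.records():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# counts TSV
# ---------------------------------------------------------------------------


def _infer_condition(sample_id: str) -> str:
    """GM_1 -> GM, DM_rep2 -> DM, W12_3 -> W12; no underscore -> whole id."""
    return sample_id.rsplit("_", 1)[0] if "_" in sample_id else sample_id


def read_counts(
    path: str | Path,
    conditions: dict[str, str] | None = None,
) -> CountMatrix:
    """Read a counts TSV: feature_id, biotype, then one column per sample.

    Condition labels default to the sample-id prefix before the final
    underscore (``GM_1`` -> ``GM``); pass ``conditions`` to override.
    Counts are coerced to integers; negatives raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "biotype" not in df.columns:
        raise ParseError(f"{path}: counts TSV must carry a 'biotype' column")
    biotypes = df["biotype"].astype(str)
    counts = df.drop(columns=["biotype"])
    values = counts.to_numpy()
    if (values < 0).any():
        raise ValidationError(f"{path}: negative count")
    if not np.allclose(values, np.round(values)):
        raise ValidationError(f"{path}: non-integer count")
    counts = counts.astype(np.int64)
    cond = pd.Series(
        {s: (conditions or {}).get(s, _infer_condition(s)) for s in counts.columns}
    )
    return CountMatrix(counts=counts, biotypes=biotypes, conditions=cond)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out.insert(0, "biotype", matrix.biotypes.loc[out.index])
    out.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT needs name, description, >=1 member"
                )
            sets.append(
                GeneSet(
                    name=fields[0],
                    description=fields[1],
                    members=frozenset(fields[2:]),
                )
            )
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t{gs.description}\t{members}\n")


# ---------------------------------------------------------------------------
# FASTA (plain parsing; genomes here are synthetic and modest in size)
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                if current in seqs:
                    raise ParseError(f"{path}: duplicate sequence name {current!r}")
                seqs[current] = []
            else:
                if current is None:
                    raise ParseError(f"{path}: sequence data before first header")
                seqs[current].append(line.upper())
    return {name: "".join(parts) for name, parts in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
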