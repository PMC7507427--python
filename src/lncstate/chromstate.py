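"""Chromatin-state classification of lncRNA TSS windows.

DE lncRNAs are examined in a strand-aware window around the TSS (2.5 kb
upstream, 1.5 kb downstream by default). A window overlapping any merged
ATAC peak marks the lncRNA open-chromatin-associated; the ATAC regions,
extended by 1 kb on each side and re-merged, are then tested for
co-localisation with H3K4me3 (promoter mark) and H3K4me1 (enhancer mark)
peaks, yielding four exclusive categories:

    ATAC_H3K4me3 > ATAC_H3K4me1 > ATAC_only > closed

with the stated precedence when both marks co-occur. Signal differences
between conditions are quantified as mean per-base coverage over the
extended regions, quantile-normalised across samples, and expressed as
log2 fold-changes; group contrasts (up vs down vs sampled non-DE
controls) use the Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import GenomicInterval, PeakSet, SignalTrack, Transcript, ValidationError

CATEGORY_K4ME3 = "ATAC_H3K4me3"
CATEGORY_K4ME1 = "ATAC_H3K4me1"
CATEGORY_ATAC_ONLY = "ATAC_only"
CATEGORY_CLOSED = "closed"
CATEGORIES = (CATEGORY_K4ME3, CATEGORY_K4ME1, CATEGORY_ATAC_ONLY, CATEGORY_CLOSED)


@dataclass(frozen=True)
class TSSWindow:
    transcript_id: str
    interval: GenomicInterval


@dataclass
class ChromatinAnnotation:
    transcript_id: str
    de_status: str
    open_chromatin: bool
    category: str
    atac_log2fc: float | None = None
    mark_log2fc: float | None = None
    bound_tfs: frozenset[str] = frozenset()


@dataclass
class GroupComparison:
    """Pairwise Mann-Whitney contrasts of per-group signal log2FC vectors."""

    groups: dict[str, np.ndarray]
    statistics: dict[tuple[str, str], float] = field(default_factory=dict)
    p_values: dict[tuple[str, str], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# interval algebra (bedtools-merge semantics: bookended intervals join at gap 0)
# ---------------------------------------------------------------------------


def merge_peaks(peaksets: list[PeakSet], gap: int = 0, name: str = "merged") -> PeakSet:
    """Union-merge intervals from one or more peak sets.

    Two intervals join when they overlap or their gap is <= ``gap`` bases
    (gap 0 joins bookended intervals, as `bedtools merge -d 0` does).
    Total covered bases never decrease; output is sorted, non-overlapping.
    """
    all_ivs = sorted(
        (iv for ps in peaksets for iv in ps.intervals),
        key=lambda iv: (iv.chrom, iv.start, iv.end),
    )
    merged: list[GenomicInterval] = []
    for iv in all_ivs:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end <= gap
        ):
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(
                    iv.chrom, merged[-1].start, iv.end, "."
                )
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end, "."))
    return PeakSet(name=name, intervals=merged)


def extend_peaks(
    peakset: PeakSet, chrom_lengths: dict[str, int], flank: int = 1000
) -> PeakSet:
    """Grow every peak by ``flank`` bp on both sides (clamped), then re-merge."""
    extended = []
    for iv in peakset.intervals:
        if iv.chrom not in chrom_lengths:
            raise ValidationError(f"no chromosome length for {iv.chrom!r}")
        start = max(0, iv.start - flank)
        end = min(chrom_lengths[iv.chrom], iv.end + flank)
        extended.append(GenomicInterval(iv.chrom, start, end, "."))
    return merge_peaks(
        [PeakSet(name=peakset.name, intervals=extended)], gap=0,
        name=f"{peakset.name}_ext",
    )


def make_tss_window(
    transcript: Transcript,
    chrom_length: int,
    upstream: int = 2500,
    downstream: int = 1500,
) -> TSSWindow:
    """Strand-aware TSS window: upstream is 5' of the direction of transcription.

    '+' strand, TSS t: [t - upstream, t + downstream);
    '-' strand, TSS t: [t - downstream + 1, t + upstream + 1);
    both clamped to [0, chrom_length).
    """
    tss = transcript.tss
    if not (0 <= tss < chrom_length):
        raise ValidationError(
            f"TSS {tss} of {transcript.id} outside chromosome of length {chrom_length}"
        )
    if transcript.interval.strand == "-":
        start, end = tss - downstream + 1, tss + upstream + 1
    else:
        start, end = tss - upstream, tss + downstream
    start = max(0, start)
    end = min(chrom_length, end)
    return TSSWindow(
        transcript_id=transcript.id,
        interval=GenomicInterval(
            transcript.interval.chrom, start, end, transcript.interval.strand
        ),
    )


def _overlapping(
    query: GenomicInterval, peaks_by_chrom: dict[str, list[GenomicInterval]]
) -> list[GenomicInterval]:
    """Peaks with >= 1 bp overlap with the query (binary search on sorted starts)."""
    peaks = peaks_by_chrom.get(query.chrom, [])
    hits = []
    for iv in peaks:
        if iv.start >= query.end:
            break
        if iv.end > query.start:
            hits.append(iv)
    return hits


def assign_open_chromatin(
    windows: list[TSSWindow], atac_peaks: PeakSet
) -> dict[str, bool]:
    """True iff the TSS window shares >= 1 bp with any ATAC peak.

    Raises if the two inputs share no chromosome names — almost always a
    naming-convention mismatch between files, never fixed silently.
    """
    if not windows or not len(atac_peaks):
        raise ValidationError("windows and ATAC peaks must both be nonempty")
    win_chroms = {w.interval.chrom for w in windows}
    if not win_chroms & atac_peaks.chroms():
        raise ValidationError(
            "no chromosome names shared between TSS windows and ATAC peaks "
            f"({sorted(win_chroms)[:3]} vs {sorted(atac_peaks.chroms())[:3]}); "
            "check naming conventions"
        )
    by_chrom = atac_peaks.by_chrom()
    return {
        w.transcript_id: bool(_overlapping(w.interval, by_chrom)) for w in windows
    }


def classify_category(
    window: TSSWindow,
    atac_peaks: PeakSet,
    k4me1_peaks: PeakSet,
    k4me3_peaks: PeakSet,
    atac_extended: PeakSet | None = None,
) -> str:
    """Four-way chromatin category of a TSS window.

    Closed iff the window overlaps no ATAC peak (same predicate as
    :func:`assign_open_chromatin`, so category != closed iff open).
    The histone marks are then tested against the EXTENDED (+/- 1 kb,
    re-merged) ATAC regions the window touches — pass ``atac_extended``;
    when omitted the raw peaks double as the co-localisation regions.
    H3K4me3 wins over H3K4me1 when both marks co-occur.
    """
    if not _overlapping(window.interval, atac_peaks.by_chrom()):
        return CATEGORY_CLOSED
    regions = _overlapping(
        window.interval, (atac_extended or atac_peaks).by_chrom()
    )
    k4me3_by = k4me3_peaks.by_chrom()
    k4me1_by = k4me1_peaks.by_chrom()
    if any(_overlapping(r, k4me3_by) for r in regions):
        return CATEGORY_K4ME3
    if any(_overlapping(r, k4me1_by) for r in regions):
        return CATEGORY_K4ME1
    return CATEGORY_ATAC_ONLY


def window_atac_regions(window: TSSWindow, atac_extended: PeakSet) -> list[GenomicInterval]:
    """The extended ATAC regions a TSS window overlaps (possibly empty)."""
    return _overlapping(window.interval, atac_extended.by_chrom())


# ---------------------------------------------------------------------------
# signal quantification
# ---------------------------------------------------------------------------


def quantify_signal(track: SignalTrack, regions: list[GenomicInterval]) -> np.ndarray:
    """Mean per-base coverage per region; uncovered bases contribute 0."""
    out = np.zeros(len(regions))
    for i, region in enumerate(regions):
        if region.chrom not in track.steps:
            continue
        starts, ends, values = track.steps[region.chrom]
        lo = np.searchsorted(ends, region.start, side="right")
        hi = np.searchsorted(starts, region.end, side="left")
        if lo >= hi:
            continue
        ov = np.minimum(ends[lo:hi], region.end) - np.maximum(
            starts[lo:hi], region.start
        )
        out[i] = float(np.sum(ov * values[lo:hi])) / region.width
    return out


def quantile_normalize(matrix: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Quantile normalisation across columns (Bolstad's algorithm).

    Each column is replaced by the row-means of the column-sorted matrix at
    its own ranks; tied values receive the mean of their tied reference
    values. Afterwards every column holds the identical value multiset.
    """
    arr = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValidationError("quantile normalization needs a 2-D matrix with >= 2 columns")
    if np.isnan(arr).any():
        raise ValidationError("missing values not supported")
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty_like(reference)
        mapped[order] = reference
        # ties: average the reference values over each tied run
        sorted_col = col[order]
        k = 0
        while k < len(sorted_col):
            m = k
            while m + 1 < len(sorted_col) and sorted_col[m + 1] == sorted_col[k]:
                m += 1
            if m > k:
                mapped[order[k : m + 1]] = reference[k : m + 1].mean()
            k = m + 1
        out[:, j] = mapped
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def signal_log2fc(
    values_b: np.ndarray, values_a: np.ndarray, pseudocount: float = 1.0
) -> np.ndarray:
    """log2((B + c) / (A + c)); antisymmetric in its arguments."""
    values_b = np.asarray(values_b, dtype=float)
    values_a = np.asarray(values_a, dtype=float)
    if values_b.shape != values_a.shape:
        raise ValidationError("signal vectors must have equal length")
    return np.log2((values_b + pseudocount) / (values_a + pseudocount))


# ---------------------------------------------------------------------------
# TF binding
# ---------------------------------------------------------------------------


def associate_tfs(
    windows: list[TSSWindow],
    atac_extended: PeakSet,
    tf_peaksets: dict[str, PeakSet],
) -> dict[str, frozenset[str]]:
    """TFs whose peaks overlap the extended ATAC region(s) of each window."""
    result: dict[str, frozenset[str]] = {}
    tf_by = {tf: ps.by_chrom() for tf, ps in tf_peaksets.items()}
    atac_by = atac_extended.by_chrom()
    for w in windows:
        regions = _overlapping(w.interval, atac_by)
        bound = frozenset(
            tf
            for tf, by in tf_by.items()
            if any(_overlapping(r, by) for r in regions)
        )
        result[w.transcript_id] = bound
    return result


def colocalization_fraction(
    tf_a: str, tf_b: str, bound: dict[str, frozenset[str]]
) -> float | None:
    """|windows bound by both| / |windows bound by either|; None if no window
    is bound by either TF (undefined, reported as NA downstream)."""
    both = sum(1 for tfs in bound.values() if tf_a in tfs and tf_b in tfs)
    either = sum(1 for tfs in bound.values() if tf_a in tfs or tf_b in tfs)
    if either == 0:
        return None
    return both / either


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def sample_non_de_controls(non_de_ids: list[str], n: int, seed: int) -> list[str]:
    """Uniform sample without replacement, reproducible for a fixed seed."""
    if n > len(non_de_ids):
        raise ValidationError(
            f"requested {n} controls from a pool of {len(non_de_ids)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(non_de_ids), size=n, replace=False)
    return [non_de_ids[i] for i in sorted(idx)]


def compare_groups(
    up_fc: np.ndarray, down_fc: np.ndarray, control_fc: np.ndarray
) -> GroupComparison:
    """Two-sided Mann-Whitney U on each pair of groups.

    Exact p for small untied samples, normal approximation with tie
    correction otherwise (scipy's method="auto").
    """
    groups = {
        "up": np.asarray(up_fc, dtype=float),
        "down": np.asarray(down_fc, dtype=float),
        "control": np.asarray(control_fc, dtype=float),
    }
    for label, vals in groups.items():
        if len(vals) == 0:
            raise ValidationError(f"empty group {label!r}")
    comparison = GroupComparison(groups=groups)
    for a, b in (("up", "control"), ("up", "down"), ("down", "control")):
        res = stats.mannwhitneyu(
            groups[a], groups[b], alternative="two-sided", method="auto"
        )
        comparison.statistics[(a, b)] = float(res.statistic)
        comparison.p_values[(a, b)] = float(res.pvalue)
    return comparison


# ---------------------------------------------------------------------------
# orchestration of the full chromatin-state annotation
# ---------------------------------------------------------------------------


def annotate_chromatin_states(
    transcripts: dict[str, Transcript],
    de_status: dict[str, str],
    atac_gm: PeakSet,
    atac_dm: PeakSet,
    signal_gm: SignalTrack,
    signal_dm: SignalTrack,
    k4me1: PeakSet,
    k4me3: PeakSet,
    tf_peaks: dict[str, PeakSet],
    chrom_lengths: dict[str, int],
    upstream: int = 2500,
    downstream: int = 1500,
    flank: int = 1000,
    mark_signals: dict[str, tuple[SignalTrack, SignalTrack]] | None = None,
) -> pd.DataFrame:
    """Run the full TSS-window chromatin annotation for a set of transcripts.

    ATAC peaks from both conditions are union-merged to define open
    chromatin, then extended/re-merged for mark and TF co-localisation and
    signal quantification. Per-transcript ATAC log2FC (DM vs GM) is the
    quantile-normalised mean coverage over the window's extended regions.
    ``mark_signals`` optionally maps a mark name ("H3K4me1"/"H3K4me3") to
    its (GM, DM) coverage tracks; when given, transcripts of that mark's
    category get a ``mark_log2fc`` computed the same way (NA otherwise).
    Returns a tidy frame indexed by transcript_id.
    """
    atac_union = merge_peaks([atac_gm, atac_dm], gap=0, name="atac_union")
    atac_ext = extend_peaks(atac_union, chrom_lengths, flank=flank)

    windows = [
        make_tss_window(transcripts[tid], chrom_lengths[transcripts[tid].interval.chrom],
                        upstream=upstream, downstream=downstream)
        for tid in de_status
    ]
    open_map = assign_open_chromatin(windows, atac_union)
    bound = associate_tfs(windows, atac_ext, tf_peaks)

    # per-window signal: mean coverage over its extended ATAC regions,
    # quantile-normalised across the two conditions before the log-ratio
    region_lists = {w.transcript_id: window_atac_regions(w, atac_ext) for w in windows}
    open_ids = [w.transcript_id for w in windows if open_map[w.transcript_id]]
    atac_fc: dict[str, float] = {}
    if open_ids:
        flat_regions = []
        spans: list[tuple[int, int]] = []
        for tid in open_ids:
            lo = len(flat_regions)
            flat_regions.extend(region_lists[tid])
            spans.append((lo, len(flat_regions)))
        gm_vals = quantify_signal(signal_gm, flat_regions)
        dm_vals = quantify_signal(signal_dm, flat_regions)
        norm = quantile_normalize(np.column_stack([gm_vals, dm_vals]))
        fc = signal_log2fc(norm[:, 1], norm[:, 0])
        widths = np.array([r.width for r in flat_regions], dtype=float)
        for tid, (lo, hi) in zip(open_ids, spans):
            atac_fc[tid] = float(np.average(fc[lo:hi], weights=widths[lo:hi]))

    categories = {
        w.transcript_id: classify_category(
            w, atac_union, k4me1, k4me3, atac_extended=atac_ext
        )
        for w in windows
    }

    # per-mark signal log2FC over the same extended regions, for the
    # transcripts whose category carries that mark
    mark_fc: dict[str, float] = {}
    mark_of_category = {CATEGORY_K4ME1: "H3K4me1", CATEGORY_K4ME3: "H3K4me3"}
    for category_name, mark in mark_of_category.items():
        if not mark_signals or mark not in mark_signals:
            continue
        gm_track, dm_track = mark_signals[mark]
        tids = [
            w.transcript_id for w in windows
            if categories[w.transcript_id] == category_name
            and region_lists[w.transcript_id]
        ]
        if not tids:
            continue
        flat, spans = [], []
        for tid in tids:
            lo = len(flat)
            flat.extend(region_lists[tid])
            spans.append((lo, len(flat)))
        norm = quantile_normalize(
            np.column_stack(
                [quantify_signal(gm_track, flat), quantify_signal(dm_track, flat)]
            )
        )
        fc = signal_log2fc(norm[:, 1], norm[:, 0])
        widths = np.array([r.width for r in flat], dtype=float)
        for tid, (lo, hi) in zip(tids, spans):
            mark_fc[tid] = float(np.average(fc[lo:hi], weights=widths[lo:hi]))

    rows = []
    for w in windows:
        tid = w.transcript_id
        rows.append(
            {
                "transcript_id": tid,
                "status": de_status[tid],
                "open_chromatin": open_map[tid],
                "category": categories[tid],
                "atac_log2fc": atac_fc.get(tid, np.nan),
                "mark_log2fc": mark_fc.get(tid, np.nan),
                "bound_tfs": ",".join(sorted(bound[tid])),
            }
        )
    return pd.DataFrame(rows).set_index("transcript_id")
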