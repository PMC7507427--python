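"""Interval algebra, signal quantification, normalisation, group tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

from lncstate import chromstate as cs
from lncstate.genomic_io import (
    GenomicInterval,
    PeakSet,
    SignalTrack,
    Transcript,
    ValidationError,
)


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def peaks(*pairs, chrom="chr1", name="p"):
    return PeakSet(name=name, intervals=[iv(s, e, chrom) for s, e in pairs])


def tx(tss, strand="+", chrom="chr1", tid="t"):
    if strand == "+":
        interval = GenomicInterval(chrom, tss, tss + 1000, "+")
    else:
        interval = GenomicInterval(chrom, tss - 999, tss + 1, "-")
    return Transcript(tid, tid + "_g", "lncRNA", interval)


# ---------------------------------------------------------------------------
# TSS windows
# ---------------------------------------------------------------------------


def test_tss_window_plus_minus_and_clamp():
    w = cs.make_tss_window(tx(10_000, "+"), chrom_length=10**6)
    assert (w.interval.start, w.interval.end) == (7500, 11_500)
    w = cs.make_tss_window(tx(10_000, "-"), chrom_length=10**6)
    assert (w.interval.start, w.interval.end) == (8501, 12_501)
    w = cs.make_tss_window(tx(100, "+"), chrom_length=10**6)
    assert (w.interval.start, w.interval.end) == (0, 1600)


def test_tss_outside_chromosome_errors():
    with pytest.raises(ValidationError, match="outside"):
        cs.make_tss_window(tx(10_000, "+"), chrom_length=5000)


# ---------------------------------------------------------------------------
# merge / extend (bedtools semantics) against a per-base bitmap oracle
# ---------------------------------------------------------------------------


def bitmap_union(peaksets, genome_len, flank=0):
    grid = np.zeros(genome_len, dtype=bool)
    for ps in peaksets:
        for p in ps.intervals:
            grid[max(0, p.start - flank) : min(genome_len, p.end + flank)] = True
    out = []
    start = None
    for i, bit in enumerate(grid):
        if bit and start is None:
            start = i
        elif not bit and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, genome_len))
    return out


def test_merge_bookended_and_gapped():
    merged = cs.merge_peaks([peaks((0, 10), (10, 20))])
    assert [(p.start, p.end) for p in merged.intervals] == [(0, 20)]
    merged = cs.merge_peaks([peaks((0, 10), (11, 20))])
    assert [(p.start, p.end) for p in merged.intervals] == [(0, 10), (11, 20)]


def test_extend_grows_and_clamps():
    lengths = {"chr1": 10_000}
    ext = cs.extend_peaks(peaks((5000, 5100)), lengths, flank=1000)
    assert [(p.start, p.end) for p in ext.intervals] == [(4000, 6100)]
    ext = cs.extend_peaks(peaks((100, 200)), lengths, flank=1000)
    assert [(p.start, p.end) for p in ext.intervals] == [(0, 1200)]


def test_merge_and_extend_match_bitmap_oracle(rng):
    for _ in range(300):
        n = int(rng.integers(1, 30))
        starts = rng.integers(0, 950, size=n)
        ivs = [iv(int(s), int(s + rng.integers(1, 60))) for s in starts]
        ps = PeakSet(name="r", intervals=ivs)
        merged = cs.merge_peaks([ps])
        assert [(p.start, p.end) for p in merged.intervals] == bitmap_union([ps], 1100)
        flank = int(rng.integers(0, 40))
        ext = cs.extend_peaks(ps, {"chr1": 1100}, flank=flank)
        assert [(p.start, p.end) for p in ext.intervals] == bitmap_union(
            [ps], 1100, flank=flank
        )


# ---------------------------------------------------------------------------
# open-chromatin assignment
# ---------------------------------------------------------------------------


def test_open_chromatin_half_open_boundary():
    w = cs.TSSWindow("t", iv(0, 100))
    assert cs.assign_open_chromatin([w], peaks((99, 200)))["t"] is True
    assert cs.assign_open_chromatin([w], peaks((100, 200)))["t"] is False


def test_open_chromatin_chrom_mismatch_errors():
    w = cs.TSSWindow("t", iv(0, 100, chrom="chr1"))
    with pytest.raises(ValidationError, match="naming"):
        cs.assign_open_chromatin([w], peaks((0, 50), chrom="1"))


def test_overlap_matches_quadratic_oracle(rng):
    for _ in range(100):
        windows = [
            cs.TSSWindow(f"t{i}", iv(int(s), int(s + rng.integers(1, 80))))
            for i, s in enumerate(rng.integers(0, 900, size=10))
        ]
        ps = peaks(*[
            (int(s), int(s + rng.integers(1, 80))) for s in rng.integers(0, 900, size=8)
        ])
        got = cs.assign_open_chromatin(windows, ps)
        for w in windows:
            expect = any(w.interval.overlaps(p) for p in ps.intervals)
            assert got[w.transcript_id] == expect


# ---------------------------------------------------------------------------
# signal quantification + normalisation
# ---------------------------------------------------------------------------


def track(*records, name="sig"):
    return SignalTrack.from_records(
        name, [(iv(s, e), v) for s, e, v in records]
    )


def test_quantify_uniform_and_half_coverage():
    t = track((0, 100, 2.0))
    assert cs.quantify_signal(t, [iv(0, 100)])[0] == pytest.approx(2.0)
    t = track((0, 50, 4.0))
    assert cs.quantify_signal(t, [iv(0, 100)])[0] == pytest.approx(2.0)


def test_quantify_matches_per_base_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(1, 15))
        pos = np.sort(rng.choice(500, size=2 * n, replace=False))
        recs = [
            (int(pos[2 * i]), int(pos[2 * i + 1]), float(rng.uniform(0, 5)))
            for i in range(n)
            if pos[2 * i] < pos[2 * i + 1]
        ]
        t = track(*recs)
        base = np.zeros(600)
        for s, e, v in recs:
            base[s:e] = v
        regions = [
            iv(int(s), int(s + rng.integers(1, 100)))
            for s in rng.integers(0, 500, size=5)
        ]
        got = cs.quantify_signal(t, regions)
        want = [base[r.start : r.end].mean() for r in regions]
        np.testing.assert_allclose(got, want, atol=1e-12)


def test_quantile_normalize_hand_example_and_properties(rng):
    out = cs.quantile_normalize(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
    np.testing.assert_allclose(out, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    same = np.tile(rng.uniform(size=(10, 1)), (1, 2))
    np.testing.assert_allclose(cs.quantile_normalize(same), same)

    x = rng.uniform(size=(40, 5))
    norm = cs.quantile_normalize(x)
    for j in range(1, 5):
        np.testing.assert_allclose(np.sort(norm[:, 0]), np.sort(norm[:, j]))
    np.testing.assert_allclose(cs.quantile_normalize(norm), norm, atol=1e-12)


def test_quantile_normalize_ties_get_mean_reference():
    out = cs.quantile_normalize(np.array([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]]))
    # tied values in column 0 share the mean of the two lowest reference values
    assert out[0, 0] == out[1, 0]


def test_signal_log2fc_examples_and_antisymmetry(rng):
    np.testing.assert_allclose(cs.signal_log2fc(np.ones(4), np.ones(4)), np.zeros(4))
    assert cs.signal_log2fc(np.array([3.0]), np.array([0.0]))[0] == pytest.approx(2.0)
    a, b = rng.uniform(0, 50, 30), rng.uniform(0, 50, 30)
    np.testing.assert_allclose(
        cs.signal_log2fc(b, a), -cs.signal_log2fc(a, b), atol=1e-12
    )


# ---------------------------------------------------------------------------
# category classification
# ---------------------------------------------------------------------------


def test_category_precedence_and_order_invariance():
    w = cs.TSSWindow("t", iv(1000, 5000))
    atac = peaks((2000, 2400))
    ext = cs.extend_peaks(atac, {"chr1": 10_000}, flank=1000)
    both = dict(
        atac_peaks=atac, atac_extended=ext,
        k4me1_peaks=peaks((1200, 1300)), k4me3_peaks=peaks((3200, 3300)),
    )
    assert cs.classify_category(w, **both) == cs.CATEGORY_K4ME3  # me3 wins
    assert (
        cs.classify_category(w, atac, peaks((9000, 9100)), peaks((9000, 9100)), ext)
        == cs.CATEGORY_ATAC_ONLY
    )
    assert (
        cs.classify_category(w, peaks((8000, 8400)), peaks((1, 2)), peaks((1, 2)))
        == cs.CATEGORY_CLOSED
    )
    # invariant to peak input ordering
    shuffled = peaks((2000, 2400))
    shuffled.intervals = list(reversed(shuffled.intervals))
    assert cs.classify_category(w, shuffled, **{k: both[k] for k in ("k4me1_peaks", "k4me3_peaks", "atac_extended")}) == cs.CATEGORY_K4ME3


# ---------------------------------------------------------------------------
# TF association
# ---------------------------------------------------------------------------


def test_tf_association_and_colocalization():
    w = cs.TSSWindow("t", iv(1000, 5000))
    ext = cs.extend_peaks(peaks((2000, 2400)), {"chr1": 10_000}, flank=1000)
    same = peaks((2100, 2300))
    bound = cs.associate_tfs([w], ext, {"MyoD": same, "MyoG": same})
    assert bound["t"] == frozenset({"MyoD", "MyoG"})
    assert cs.colocalization_fraction("MyoD", "MyoG", bound) == 1.0
    assert cs.colocalization_fraction("Usf1", "Max", bound) is None


def test_tf_association_matches_all_pairs_oracle(rng):
    for _ in range(40):
        windows = [
            cs.TSSWindow(f"t{i}", iv(int(s), int(s) + 200))
            for i, s in enumerate(rng.integers(0, 3000, size=8))
        ]
        ext = peaks(*[(int(s), int(s) + 150) for s in rng.integers(0, 3000, size=6)])
        tfs = {
            name: peaks(*[(int(s), int(s) + 80) for s in rng.integers(0, 3000, size=4)])
            for name in ("a", "b")
        }
        got = cs.associate_tfs(windows, ext, tfs)
        for w in windows:
            regions = [r for r in ext.intervals if w.interval.overlaps(r)]
            for name, ps in tfs.items():
                expect = any(r.overlaps(p) for r in regions for p in ps.intervals)
                assert (name in got[w.transcript_id]) == expect


# ---------------------------------------------------------------------------
# control sampling + group comparison
# ---------------------------------------------------------------------------


def test_control_sampling_reproducible_and_uniform():
    pool = [f"x{i}" for i in range(10)]
    assert sorted(cs.sample_non_de_controls(pool, 10, seed=3)) == sorted(pool)
    assert cs.sample_non_de_controls(pool, 4, seed=5) == cs.sample_non_de_controls(
        pool, 4, seed=5
    )
    with pytest.raises(ValidationError):
        cs.sample_non_de_controls(pool, 11, seed=1)
    # empirical inclusion frequency uniform over repeated draws
    counts = np.zeros(10)
    for seed in range(2000):
        for item in cs.sample_non_de_controls(pool, 3, seed=seed):
            counts[pool.index(item)] += 1
    chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
    assert chi2 < stats.chi2.ppf(0.999, df=9)


def test_mann_whitney_examples():
    res = stats.mannwhitneyu([5, 6, 7], [-7, -6, -5], alternative="greater")
    assert res.statistic == 9 and res.pvalue == pytest.approx(0.05)
    comp = cs.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert comp.p_values[("up", "down")] == pytest.approx(1.0)


def test_mann_whitney_matches_exact_enumeration(rng):
    """Implementation agrees with brute-force U-permutation p for n <= 8."""
    for _ in range(20):
        n, m = int(rng.integers(3, 5)), int(rng.integers(3, 5))
        x = rng.normal(size=n)
        y = rng.normal(size=m)
        comp = cs.compare_groups(x, y, np.r_[x, y])
        u_obs, p_obs = comp.statistics[("up", "down")], comp.p_values[("up", "down")]
        pooled = np.r_[x, y]
        us = []
        for idx in itertools.combinations(range(n + m), n):
            xs = pooled[list(idx)]
            ys = pooled[[i for i in range(n + m) if i not in idx]]
            us.append(sum(1 for a in xs for b in ys if a > b))
        us = np.array(us)
        # two-sided exact p: double the smaller tail (with point mass)
        lo = (us <= u_obs).mean()
        hi = (us >= u_obs).mean()
        assert p_obs == pytest.approx(min(1.0, 2 * min(lo, hi)), abs=1e-9)


def test_mark_signal_log2fc_for_marked_categories():
    """Optional histone-mark tracks yield mark_log2fc only for their category."""
    from lncstate.genomic_io import Transcript

    transcripts = {}
    status = {}
    for i, tss in enumerate((10_000, 30_000, 50_000, 70_000)):
        tid = f"t{i}"
        transcripts[tid] = Transcript(
            tid, f"{tid}_g", "lncRNA", GenomicInterval("chr1", tss, tss + 1000, "+")
        )
        status[tid] = "up" if i % 2 == 0 else "down"
    # ATAC peak on every TSS; H3K4me1 next to t0/t1, H3K4me3 next to t2/t3
    atac = peaks(*[(t - 200, t + 200) for t in (10_000, 30_000, 50_000, 70_000)])
    k4me1 = peaks((10_500, 10_800), (30_500, 30_800))
    k4me3 = peaks((50_500, 50_800), (70_500, 70_800))
    sig_gm = track(*[(t - 200, t + 200, 40.0) for t in (10_000, 30_000, 50_000, 70_000)])
    sig_dm = track(*[(t - 200, t + 200, 40.0) for t in (10_000, 30_000, 50_000, 70_000)])
    # mark signal: gains 4x where the lncRNA is up, loses 4x where down
    me1_gm = track((10_300, 10_900, 20.0), (30_300, 30_900, 24.0))
    me1_dm = track((10_300, 10_900, 80.0), (30_300, 30_900, 6.0))
    frame = cs.annotate_chromatin_states(
        transcripts=transcripts,
        de_status=status,
        atac_gm=atac, atac_dm=atac,
        signal_gm=sig_gm, signal_dm=sig_dm,
        k4me1=k4me1, k4me3=k4me3,
        tf_peaks={},
        chrom_lengths={"chr1": 100_000},
        mark_signals={"H3K4me1": (me1_gm, me1_dm)},
    )
    assert frame.loc["t0", "category"] == cs.CATEGORY_K4ME1
    assert frame.loc["t2", "category"] == cs.CATEGORY_K4ME3
    assert frame.loc["t0", "mark_log2fc"] > 0 > frame.loc["t1", "mark_log2fc"]
    # no H3K4me3 track supplied -> NA for that category
    assert np.isnan(frame.loc["t2", "mark_log2fc"])
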