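"""Synthetic-study generator: determinism, truth consistency, planted effects."""

import hashlib
from pathlib import Path

import numpy as np
import pytest

from lncstate import chromstate, coexpr, diffexpr, synthio
from lncstate.genomic_io import ValidationError, read_gtf


def file_hashes(root: Path) -> dict[str, str]:
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(root))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def test_same_seed_gives_byte_identical_files(tmp_path):
    cfg = synthio.SimulationConfig(
        seed=7, n_lnc=40, n_pcg=200, chrom_length=800_000,
        module_size=20, module_lnc=5,
    )
    synthio.generate_study(cfg, tmp_path / "a")
    synthio.generate_study(cfg, tmp_path / "b")
    assert file_hashes(tmp_path / "a") == file_hashes(tmp_path / "b")


def test_overcrowded_chromosome_errors():
    cfg = synthio.SimulationConfig(n_lnc=500, n_pcg=2000, chrom_length=100_000)
    with pytest.raises(ValidationError, match="overcrowded"):
        synthio.simulate_annotation(cfg)


def test_no_lncrnas_means_only_protein_coding(tmp_path):
    cfg = synthio.SimulationConfig(
        n_lnc=0, module_lnc=0, n_pcg=300, chrom_length=1_000_000
    )
    transcripts, _, _ = synthio.simulate_annotation(cfg)
    assert {t.biotype for t in transcripts} == {"protein_coding"}


def test_tss_windows_never_clamped(study):
    transcripts = read_gtf(study["paths"]["gtf"])
    for t in transcripts:
        w = chromstate.make_tss_window(t, chrom_length=study["config"].chrom_length)
        assert w.interval.width == 4000


def test_truth_table_consistent_with_files(sim_config):
    """The generator's self-check (re-derives categories/TFs from the files)."""
    transcripts, chrom_lengths, _ = synthio.simulate_annotation(sim_config)
    truth = synthio.assign_truth(sim_config)
    chromatin = synthio.simulate_chromatin(sim_config, truth, transcripts)
    synthio.validate_truth(sim_config, truth, transcripts, chromatin, chrom_lengths)


def test_poisson_limit_when_dispersion_zero():
    cfg = synthio.SimulationConfig(
        seed=3, dispersion=0.0, n_lnc=30, n_pcg=120, chrom_length=600_000,
        module_size=20, module_lnc=5,
    )
    truth = synthio.assign_truth(cfg)
    matrix = synthio.simulate_counts(cfg, truth)
    not_de = truth.features.index[
        (truth.features["de_status"] == "not_de") & (truth.features["module"] < 0)
    ]
    gm = matrix.counts.loc[not_de, ["GM_1", "GM_2", "GM_3"]].to_numpy(float)
    # Poisson: variance ~ mean; the index of dispersion has only 2 df per
    # feature, so average it across features (NB with phi=0.1 and counts
    # ~100s would give a mean ratio far above this band)
    ratio = gm.var(axis=1, ddof=1) / np.maximum(gm.mean(axis=1), 1)
    assert 0.6 < ratio.mean() < 1.5


def test_planted_log2fc_recovered_empirically(study):
    """Planted |LFC| = 2 is recovered from count means (the generative scale).

    CPM-level fold-changes additionally carry the classic composition bias
    (~0.4 log2 here, since 30% of the transcriptome moves asymmetrically),
    which scale-factor normalisations such as TMM exist to remove.
    """
    truth = study["truth"].features
    matrix = synthio.simulate_counts(study["config"], study["truth"])
    gm = matrix.counts[["GM_1", "GM_2", "GM_3"]].mean(axis=1)
    dm = matrix.counts[["DM60_1", "DM60_2", "DM60_3"]].mean(axis=1)
    lfc = np.log2((dm + 0.5) / (gm + 0.5))
    up = truth.index[truth["de_status"] == "up"]
    assert 1.6 <= lfc.loc[up].mean() <= 2.4
    down = truth.index[truth["de_status"] == "down"]
    assert -2.4 <= lfc.loc[down].mean() <= -1.6


def test_within_module_correlation_near_target(study):
    truth = study["truth"].features
    matrix = synthio.simulate_counts(study["config"], study["truth"])
    cpm = diffexpr.compute_cpm(matrix.counts)
    c2c12 = [s for s in matrix.sample_ids
             if matrix.conditions[s] in synthio.C2C12_CONDITIONS]
    expr = coexpr.log_cpm(cpm[c2c12])
    means = []
    for m in range(study["config"].n_modules):
        ids = list(truth.index[truth["module"] == m])
        r = np.corrcoef(expr.loc[ids])
        iu = np.triu_indices(len(ids), 1)
        means.append(r[iu].mean())
    assert abs(np.mean(means) - study["config"].target_module_r) <= 0.1


def test_closed_lncrnas_have_no_atac_peak_in_window(study):
    truth = study["truth"].features
    transcripts = {t.id: t for t in read_gtf(study["paths"]["gtf"])}
    from lncstate.genomic_io import read_bed

    union = chromstate.merge_peaks(
        [read_bed(study["paths"]["atac_gm"]), read_bed(study["paths"]["atac_dm"])]
    )
    closed = truth.index[truth["category"] == chromstate.CATEGORY_CLOSED]
    by = union.by_chrom()
    for fid in closed:
        w = chromstate.make_tss_window(
            transcripts[fid], chrom_length=study["config"].chrom_length
        )
        assert not chromstate._overlapping(w.interval, by)


def test_full_colocalization_when_configured(tmp_path):
    cfg = synthio.SimulationConfig(
        seed=5, myod_myog_both=1.0, myod_myog_only_each=0.0,
        n_lnc=80, n_pcg=200, chrom_length=1_600_000, module_lnc=5, module_size=20,
    )
    transcripts, chrom_lengths, _ = synthio.simulate_annotation(cfg)
    truth = synthio.assign_truth(cfg)
    chromatin = synthio.simulate_chromatin(cfg, truth, transcripts)
    union = chromstate.merge_peaks(list(chromatin.atac.values()))
    ext = chromstate.extend_peaks(union, chrom_lengths)
    lnc = [t for t in transcripts if t.biotype == "lncRNA"]
    windows = [
        chromstate.make_tss_window(t, chrom_lengths[t.interval.chrom]) for t in lnc
    ]
    bound = chromstate.associate_tfs(windows, ext, chromatin.tf_peaks)
    frac = chromstate.colocalization_fraction("MyoD", "MyoG", bound)
    assert frac == 1.0


def test_motif_insertion_rates(tmp_path):
    cfg = synthio.SimulationConfig(seed=9, motif_fg_rate=1.0, motif_bg_rate=0.0,
                                   n_lnc=100, n_pcg=200, chrom_length=1_700_000,
                                   module_lnc=5, module_size=20)
    transcripts, chrom_lengths, genome = synthio.simulate_annotation(cfg)
    truth = synthio.assign_truth(cfg)
    chromatin = synthio.simulate_chromatin(cfg, truth, transcripts)
    fg, bg, genome = synthio.simulate_motif_regions(
        cfg, truth, chromatin, transcripts, genome
    )
    ins = truth.insertions
    myod_regions = set(ins.loc[ins["motif"] == "MyoD", "region"])
    de_open = {
        fid for fid in chromatin.peak_center
        if truth.features.at[fid, "de_status"] != "not_de"
    }
    assert myod_regions == de_open  # rate 1.0 in fg, 0.0 in bg
    # the consensus is really in the sequence
    from lncstate import motifenr

    pwm = {p.name: p for p in motifenr.default_pwms()}["MyoD"]
    consensus = pwm.consensus()
    for region in fg.intervals:
        seq = genome[region.chrom][region.start : region.end]
        assert consensus in seq
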