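"""Synthetic study generator: complete pipeline inputs with known ground truth.

The generator emulates the statistical structure of a myoblast
differentiation study: a C2C12-like arm (growth medium GM plus a
differentiation time course DM12..DM96, 3 replicates each) and a
satellite-cell-like arm (donor ages W2..W12). It emits, per run:

* a transcript annotation (GTF) and random genome (FASTA + chrom.sizes);
* NB-distributed counts with planted DE (|log2FC| = 2 between GM and DM60
  by default), planted co-expression modules carrying TF hubs, and a
  planted rise-then-fall satellite profile for the up-regulated lncRNA set;
* ATAC/H3K4me1/H3K4me3/TF peak BEDs and ATAC signal bedGraphs encoding
  planted TSS chromatin categories and condition-dependent signal gain;
* foreground/background motif regions with consensus instances embedded in
  the genome sequence;
* gene sets (GMT), a TF list, and a truth table for every planted feature.

Identical config + seed give byte-identical files. Per-stage generators
draw from seeds derived from the global seed, so stages are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chromstate
from .genomic_io import (
    CountMatrix,
    GeneSet,
    GenomicInterval,
    PeakSet,
    SignalTrack,
    Transcript,
    ValidationError,
    write_bed,
    write_bedgraph,
    write_counts,
    write_fasta,
    write_gmt,
    write_gtf,
)
from .motifenr import default_pwms

C2C12_CONDITIONS = ("GM", "DM12", "DM24", "DM48", "DM60", "DM96")
SATELLITE_CONDITIONS = ("W2", "W4", "W6", "W8", "W10", "W12")

#: rise-then-fall log2 offsets over satellite ages for the planted "up"
#: lncRNA set (peak at W6, decline below baseline by W12); the "down" set
#: is mirrored. Scaled by half the planted effect size.
SATELLITE_SHAPE = {"W2": 0.0, "W4": 1.5, "W6": 2.0, "W8": 0.5, "W10": -1.0, "W12": -2.0}

TF_NAMES = (
    "MyoD", "MyoG", "Mef2c", "Heyl", "Usf1", "Max",
    "Cebpb", "Myf5", "Pax7", "Six1", "Runx1", "Atf3",
)


@dataclass
class SimulationConfig:
    seed: int = 1
    n_chromosomes: int = 2
    chrom_length: int = 5_000_000
    n_lnc: int = 300
    n_pcg: int = 1500  # includes the TF features
    replicates: int = 3
    dispersion: float = 0.1
    de_fraction: float = 0.3
    de_log2fc: float = 2.0
    base_log2_mean_range: tuple[float, float] = (5.0, 9.0)
    n_modules: int = 5
    module_size: int = 50
    module_lnc: int = 15
    module_tfs: int = 2
    target_module_r: float = 0.8
    # categories among DE (and non-DE) lncRNAs; remainder is closed
    category_proportions: dict = field(
        default_factory=lambda: {
            chromstate.CATEGORY_K4ME3: 0.28,
            chromstate.CATEGORY_K4ME1: 0.25,
            chromstate.CATEGORY_ATAC_ONLY: 0.11,
        }
    )
    atac_gain_log2: float = 2.0  # DM60/GM ATAC signal log2 ratio for up lncRNAs
    signal_base_log2: float = 6.0
    signal_spread_log2: float = 1.5
    signal_noise_log2: float = 0.2
    myod_myog_both: float = 0.7  # joint binding probability at marked lncRNAs
    myod_myog_only_each: float = 0.08
    other_tf_bind_prob: float = 0.3
    motif_fg_rate: float = 0.6
    motif_bg_rate: float = 0.05
    motif_region_width: int = 400

    def __post_init__(self) -> None:
        if self.n_lnc < 0 or min(self.n_pcg, self.replicates, self.n_chromosomes) <= 0:
            raise ValidationError("size parameters must be positive (n_lnc may be 0)")
        if sum(self.category_proportions.values()) > 1.0 + 1e-9:
            raise ValidationError("category proportions must sum to <= 1")

    @property
    def conditions(self) -> tuple[str, ...]:
        return C2C12_CONDITIONS + SATELLITE_CONDITIONS

    @property
    def n_features(self) -> int:
        return self.n_lnc + self.n_pcg


@dataclass
class TruthTable:
    """Per-feature planted ground truth, consistent with the emitted files."""

    features: pd.DataFrame  # de_status, true_log2fc, module, category, bound_tfs
    insertions: pd.DataFrame  # motif insertions: region, motif, offset

    def de_ids(self, status: str, biotype: str | None = None) -> list[str]:
        f = self.features
        mask = f["de_status"] == status
        if biotype:
            mask &= f["biotype"] == biotype
        return list(f.index[mask])


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# annotation + genome
# ---------------------------------------------------------------------------


def simulate_annotation(
    config: SimulationConfig,
) -> tuple[list[Transcript], dict[str, int], dict[str, str]]:
    """Place non-overlapping transcripts on random-sequence chromosomes.

    Transcripts sit on a fixed-stride grid with >= 5 kb spacing so every
    TSS window, extended peak region and motif region of one transcript is
    disjoint from its neighbours'. Raises when the genome cannot hold all
    transcripts at that spacing.
    """
    rng = _rng(config, 1)
    margin = 6000
    per_chrom = int(np.ceil(config.n_features / config.n_chromosomes))
    stride = (config.chrom_length - 2 * margin) // per_chrom
    if stride < 5000:
        raise ValidationError(
            f"overcrowded chromosome: stride {stride} bp < 5 kb minimum spacing"
        )
    ids = [f"lnc_{i:04d}" for i in range(config.n_lnc)]
    n_plain_pcg = config.n_pcg - len(TF_NAMES)
    ids += list(TF_NAMES) + [f"pcg_{i:04d}" for i in range(n_plain_pcg)]
    biotypes = ["lncRNA"] * config.n_lnc + ["protein_coding"] * config.n_pcg
    order = rng.permutation(config.n_features)

    transcripts = []
    for slot, feat_idx in enumerate(order):
        chrom = f"chr{slot % config.n_chromosomes + 1}"
        grid = margin + (slot // config.n_chromosomes) * stride + stride // 2
        tss = int(grid + rng.integers(-300, 301))
        length = int(rng.integers(500, 3001))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            iv = GenomicInterval(chrom, tss, tss + length, "+")
        else:
            iv = GenomicInterval(chrom, tss - length + 1, tss + 1, "-")
        fid = ids[feat_idx]
        transcripts.append(
            Transcript(id=fid, gene_id=f"{fid}_g", biotype=biotypes[feat_idx], interval=iv)
        )
    transcripts.sort(key=lambda t: (t.interval.chrom, t.interval.start))

    chrom_lengths = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)
    }
    genome = {}
    for chrom, length in chrom_lengths.items():
        codes = rng.integers(0, 4, size=length)
        genome[chrom] = (
            np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode()
        )
    return transcripts, chrom_lengths, genome


# ---------------------------------------------------------------------------
# truth assignment
# ---------------------------------------------------------------------------


def assign_truth(config: SimulationConfig) -> TruthTable:
    """Plant DE status, module membership and chromatin categories.

    Modules alternate direction (+, +, -, -, 0, ...); the four core
    myogenic TFs land in the two up-regulated modules. Categories are
    assigned to every lncRNA (DE and non-DE alike) from the configured
    proportions, remainder closed.
    """
    rng = _rng(config, 2)
    lnc_ids = [f"lnc_{i:04d}" for i in range(config.n_lnc)]
    plain_pcg = [f"pcg_{i:04d}" for i in range(config.n_pcg - len(TF_NAMES))]

    directions = [(+1, +1, -1, -1, 0)[m % 5] for m in range(config.n_modules)]
    n_mod_pcg = config.module_size - config.module_lnc - config.module_tfs

    lnc_pool = list(rng.permutation(lnc_ids))
    pcg_pool = list(rng.permutation(plain_pcg))
    tf_pool = list(TF_NAMES)  # core TFs first, deterministic order

    module_of: dict[str, int] = {}
    direction_of: dict[str, int] = {}
    for m in range(config.n_modules):
        members = (
            [tf_pool.pop(0) for _ in range(min(config.module_tfs, len(tf_pool)))]
            + [lnc_pool.pop() for _ in range(config.module_lnc)]
            + [pcg_pool.pop() for _ in range(n_mod_pcg)]
        )
        for fid in members:
            module_of[fid] = m
            direction_of[fid] = directions[m]

    # extra (non-module) DE features to reach the global DE fraction
    n_de_target = int(round(config.de_fraction * config.n_features))
    n_module_de = sum(1 for fid, d in direction_of.items() if d != 0)
    n_extra = max(0, n_de_target - n_module_de)
    # keep lncRNA share of extras proportional to the lncRNA share overall
    n_extra_lnc = int(round(n_extra * config.n_lnc / config.n_features))
    extra_lnc = [lnc_pool.pop() for _ in range(min(n_extra_lnc, len(lnc_pool)))]
    extra_pcg = [pcg_pool.pop() for _ in range(min(n_extra - len(extra_lnc), len(pcg_pool)))]
    for i, fid in enumerate(extra_lnc + extra_pcg):
        direction_of[fid] = 1 if i % 2 == 0 else -1

    rows = []
    cat_names = list(config.category_proportions)
    cat_probs = list(config.category_proportions.values())
    cat_probs.append(max(0.0, 1.0 - sum(cat_probs)))
    cat_names.append(chromstate.CATEGORY_CLOSED)
    all_ids = lnc_ids + list(TF_NAMES) + plain_pcg
    for fid in all_ids:
        biotype = "lncRNA" if fid.startswith("lnc_") else "protein_coding"
        d = direction_of.get(fid, 0)
        category = ""
        if biotype == "lncRNA":
            category = cat_names[rng.choice(len(cat_names), p=cat_probs)]
        rows.append(
            {
                "feature_id": fid,
                "biotype": biotype,
                "is_tf": fid in TF_NAMES,
                "de_status": {1: "up", -1: "down", 0: "not_de"}[d],
                "true_log2fc": d * config.de_log2fc,
                "module": module_of.get(fid, -1),
                "category": category,
            }
        )
    features = pd.DataFrame(rows).set_index("feature_id")
    return TruthTable(features=features, insertions=pd.DataFrame())


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def _log2_noise_var(base_log2_mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Approximate per-sample variance of log2 counts under NB(mu, phi)."""
    mu = 2.0**base_log2_mean
    return (1.0 / mu + dispersion) / np.log(2.0) ** 2


def simulate_counts(config: SimulationConfig, truth: TruthTable) -> CountMatrix:
    """NB counts for both arms with planted DE, modules and satellite shape.

    log2 mean = base + Delta * ramp0(cond)         (C2C12 DE mean trajectory)
              + q(cond)                            (module / feature profile)
              + (Delta/2) * shape(age) + jitter    (satellite arm, lncRNA sets
                                                    and core TFs only)

    ramp0 is the fixed mean differentiation trajectory, anchored at 0 in GM
    and 1 at DM60 so the GM-vs-DM60 contrast recovers Delta exactly in
    expectation. q lives in the "free" condition subspace (zero at GM and
    DM60, so it never leaks into the DE contrast): module members share a
    module profile, non-module DE features get individual ones. The five
    module profiles form a regular simplex in that subspace — pairwise
    correlation exactly -1/4 regardless of the seed (only the simplex
    orientation is random) — so no two planted modules can collide into one
    cluster of the unsigned network by an unlucky draw. Profile variances
    are solved so the expected within-module Pearson correlation of log2
    expression across the C2C12 arm hits the configured target.
    """
    rng = _rng(config, 3)
    feats = truth.features
    ids = list(feats.index)
    n = len(ids)
    base = rng.uniform(*config.base_log2_mean_range, size=n)
    noise_var = _log2_noise_var(base, config.dispersion)
    direction = feats["true_log2fc"].to_numpy() / config.de_log2fc

    ramp0 = {"GM": 0.0, "DM12": 0.5, "DM24": 0.5, "DM48": 0.5, "DM60": 1.0, "DM96": 0.5}
    ramp0_var = float(np.var([ramp0[c] for c in C2C12_CONDITIONS]))
    free_conds = [c for c in C2C12_CONDITIONS if c not in ("GM", "DM60")]
    n_free = len(free_conds)

    def profile_from_coords(coords: np.ndarray, var_target: float) -> dict[str, float]:
        """Free-subspace profile with a prescribed variance across conditions."""
        q = dict.fromkeys(C2C12_CONDITIONS, 0.0)
        for c, value in zip(free_conds, coords):
            q[c] = float(value)
        vals = np.array([q[c] for c in C2C12_CONDITIONS])
        scale = np.sqrt(var_target / max(np.var(vals), 1e-12))
        return {c: float(v * scale) for c, v in q.items()}

    # regular-simplex module directions in the free subspace: n_modules unit
    # vectors with pairwise inner product -1/(n_modules - 1), randomly rotated
    n_mod = config.n_modules
    if n_mod > n_free + 1:
        raise ValidationError(
            f"{n_mod} modules need >= {n_mod - 1} free conditions, have {n_free}"
        )
    centred = np.eye(n_mod) - 1.0 / n_mod
    u, s, _ = np.linalg.svd(centred)
    simplex = (u[:, : n_mod - 1] * s[: n_mod - 1])  # (n_mod, n_mod-1)
    simplex /= np.linalg.norm(simplex, axis=1, keepdims=True)
    q_rot, _ = np.linalg.qr(rng.standard_normal((n_free, n_free)))
    directions_free = simplex @ q_rot[: n_mod - 1, :]  # (n_mod, n_free)

    module_profile = {}
    module_delta = {}
    for m in range(n_mod):
        members = feats.index[feats["module"] == m]
        v_bar = float(np.mean(noise_var[[ids.index(f) for f in members]]))
        d_m = float(feats.loc[members, "true_log2fc"].iloc[0])
        module_delta[m] = d_m
        target_cov = config.target_module_r / (1 - config.target_module_r) * v_bar
        v_q = max(target_cov - d_m**2 * ramp0_var, 0.05)
        module_profile[m] = profile_from_coords(directions_free[m], v_q)

    # individual profiles for DE features outside any module
    v_bar_all = float(np.mean(noise_var))
    v_q_single = max(
        config.target_module_r / (1 - config.target_module_r) * v_bar_all
        - config.de_log2fc**2 * ramp0_var,
        0.05,
    )
    feature_profile: dict[str, dict[str, float]] = {}
    for i, fid in enumerate(ids):
        m = feats.at[fid, "module"]
        if m >= 0:
            feature_profile[fid] = module_profile[m]
        elif direction[i] != 0:
            coords = rng.standard_normal(n_free)
            coords /= np.linalg.norm(coords)
            feature_profile[fid] = profile_from_coords(coords, v_q_single)

    shape = SATELLITE_SHAPE
    sat_core_tfs = {"MyoD", "MyoG", "Mef2c", "Heyl"}

    samples = []
    cond_of = {}
    for cond in config.conditions:
        for r in range(1, config.replicates + 1):
            sid = f"{cond}_{r}"
            samples.append(sid)
            cond_of[sid] = cond

    log2mu = np.zeros((n, len(samples)))
    sat_jitter = {
        fid: {c: float(rng.normal(0, 0.3)) for c in SATELLITE_CONDITIONS}
        for fid in ids
        if feats.at[fid, "de_status"] != "not_de" and feats.at[fid, "biotype"] == "lncRNA"
    }
    for j, sid in enumerate(samples):
        cond = cond_of[sid]
        for i, fid in enumerate(ids):
            v = base[i]
            if cond in C2C12_CONDITIONS:
                if direction[i] != 0:
                    v += direction[i] * config.de_log2fc * ramp0[cond]
                if fid in feature_profile:
                    v += feature_profile[fid][cond]
            else:
                if fid in sat_jitter:
                    v += direction[i] * (config.de_log2fc / 2.0) * shape[cond]
                    v += sat_jitter[fid][cond]
                elif fid in sat_core_tfs:
                    v += shape[cond]
            log2mu[i, j] = v

    mu = 2.0**log2mu
    if config.dispersion <= 0:
        counts = rng.poisson(mu)
    else:
        shape_nb = 1.0 / config.dispersion
        counts = rng.negative_binomial(shape_nb, shape_nb / (shape_nb + mu))
    df = pd.DataFrame(counts.astype(np.int64), index=ids, columns=samples)
    return CountMatrix(
        counts=df,
        biotypes=feats["biotype"].copy(),
        conditions=pd.Series(cond_of),
    )


# ---------------------------------------------------------------------------
# chromatin
# ---------------------------------------------------------------------------


@dataclass
class ChromatinFiles:
    atac: dict[str, PeakSet]  # condition -> peaks (GM, DM)
    signal: dict[str, SignalTrack]
    k4me1: PeakSet
    k4me3: PeakSet
    tf_peaks: dict[str, PeakSet]
    peak_center: dict[str, int]  # transcript -> planted ATAC peak center


def simulate_chromatin(
    config: SimulationConfig,
    truth: TruthTable,
    transcripts: list[Transcript],
) -> ChromatinFiles:
    """Peaks and signal encoding the planted categories and signal gain.

    Every open-category lncRNA gets an ATAC peak overlapping its TSS in
    both conditions; marked categories additionally get an H3K4me1 or
    H3K4me3 peak within 1 kb of the ATAC peak (inside the extended
    region). Closed lncRNAs get nothing. The DM ATAC signal is GM times
    2^(+/- gain) for up/down lncRNAs, with lognormal noise. TF peaks land
    on the ATAC peak of marked lncRNAs; MyoD and MyoG are placed jointly
    with a configurable co-localisation rate, and the truth table records
    every bound TF.
    """
    rng = _rng(config, 4)
    feats = truth.features
    tx_by_id = {t.id: t for t in transcripts}

    atac = {"GM": [], "DM": []}
    signal = {"GM": [], "DM": []}
    k4me1, k4me3 = [], []
    tf_peaks: dict[str, list[GenomicInterval]] = {tf: [] for tf in TF_NAMES}
    bound_tfs: dict[str, list[str]] = {}
    peak_center: dict[str, int] = {}

    other_tfs = [tf for tf in TF_NAMES if tf not in ("MyoD", "MyoG")]
    for fid in feats.index[feats["biotype"] == "lncRNA"]:
        category = feats.at[fid, "category"]
        if category == chromstate.CATEGORY_CLOSED:
            continue
        tx = tx_by_id[fid]
        chrom = tx.interval.chrom
        center = int(tx.tss + rng.integers(-200, 201))
        half = int(rng.integers(150, 301))
        peak_center[fid] = center
        for cond in ("GM", "DM"):
            js, je = int(rng.integers(-30, 31)), int(rng.integers(-30, 31))
            atac[cond].append(GenomicInterval(chrom, center - half + js, center + half + je))
        gm_log2 = config.signal_base_log2 + rng.normal(0, config.signal_spread_log2)
        d = {"up": 1, "down": -1, "not_de": 0}[feats.at[fid, "de_status"]]
        dm_log2 = (
            gm_log2
            + d * config.atac_gain_log2
            + rng.normal(0, config.signal_noise_log2)
        )
        signal["GM"].append((atac["GM"][-1], float(2.0**gm_log2)))
        signal["DM"].append((atac["DM"][-1], float(2.0**dm_log2)))

        if category in (chromstate.CATEGORY_K4ME1, chromstate.CATEGORY_K4ME3):
            offset = int(rng.integers(100, 700))
            side = 1 if rng.random() < 0.5 else -1
            edge = center + side * (half + offset)
            mark_iv = GenomicInterval(chrom, edge - 150, edge + 150)
            (k4me1 if category == chromstate.CATEGORY_K4ME1 else k4me3).append(mark_iv)

            # TF binding on the ATAC peak itself
            bound = []
            u = rng.random()
            if u < config.myod_myog_both:
                bound += ["MyoD", "MyoG"]
            elif u < config.myod_myog_both + config.myod_myog_only_each:
                bound.append("MyoD")
            elif u < config.myod_myog_both + 2 * config.myod_myog_only_each:
                bound.append("MyoG")
            for tf in other_tfs:
                if rng.random() < config.other_tf_bind_prob:
                    bound.append(tf)
            for tf in bound:
                shift = int(rng.integers(-100, 101))
                tf_peaks[tf].append(
                    GenomicInterval(chrom, center - 100 + shift, center + 100 + shift)
                )
            bound_tfs[fid] = bound

    truth.features["bound_tfs"] = [
        ",".join(sorted(bound_tfs.get(fid, []))) for fid in feats.index
    ]
    return ChromatinFiles(
        atac={c: PeakSet(name=f"ATAC_{c}", intervals=ivs) for c, ivs in atac.items()},
        signal={
            c: SignalTrack.from_records(f"ATAC_signal_{c}", recs)
            for c, recs in signal.items()
        },
        k4me1=PeakSet(name="H3K4me1", intervals=k4me1),
        k4me3=PeakSet(name="H3K4me3", intervals=k4me3),
        tf_peaks={
            tf: PeakSet(name=tf, intervals=ivs) for tf, ivs in tf_peaks.items() if ivs
        },
        peak_center=peak_center,
    )


# ---------------------------------------------------------------------------
# motif regions
# ---------------------------------------------------------------------------


def simulate_motif_regions(
    config: SimulationConfig,
    truth: TruthTable,
    chromatin: ChromatinFiles,
    transcripts: list[Transcript],
    genome: dict[str, str],
) -> tuple[PeakSet, PeakSet, dict[str, str]]:
    """Foreground/background regions with embedded motif consensus instances.

    Foreground: fixed-width regions on the ATAC peak of open DE lncRNAs;
    background: same for open non-DE lncRNAs. MyoD (and, at 70% of the
    rate, MyoG) consensus sequences are spliced into foreground regions at
    ``motif_fg_rate`` and into background at ``motif_bg_rate``. Returns the
    region sets and the mutated genome; insertions are logged in the truth.
    """
    rng = _rng(config, 5)
    feats = truth.features
    pwms = {p.name: p for p in default_pwms()}
    myod, myog = pwms["MyoD"], pwms["MyoG"]
    half = config.motif_region_width // 2

    seqs = {chrom: bytearray(seq.encode()) for chrom, seq in genome.items()}
    tx_by_id = {t.id: t for t in transcripts}
    fg, bg = [], []
    insertions = []

    def splice(region: GenomicInterval, pwm, rid: str) -> None:
        consensus = pwm.consensus()
        off = int(rng.integers(0, region.width - pwm.width))
        seqs[region.chrom][region.start + off : region.start + off + pwm.width] = (
            consensus.encode()
        )
        insertions.append({"region": rid, "motif": pwm.name, "offset": off})

    for fid, center in sorted(chromatin.peak_center.items()):
        chrom = tx_by_id[fid].interval.chrom
        region = GenomicInterval(chrom, center - half, center + half)
        is_de = feats.at[fid, "de_status"] != "not_de"
        (fg if is_de else bg).append(region)
        fg_rate, bg_rate = config.motif_fg_rate, config.motif_bg_rate
        rate = fg_rate if is_de else bg_rate
        if rng.random() < rate:
            splice(region, myod, fid)
        if rng.random() < rate * 0.7:
            splice(region, myog, fid)

    truth.insertions = pd.DataFrame(insertions, columns=["region", "motif", "offset"])
    mutated = {chrom: bytes(b).decode() for chrom, b in seqs.items()}
    return (
        PeakSet(name="fg", intervals=fg),
        PeakSet(name="bg", intervals=bg),
        mutated,
    )


# ---------------------------------------------------------------------------
# truth self-check and full study emission
# ---------------------------------------------------------------------------


def validate_truth(
    config: SimulationConfig,
    truth: TruthTable,
    transcripts: list[Transcript],
    chromatin: ChromatinFiles,
    chrom_lengths: dict[str, int],
) -> None:
    """Cross-validate the truth table against the generated chromatin files.

    Checks, for every lncRNA: open categories have an ATAC peak overlapping
    the TSS window and closed ones do not; marked categories have their
    mark peak overlapping the extended ATAC region; every recorded bound TF
    has a peak on the extended region. Raises ValidationError on any
    inconsistency.
    """
    atac_union = chromstate.merge_peaks(list(chromatin.atac.values()), name="union")
    atac_ext = chromstate.extend_peaks(atac_union, chrom_lengths)
    tx_by_id = {t.id: t for t in transcripts}
    feats = truth.features
    for fid in feats.index[feats["biotype"] == "lncRNA"]:
        tx = tx_by_id[fid]
        window = chromstate.make_tss_window(tx, chrom_lengths[tx.interval.chrom])
        category = chromstate.classify_category(
            window, atac_union, chromatin.k4me1, chromatin.k4me3, atac_extended=atac_ext
        )
        if category != feats.at[fid, "category"]:
            raise ValidationError(
                f"truth inconsistency for {fid}: planted {feats.at[fid, 'category']}, "
                f"files imply {category}"
            )
        planted = set(feats.at[fid, "bound_tfs"].split(",")) - {""}
        regions = chromstate.window_atac_regions(window, atac_ext)
        for tf in planted:
            by = chromatin.tf_peaks[tf].by_chrom()
            if not any(chromstate._overlapping(r, by) for r in regions):
                raise ValidationError(f"bound TF {tf} of {fid} has no overlapping peak")


def generate_study(
    config: SimulationConfig, outdir: str | Path
) -> tuple[dict[str, Path], TruthTable]:
    """Generate and write the complete synthetic study; return paths + truth."""
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)

    transcripts, chrom_lengths, genome = simulate_annotation(config)
    truth = assign_truth(config)
    matrix = simulate_counts(config, truth)
    chromatin = simulate_chromatin(config, truth, transcripts)
    fg, bg, genome = simulate_motif_regions(
        config, truth, chromatin, transcripts, genome
    )
    validate_truth(config, truth, transcripts, chromatin, chrom_lengths)

    paths: dict[str, Path] = {}

    def _p(key: str, name: str) -> Path:
        paths[key] = outdir / name
        return paths[key]

    write_gtf(transcripts, _p("gtf", "ann.gtf"))
    write_fasta(genome, _p("fasta", "genome.fa"))
    with open(_p("chrom_sizes", "chrom.sizes"), "w") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    write_counts(matrix, _p("counts", "counts.tsv"))
    for cond in ("GM", "DM"):
        write_bed(chromatin.atac[cond], _p(f"atac_{cond.lower()}", f"atac_{cond.lower()}.bed"))
        write_bedgraph(
            chromatin.signal[cond],
            _p(f"signal_{cond.lower()}", f"atac_{cond.lower()}.bedgraph"),
        )
    write_bed(chromatin.k4me1, _p("k4me1", "k4me1.bed"))
    write_bed(chromatin.k4me3, _p("k4me3", "k4me3.bed"))
    for tf, ps in sorted(chromatin.tf_peaks.items()):
        write_bed(ps, _p(f"tf_{tf}", f"tf_{tf}.bed"))
    write_bed(fg, _p("fg", "fg.bed"))
    write_bed(bg, _p("bg", "bg.bed"))

    up = truth.de_ids("up", "lncRNA")
    down = truth.de_ids("down", "lncRNA")
    write_gmt(
        [
            GeneSet("up_lncRNAs", frozenset(up), "lncRNAs up-regulated GM->DM60"),
            GeneSet("down_lncRNAs", frozenset(down), "lncRNAs down-regulated GM->DM60"),
        ],
        _p("gmt", "sets.gmt"),
    )
    with open(_p("tf_list", "tf_list.txt"), "w") as fh:
        fh.write("\n".join(TF_NAMES) + "\n")

    truth.features.to_csv(_p("truth_features", "truth/features.tsv"), sep="\t")
    truth.insertions.to_csv(
        _p("truth_insertions", "truth/insertions.tsv"), sep="\t", index=False
    )
    return paths, truth
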