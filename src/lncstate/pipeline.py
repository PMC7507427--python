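"""End-to-end orchestration: config validation, staged runs, run manifest.

A run proceeds simulate -> de -> chromstate -> network -> gsea -> motif.
Every stage records input hashes, a parameter snapshot and output hashes in
the manifest, so a rerun with identical inputs and parameters can be
checked for drift hash-by-hash. All thresholds live in the config with the
study defaults: TSS window 2500/1500, peak flank 1000, alpha 0.05,
|log2FC| >= 1, CPM >= 1, network weight > 0.05 with p < 0.01.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chromstate, coexpr, diffexpr, gsea, motifenr, synthio
from .genomic_io import (
    ValidationError,
    read_bed,
    read_bedgraph,
    read_counts,
    read_fasta,
    read_gmt,
    read_gtf,
)

logger = logging.getLogger("lncstate.pipeline")


@dataclass
class PipelineConfig:
    outdir: str = "results"
    datadir: str = "data"
    seed: int = 1
    # thresholds (study defaults)
    alpha: float = 0.05
    lfc: float = 1.0
    cpm_min: float = 1.0
    weight_min: float = 0.05
    p_max: float = 0.01
    upstream: int = 2500
    downstream: int = 1500
    flank: int = 1000
    nperm: int = 1000
    pearson_alpha: float = 0.05
    min_module_size: int = 20
    cut_height: float = 0.9
    power: float | str = 6.0
    cond_a: str = "GM"
    cond_b: str = "DM60"
    gsea_contrasts: tuple = (("W2", "W6"), ("W2", "W12"))
    simulate: bool = True

    def __post_init__(self) -> None:
        for key in ("alpha", "lfc", "cpm_min", "weight_min", "p_max",
                    "upstream", "downstream", "flank", "nperm"):
            if not (getattr(self, key) > 0):
                raise ValidationError(f"config key {key!r} must be positive")


def validate_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; unknown keys are rejected, missing ones defaulted."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    known = {f.name: f for f in fields(PipelineConfig)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    for key, value in raw.items():
        want = known[key].type
        if key in ("gsea_contrasts",):
            raw[key] = tuple(tuple(pair) for pair in value)
        elif isinstance(value, bool) and want not in ("bool",):
            raise ValidationError(f"config key {key!r}: unexpected boolean")
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ValidationError(str(exc)) from exc


def serialize_config(config: PipelineConfig, path: str | Path) -> None:
    data = asdict(config)
    data["gsea_contrasts"] = [list(p) for p in config.gsea_contrasts]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    rows: list[dict] = field(default_factory=list)

    def record(
        self,
        stage: str,
        inputs: list[Path],
        outputs: list[Path],
        params: dict,
    ) -> None:
        self.rows.append(
            {
                "stage": stage,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "params": ";".join(f"{k}={v}" for k, v in sorted(params.items())),
                "input_hashes": ";".join(
                    f"{p.name}={_sha256(p)}" for p in inputs if p.exists()
                ),
                "output_hashes": ";".join(
                    f"{p.name}={_sha256(p)}" for p in outputs if p.exists()
                ),
            }
        )

    def write(self, path: str | Path) -> None:
        pd.DataFrame(self.rows).to_csv(path, sep="\t", index=False)

    def output_hashes(self) -> dict[str, str]:
        out = {}
        for row in self.rows:
            for item in row["output_hashes"].split(";"):
                if item:
                    name, digest = item.split("=", 1)
                    out[f"{row['stage']}/{name}"] = digest
        return out


# ---------------------------------------------------------------------------
# staged pipeline
# ---------------------------------------------------------------------------


def _preflight(paths: dict[str, Path]) -> None:
    missing = [str(p) for p in paths.values() if not p.exists()]
    if missing:
        raise ValidationError("missing input file(s): " + ", ".join(sorted(missing)))


def run_all(config: PipelineConfig) -> RunManifest:
    """Run every stage in dependency order; returns the populated manifest.

    With ``simulate=True`` the synthetic study is generated first under
    ``datadir``; otherwise the files are expected to exist there already.
    """
    outdir = Path(config.outdir)
    datadir = Path(config.datadir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    t0 = time.time()

    def log_stage(stage: str) -> None:
        logger.info(
            "stage=%s seed=%d elapsed=%.1fs params=%s",
            stage, config.seed, time.time() - t0,
            {k: v for k, v in asdict(config).items() if not isinstance(v, str)},
        )

    # -- simulate ----------------------------------------------------------
    sim_config = synthio.SimulationConfig(seed=config.seed)
    if config.simulate:
        log_stage("simulate")
        paths, _truth = synthio.generate_study(sim_config, datadir)
        manifest.record(
            "simulate", [], sorted(paths.values()), {"seed": config.seed}
        )
    else:
        paths = {
            key: datadir / name
            for key, name in [
                ("gtf", "ann.gtf"), ("fasta", "genome.fa"),
                ("chrom_sizes", "chrom.sizes"), ("counts", "counts.tsv"),
                ("atac_gm", "atac_gm.bed"), ("atac_dm", "atac_dm.bed"),
                ("signal_gm", "atac_gm.bedgraph"), ("signal_dm", "atac_dm.bedgraph"),
                ("k4me1", "k4me1.bed"), ("k4me3", "k4me3.bed"),
                ("fg", "fg.bed"), ("bg", "bg.bed"),
                ("gmt", "sets.gmt"), ("tf_list", "tf_list.txt"),
            ]
        }
        for bed in sorted(datadir.glob("tf_*.bed")):
            paths[bed.stem] = bed
        _preflight(paths)

    # -- differential expression ------------------------------------------
    log_stage("de")
    matrix = read_counts(paths["counts"])
    de_results = diffexpr.de_test(
        matrix, config.cond_a, config.cond_b,
        alpha=config.alpha, lfc_threshold=config.lfc,
    )
    cpm = diffexpr.compute_cpm(matrix.counts)
    de_results = diffexpr.filter_low_expression(
        de_results, cpm, matrix, config.cond_a, config.cond_b, cpm_min=config.cpm_min
    )
    de_frame = diffexpr.results_to_frame(de_results)
    de_path = outdir / "de.tsv"
    de_frame.to_csv(de_path, sep="\t")
    manifest.record(
        "de", [paths["counts"]], [de_path],
        {"alpha": config.alpha, "lfc": config.lfc, "cpm_min": config.cpm_min,
         "contrast": f"{config.cond_a}:{config.cond_b}"},
    )

    # -- chromatin state ----------------------------------------------------
    log_stage("chromstate")
    transcripts = {t.id: t for t in read_gtf(paths["gtf"])}
    chrom_lengths = {}
    with open(paths["chrom_sizes"]) as fh:
        for line in fh:
            chrom, length = line.split("\t")
            chrom_lengths[chrom] = int(length)
    tf_peaks = {
        key.removeprefix("tf_"): read_bed(path, name=key.removeprefix("tf_"))
        for key, path in paths.items()
        if key.startswith("tf_") and key != "tf_list"
    }
    lnc_status = {
        fid: de_frame.at[fid, "status"]
        for fid in de_frame.index
        if de_frame.at[fid, "biotype"] == "lncRNA"
    }
    chrom_frame = chromstate.annotate_chromatin_states(
        transcripts=transcripts,
        de_status=lnc_status,
        atac_gm=read_bed(paths["atac_gm"], name="ATAC_GM"),
        atac_dm=read_bed(paths["atac_dm"], name="ATAC_DM"),
        signal_gm=read_bedgraph(paths["signal_gm"]),
        signal_dm=read_bedgraph(paths["signal_dm"]),
        k4me1=read_bed(paths["k4me1"], name="H3K4me1"),
        k4me3=read_bed(paths["k4me3"], name="H3K4me3"),
        tf_peaks=tf_peaks,
        chrom_lengths=chrom_lengths,
        upstream=config.upstream,
        downstream=config.downstream,
        flank=config.flank,
    )
    chrom_path = outdir / "chromstate.tsv"
    chrom_frame.to_csv(chrom_path, sep="\t")
    manifest.record(
        "chromstate",
        [paths["gtf"], paths["atac_gm"], paths["atac_dm"]],
        [chrom_path],
        {"upstream": config.upstream, "downstream": config.downstream,
         "flank": config.flank, "seed": config.seed},
    )

    # -- co-expression network --------------------------------------------
    log_stage("network")
    de_ids = list(de_frame.index[de_frame["status"] != "not_de"])
    c2c12_samples = [
        s for s in matrix.sample_ids
        if matrix.conditions[s] in synthio.C2C12_CONDITIONS
    ]
    expr = coexpr.log_cpm(cpm.loc[de_ids, c2c12_samples])
    expr = expr.loc[expr.std(axis=1) > 0]
    power = (
        coexpr.pick_soft_threshold(expr)
        if config.power == "auto"
        else float(config.power)
    )
    edges = coexpr.weighted_edges(expr, power)
    tom = coexpr.tom_similarity(coexpr.adjacency(expr, power))
    modules = coexpr.detect_modules(
        tom, list(expr.index),
        min_module_size=config.min_module_size, cut_height=config.cut_height,
    )
    tf_ids = {
        line.strip() for line in open(paths["tf_list"]) if line.strip()
    }
    lnc_ids = {f for f in expr.index if matrix.biotypes[f] == "lncRNA"}
    tf_lnc = coexpr.build_tf_lnc_network(
        edges, tf_ids & set(expr.index), lnc_ids,
        weight_min=config.weight_min, p_max=config.p_max,
    )
    pearson = coexpr.pearson_edges(expr, expr, alpha=config.pearson_alpha)
    edges_path = outdir / "edges.tsv"
    modules_path = outdir / "modules.tsv"
    edges["module_a"] = modules.reindex(edges["a"]).to_numpy()
    edges["module_b"] = modules.reindex(edges["b"]).to_numpy()
    tf_lnc.to_csv(edges_path, sep="\t", index=False)
    modules.rename("module").to_csv(modules_path, sep="\t", index_label="feature_id")
    wgcna_pairs = {
        (a, b)
        for a, b, w in zip(edges["a"], edges["b"], edges["weight"])
        if w > config.weight_min
    }
    pearson_pairs = {(e.feature_a, e.feature_b) for e in pearson}
    overlap = coexpr.network_overlap(wgcna_pairs, pearson_pairs)
    overlap_path = outdir / "network_overlap.tsv"
    pd.Series(overlap).to_csv(overlap_path, sep="\t", header=False)
    manifest.record(
        "network", [paths["counts"], de_path], [edges_path, modules_path, overlap_path],
        {"power": power, "weight_min": config.weight_min, "p_max": config.p_max,
         "min_module_size": config.min_module_size, "cut_height": config.cut_height},
    )

    # -- GSEA ---------------------------------------------------------------
    log_stage("gsea")
    gene_sets = read_gmt(paths["gmt"])
    gsea_rows = []
    for cond_a, cond_b in config.gsea_contrasts:
        frame = gsea.gsea_prerank(
            matrix, cond_a, cond_b, gene_sets,
            n_perm=config.nperm, seed=config.seed,
        )
        frame.insert(0, "contrast", f"{cond_b}_vs_{cond_a}")
        gsea_rows.append(frame)
    gsea_frame = pd.concat(gsea_rows)
    gsea_path = outdir / "gsea.tsv"
    gsea_frame.to_csv(gsea_path, sep="\t")
    manifest.record(
        "gsea", [paths["counts"], paths["gmt"]], [gsea_path],
        {"nperm": config.nperm, "seed": config.seed},
    )

    # -- motif enrichment ---------------------------------------------------
    log_stage("motif")
    genome = read_fasta(paths["fasta"])
    enrich_frame = motifenr.enrich(
        read_bed(paths["fg"]).intervals,
        read_bed(paths["bg"]).intervals,
        genome,
        motifenr.default_pwms(),
    )
    motif_path = outdir / "motif_enrichment.tsv"
    enrich_frame.to_csv(motif_path, sep="\t")
    manifest.record(
        "motif", [paths["fg"], paths["bg"], paths["fasta"]], [motif_path], {}
    )

    manifest.write(outdir / "manifest.tsv")
    serialize_config(config, outdir / "config_used.yaml")
    logger.info("pipeline complete in %.1fs", time.time() - t0)
    return manifest
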