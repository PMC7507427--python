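"""Differential expression between two conditions from a count matrix.

The engine is a negative-binomial Wald test on the difference of log2 CPM
means, with method-of-moments dispersion. It is a deliberately transparent
stand-in for the edgeR-style exact test typically run on such data: the
downstream integration only consumes per-feature log2FC, p and an up/down
call, all of which this test provides from first principles.

A feature is called DE when BOTH |log2FC| >= lfc_threshold AND p < alpha
(defaults 1 and 0.05), and labelled up or down by the sign of log2FC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import CountMatrix, ValidationError

#: pseudocount (in CPM units) added inside the log2 fold-change
PSEUDOCOUNT_CPM = 1.0


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    biotype: str
    mean_cpm_a: float
    mean_cpm_b: float
    log2fc: float
    p_value: float
    status: str  # up | down | not_de


@dataclass
class NBModel:
    """Per-feature NB parameters: mean per condition, dispersion phi.

    Variance model: var = mu + phi * mu^2 (phi = 0 recovers Poisson).
    """

    mean_a: pd.Series
    mean_b: pd.Series
    dispersion: pd.Series

    def __post_init__(self) -> None:
        if (self.dispersion < 0).any():
            raise ValidationError("negative dispersion")


def compute_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: counts / column-sum * 1e6, per sample."""
    libsize = counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValidationError(f"zero library size for sample(s) {list(zero.index)}")
    return counts / libsize * 1e6


def estimate_dispersion(
    counts: pd.DataFrame, condition_labels: pd.Series
) -> pd.Series:
    """Method-of-moments NB dispersion per feature, pooled across conditions.

    phi_hat = max(0, (s^2 - xbar) / xbar^2) within each condition, combined
    as a df-weighted mean over conditions with >= 2 replicates.
    """
    conds = condition_labels.loc[counts.columns]
    per_cond = []
    weights = []
    for cond in conds.unique():
        cols = conds.index[conds == cond]
        if len(cols) < 2:
            continue
        block = counts[cols].to_numpy(dtype=float)
        xbar = block.mean(axis=1)
        s2 = block.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi = np.where(xbar > 0, (s2 - xbar) / np.maximum(xbar, 1e-12) ** 2, 0.0)
        per_cond.append(np.maximum(phi, 0.0))
        weights.append(len(cols) - 1)
    if not per_cond:
        raise ValidationError("dispersion needs >= 2 replicates in some condition")
    pooled = np.average(np.vstack(per_cond), axis=0, weights=weights)
    return pd.Series(pooled, index=counts.index)


def _log2_mean_se(
    cpm_block: np.ndarray, count_block: np.ndarray, phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean log2(CPM + c) and its delta-method standard error under NB noise.

    Var(count) = mu + phi mu^2 per replicate; the CPM scale factor cancels
    in the coefficient of variation, so on the log2 scale
    Var(log2 cpm_bar) ~= (1/mu + phi) / (n ln(2)^2) with mu the count mean,
    damped by the pseudocount via the ratio cpm_bar/(cpm_bar + c).
    """
    n = cpm_block.shape[1]
    cpm_bar = cpm_block.mean(axis=1)
    mu = np.maximum(count_block.mean(axis=1), 1e-8)
    shrink = cpm_bar / (cpm_bar + PSEUDOCOUNT_CPM)
    var_log = (1.0 / mu + phi) / (n * np.log(2) ** 2) * shrink**2
    return np.log2(cpm_bar + PSEUDOCOUNT_CPM), np.sqrt(var_log)


def de_test(
    matrix: CountMatrix,
    cond_a: str,
    cond_b: str,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    fdr: bool = False,
) -> list[DEResult]:
    """Call DE features between two conditions (B vs A).

    log2FC = log2((mean_cpm_B + c) / (mean_cpm_A + c)) with c = 1 CPM;
    p is two-sided from a Wald statistic on the log2-mean difference,
    referenced to a t distribution with (nA - 1) + (nB - 1) df. With
    ``fdr=True`` the alpha cut is applied to Benjamini-Hochberg-adjusted
    p-values instead of raw ones (off by default).
    """
    samples_a = matrix.samples_for(cond_a)
    samples_b = matrix.samples_for(cond_b)
    cpm = compute_cpm(matrix.counts)
    phi = estimate_dispersion(
        matrix.counts[samples_a + samples_b], matrix.conditions
    ).to_numpy()

    ca = matrix.counts[samples_a].to_numpy(dtype=float)
    cb = matrix.counts[samples_b].to_numpy(dtype=float)
    pa = cpm[samples_a].to_numpy()
    pb = cpm[samples_b].to_numpy()

    la, se_a = _log2_mean_se(pa, ca, phi)
    lb, se_b = _log2_mean_se(pb, cb, phi)
    log2fc = lb - la
    se = np.sqrt(se_a**2 + se_b**2)
    df = (len(samples_a) - 1) + (len(samples_b) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, log2fc / np.maximum(se, 1e-300), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_stat), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    p_for_call = _bh_adjust(p) if fdr else p
    results = []
    for i, fid in enumerate(matrix.feature_ids):
        if p_for_call[i] < alpha and log2fc[i] >= lfc_threshold:
            status = "up"
        elif p_for_call[i] < alpha and log2fc[i] <= -lfc_threshold:
            status = "down"
        else:
            status = "not_de"
        results.append(
            DEResult(
                feature_id=fid,
                biotype=matrix.biotypes[fid],
                mean_cpm_a=float(pa[i].mean()),
                mean_cpm_b=float(pb[i].mean()),
                log2fc=float(log2fc[i]),
                p_value=float(p[i]),
                status=status,
            )
        )
    return results


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def filter_low_expression(
    results: list[DEResult],
    cpm: pd.DataFrame,
    matrix: CountMatrix,
    cond_a: str,
    cond_b: str,
    cpm_min: float = 1.0,
) -> list[DEResult]:
    """Drop features whose mean CPM is below ``cpm_min`` in BOTH conditions."""
    mean_a = cpm[matrix.samples_for(cond_a)].mean(axis=1)
    mean_b = cpm[matrix.samples_for(cond_b)].mean(axis=1)
    keep = (mean_a >= cpm_min) | (mean_b >= cpm_min)
    return [r for r in results if keep.get(r.feature_id, False)]


def results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "biotype": [r.biotype for r in results],
            "mean_cpm_a": [r.mean_cpm_a for r in results],
            "mean_cpm_b": [r.mean_cpm_b for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p_value for r in results],
            "status": [r.status for r in results],
        }
    ).set_index("feature_id")
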