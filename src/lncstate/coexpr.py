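"""TF-lncRNA co-expression network: weighted-network modules plus Pearson edges.

Two complementary views of co-expression over log2(CPM+1) profiles:

* a weighted (WGCNA-style, unsigned) network — soft-thresholded adjacency
  a_ij = |r_ij|^beta with beta chosen by the scale-free topology criterion,
  topological overlap TOM_ij as the edge weight, and modules from
  average-linkage clustering of 1 - TOM with a static height cut;
* plain Pearson edge testing with the closed-form t-distribution p-value.

The TF-lncRNA network keeps edges with one TF endpoint and one lncRNA
endpoint passing weight > 0.05 and p < 0.01 (defaults). The two views are
compared by the fraction of weighted-network pairs also found by Pearson.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .genomic_io import ValidationError

#: module labels in WGCNA colour style, assigned by descending module size;
#: unassigned features get "grey"
MODULE_COLOURS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
)
UNASSIGNED = "grey"


@dataclass(frozen=True)
class CorrelationEdge:
    """Undirected edge; endpoints stored in canonical (a < b) order."""

    feature_a: str
    feature_b: str
    r: float
    p_value: float
    wgcna_weight: float = np.nan

    def __post_init__(self) -> None:
        if self.feature_a >= self.feature_b:
            raise ValidationError("edge endpoints must be in canonical a < b order")


@dataclass
class WGCNAParams:
    power: float = 6.0
    min_module_size: int = 20
    cut_height: float = 0.9
    network_type: str = "unsigned"

    def __post_init__(self) -> None:
        if self.power < 1:
            raise ValidationError("soft-threshold power must be >= 1")


def log_cpm(cpm: pd.DataFrame) -> pd.DataFrame:
    return np.log2(cpm + 1.0)


# ---------------------------------------------------------------------------
# Pearson edges
# ---------------------------------------------------------------------------


def pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from t = r sqrt((n-2)/(1-r^2)), df = n - 2."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    return np.minimum(2.0 * stats.t.sf(np.abs(t), n - 2), 1.0)


def pearson_edges(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    alpha: float = 0.05,
) -> list[CorrelationEdge]:
    """Significant Pearson edges between two feature blocks (features x samples).

    Zero-variance features are excluded (they have no defined correlation).
    Needs >= 3 shared samples. Self-pairs and duplicate ids are skipped.
    """
    shared = [s for s in expr_a.columns if s in set(expr_b.columns)]
    n = len(shared)
    if n < 3:
        raise ValidationError(f"need >= 3 shared samples, got {n}")
    a = expr_a[shared]
    b = expr_b[shared]
    a = a.loc[a.std(axis=1) > 0]
    b = b.loc[b.std(axis=1) > 0]
    if a.empty or b.empty:
        return []
    az = _standardize(a.to_numpy())
    bz = _standardize(b.to_numpy())
    r = az @ bz.T / n
    p = pearson_p(r, n)
    edges = []
    for i, fa in enumerate(a.index):
        for j, fb in enumerate(b.index):
            if fa == fb:
                continue
            lo, hi = sorted((fa, fb))
            if p[i, j] < alpha:
                edges.append(
                    CorrelationEdge(lo, hi, float(r[i, j]), float(p[i, j]))
                )
    # deduplicate symmetric pairs when the two blocks overlap
    seen: dict[tuple[str, str], CorrelationEdge] = {}
    for e in edges:
        seen[(e.feature_a, e.feature_b)] = e
    return sorted(seen.values(), key=lambda e: (e.feature_a, e.feature_b))


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return (x - mu) / sd


# ---------------------------------------------------------------------------
# weighted network
# ---------------------------------------------------------------------------


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Feature-feature Pearson correlation (features x samples input)."""
    z = _standardize(expr.to_numpy())
    r = z @ z.T / expr.shape[1]
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(np.clip(r, -1, 1), index=expr.index, columns=expr.index)


def adjacency(expr: pd.DataFrame, power: float) -> pd.DataFrame:
    """Unsigned soft-thresholded adjacency a_ij = |r_ij|^beta, diagonal 1."""
    r = correlation_matrix(expr)
    return np.abs(r) ** power


def tom_similarity(adj: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj and k_i = sum_u a_iu, all sums over u != i, j
    (diagonal treated as 0). TOM diagonal is defined as 1.
    """
    a = adj.to_numpy(dtype=float) if isinstance(adj, pd.DataFrame) else np.asarray(adj, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a  # l_ij includes u = i, j terms only via a_ii = a_jj = 0, so none
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) ~ log10 k regression over binned connectivity."""
    a = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r**2)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16),
    r2_target: float = 0.8,
) -> float:
    """Smallest power whose scale-free fit R^2 reaches the target.

    Falls back to the power with maximal R^2 when none reaches it.
    """
    if not candidate_powers:
        raise ValidationError("candidate_powers must be nonempty")
    if expr.shape[0] < 10:
        raise ValidationError("soft-threshold selection needs >= 10 features")
    r = np.abs(correlation_matrix(expr).to_numpy())
    best_power, best_r2 = candidate_powers[0], -1.0
    for beta in candidate_powers:
        r2 = scale_free_fit(r**beta)
        if r2 >= r2_target:
            return float(beta)
        if r2 > best_r2:
            best_power, best_r2 = beta, r2
    return float(best_power)


def detect_modules(
    tom: np.ndarray,
    feature_ids: list[str],
    min_module_size: int = 20,
    cut_height: float = 0.9,
) -> pd.Series:
    """Modules from average-linkage clustering of 1 - TOM, static height cut.

    Clusters smaller than ``min_module_size`` are unassigned ("grey").
    Labels are colour-style strings ordered by descending module size;
    deterministic for a fixed input.
    """
    tom = np.asarray(tom, dtype=float)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    # guard tiny negative asymmetries from float arithmetic
    dissim = np.maximum((dissim + dissim.T) / 2.0, 0.0)
    link = average(squareform(dissim, checks=False))
    raw = fcluster(link, t=cut_height, criterion="distance")
    labels = pd.Series(UNASSIGNED, index=pd.Index(feature_ids), dtype=object)
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_module_size]
    # order by (size desc, first-member position) for determinism under ties
    first_pos = {c: int(np.argmax(raw == c)) for c in kept}
    kept.sort(key=lambda c: (-sizes[c], first_pos[c]))
    for rank, cluster in enumerate(kept):
        colour = (
            MODULE_COLOURS[rank]
            if rank < len(MODULE_COLOURS)
            else f"module_{rank + 1}"
        )
        labels.iloc[np.nonzero(raw == cluster)[0]] = colour
    return labels


# ---------------------------------------------------------------------------
# network assembly and comparison
# ---------------------------------------------------------------------------


def weighted_edges(
    expr: pd.DataFrame, power: float, use_adjacency_weight: bool = False
) -> pd.DataFrame:
    """All pairwise edges with r, p (t-test) and weight (TOM by default,
    |r|^beta when ``use_adjacency_weight``). Returns a canonical-order frame."""
    n = expr.shape[1]
    r = correlation_matrix(expr).to_numpy()
    adj = np.abs(r) ** power
    weight = adj if use_adjacency_weight else tom_similarity(adj)
    p = pearson_p(r, n)
    ids = list(expr.index)
    iu, ju = np.triu_indices(len(ids), k=1)
    return pd.DataFrame(
        {
            "a": [min(ids[i], ids[j]) for i, j in zip(iu, ju)],
            "b": [max(ids[i], ids[j]) for i, j in zip(iu, ju)],
            "r": r[iu, ju],
            "p": p[iu, ju],
            "weight": weight[iu, ju],
        }
    )


def build_tf_lnc_network(
    edges: pd.DataFrame,
    tf_ids: set[str],
    lnc_ids: set[str],
    weight_min: float = 0.05,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Filter to TF-lncRNA edges with weight > weight_min and p < p_max."""
    if not tf_ids:
        raise ValidationError("tf_ids must be nonempty")
    is_tf_a = edges["a"].isin(tf_ids)
    is_tf_b = edges["b"].isin(tf_ids)
    is_lnc_a = edges["a"].isin(lnc_ids)
    is_lnc_b = edges["b"].isin(lnc_ids)
    cross = (is_tf_a & is_lnc_b) | (is_tf_b & is_lnc_a)
    keep = cross & (edges["weight"] > weight_min) & (edges["p"] < p_max)
    return edges.loc[keep].reset_index(drop=True)


def network_overlap(
    wgcna_pairs: set[tuple[str, str]], pearson_pairs: set[tuple[str, str]]
) -> dict[str, float]:
    """Fraction of weighted-network pairs confirmed by Pearson, plus Venn counts."""
    inter = wgcna_pairs & pearson_pairs
    return {
        "overlap_fraction": len(inter) / len(wgcna_pairs) if wgcna_pairs else 0.0,
        "wgcna_only": float(len(wgcna_pairs - pearson_pairs)),
        "pearson_only": float(len(pearson_pairs - wgcna_pairs)),
        "both": float(len(inter)),
    }
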