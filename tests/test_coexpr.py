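"""Co-expression network: Pearson edges, soft threshold, TOM, modules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncstate import coexpr
from lncstate.genomic_io import ValidationError


def frame(x: np.ndarray, prefix="f") -> pd.DataFrame:
    return pd.DataFrame(x, index=[f"{prefix}{i}" for i in range(x.shape[0])])


# ---------------------------------------------------------------------------
# Pearson edges
# ---------------------------------------------------------------------------


def test_perfect_linear_relations():
    x = np.arange(6.0)
    expr_a = frame(x[None, :], prefix="a")
    edges = coexpr.pearson_edges(expr_a, frame(2 * x[None, :] + 1, prefix="b"), alpha=1.1)
    assert edges[0].r == pytest.approx(1.0)
    edges = coexpr.pearson_edges(expr_a, frame(-x[None, :], prefix="b"), alpha=1.1)
    assert edges[0].r == pytest.approx(-1.0)


def test_pearson_p_matches_t_closed_form(rng):
    x = rng.normal(size=(1, 5))
    y = rng.normal(size=(1, 5))
    (edge,) = coexpr.pearson_edges(frame(x, "a"), frame(y, "b"), alpha=1.1)
    t = edge.r * np.sqrt(3 / (1 - edge.r**2))
    assert edge.p_value == pytest.approx(2 * stats.t.sf(abs(t), 3), abs=1e-10)


def test_pearson_needs_three_samples_and_drops_flat(rng):
    with pytest.raises(ValidationError, match="3"):
        coexpr.pearson_edges(frame(np.ones((2, 2))), frame(np.ones((2, 2))))
    flat = frame(np.vstack([np.ones(6), rng.normal(size=6)]))
    edges = coexpr.pearson_edges(flat, flat, alpha=1.1)
    assert all("f0" not in (e.feature_a, e.feature_b) for e in edges)


def test_pearson_r_invariant_to_affine_rescaling(rng):
    x = rng.normal(size=(4, 8))
    e1 = coexpr.pearson_edges(frame(x), frame(x), alpha=1.1)
    e2 = coexpr.pearson_edges(frame(3 * x + 7), frame(x), alpha=1.1)
    np.testing.assert_allclose([e.r for e in e1], [e.r for e in e2], atol=1e-12)


# ---------------------------------------------------------------------------
# soft threshold
# ---------------------------------------------------------------------------


def hub_expression(rng, n=200, samples=60):
    """Latent-factor data with power-law-ish loadings -> near-scale-free net."""
    w = rng.uniform(0.05, 1.0, n) ** 2.5
    f = rng.standard_normal(samples)
    x = np.sqrt(w)[:, None] * f[None, :] + np.sqrt(1 - w)[:, None] * rng.standard_normal(
        (n, samples)
    )
    return frame(x)


def test_soft_threshold_reaches_scale_free_fit():
    rng = np.random.default_rng(5)
    expr = hub_expression(rng)
    beta = coexpr.pick_soft_threshold(expr)
    r = np.abs(coexpr.correlation_matrix(expr).to_numpy())
    assert coexpr.scale_free_fit(r**beta) >= 0.8


def test_soft_threshold_smallest_passing_power_wins():
    rng = np.random.default_rng(5)
    expr = hub_expression(rng)
    # both powers pass the criterion here; the smaller must be returned
    r = np.abs(coexpr.correlation_matrix(expr).to_numpy())
    assert coexpr.scale_free_fit(r**2) >= 0.8
    assert coexpr.scale_free_fit(r**3) >= 0.8
    assert coexpr.pick_soft_threshold(expr, candidate_powers=(2, 3)) == 2.0


def test_soft_threshold_needs_features():
    with pytest.raises(ValidationError, match="10"):
        coexpr.pick_soft_threshold(frame(np.random.default_rng(0).normal(size=(5, 8))))


# ---------------------------------------------------------------------------
# adjacency and TOM
# ---------------------------------------------------------------------------


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            out[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return out


def test_tom_two_node_hand_value():
    a = np.array([[1.0, 0.5], [0.5, 1.0]])
    tom = coexpr.tom_similarity(a)
    assert tom[0, 1] == pytest.approx(0.5)
    assert tom[0, 0] == 1.0


def test_identical_expression_gives_unit_network(rng):
    x = np.tile(rng.normal(size=8), (5, 1))
    adj = coexpr.adjacency(frame(x), power=6)
    np.testing.assert_allclose(adj.to_numpy(), 1.0)
    np.testing.assert_allclose(coexpr.tom_similarity(adj), 1.0)


@pytest.mark.parametrize("n", [12, 30])
def test_tom_matches_cubic_brute_force(rng, n):
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    np.testing.assert_allclose(
        coexpr.tom_similarity(a), brute_force_tom(np.where(np.eye(n), 0, a)), atol=1e-12
    )


def test_tom_rejects_non_square():
    with pytest.raises(ValidationError, match="square"):
        coexpr.tom_similarity(np.ones((3, 4)))


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------


def block_expression(rng, n_blocks=2, size=30, samples=40, r=0.95):
    rows = []
    for _ in range(n_blocks):
        f = rng.standard_normal(samples)
        load = np.sqrt(r)
        rows.append(
            load * f[None, :]
            + np.sqrt(1 - r) * rng.standard_normal((size, samples))
        )
    return frame(np.vstack(rows))


def test_two_planted_blocks_found(rng):
    expr = block_expression(rng)
    tom = coexpr.tom_similarity(coexpr.adjacency(expr, 6))
    labels = coexpr.detect_modules(tom, list(expr.index), min_module_size=10)
    non_grey = labels[labels != coexpr.UNASSIGNED]
    assert non_grey.nunique() == 2
    # blocks map one-to-one onto labels
    assert labels.iloc[:30].nunique() == 1 and labels.iloc[30:].nunique() == 1


def test_all_identical_features_form_one_module(rng):
    x = np.tile(rng.normal(size=10), (25, 1))
    tom = coexpr.tom_similarity(coexpr.adjacency(frame(x), 6))
    labels = coexpr.detect_modules(tom, [f"f{i}" for i in range(25)], min_module_size=5)
    assert labels.nunique() == 1 and labels.iloc[0] == "turquoise"


def test_five_planted_modules_recovered(rng):
    from sklearn.metrics import adjusted_rand_score

    expr = block_expression(rng, n_blocks=5, size=50, samples=30, r=0.8)
    tom = coexpr.tom_similarity(coexpr.adjacency(expr, 6))
    labels = coexpr.detect_modules(tom, list(expr.index))
    truth = np.repeat(np.arange(5), 50)
    assert adjusted_rand_score(truth, labels) >= 0.8


# ---------------------------------------------------------------------------
# TF-lncRNA network and overlap
# ---------------------------------------------------------------------------


def random_edge_table(rng, n=200):
    names = [f"g{i}" for i in range(30)]
    a = rng.choice(names, n)
    b = rng.choice(names, n)
    keep = a != b
    a, b = a[keep], b[keep]
    lo = np.where(a < b, a, b)
    hi = np.where(a < b, b, a)
    return pd.DataFrame(
        {
            "a": lo, "b": hi,
            "r": rng.uniform(-1, 1, keep.sum()),
            "p": rng.uniform(0, 1, keep.sum()),
            "weight": rng.uniform(0, 1, keep.sum()),
        }
    )


def test_tf_lnc_filter_thresholds_and_oracle(rng):
    edges = random_edge_table(rng)
    tf_ids = {f"g{i}" for i in range(10)}
    lnc_ids = {f"g{i}" for i in range(10, 30)}
    out = coexpr.build_tf_lnc_network(edges, tf_ids, lnc_ids, 0.05, 0.01)
    for _, row in edges.iterrows():
        cross = (row["a"] in tf_ids and row["b"] in lnc_ids) or (
            row["b"] in tf_ids and row["a"] in lnc_ids
        )
        expected = cross and row["weight"] > 0.05 and row["p"] < 0.01
        present = (
            ((out["a"] == row["a"]) & (out["b"] == row["b"]))
            .any()
        )
        assert present == expected
    # monotone in the weight threshold
    n_loose = len(coexpr.build_tf_lnc_network(edges, tf_ids, lnc_ids, 0.05, 0.5))
    n_tight = len(coexpr.build_tf_lnc_network(edges, tf_ids, lnc_ids, 0.5, 0.5))
    assert n_tight <= n_loose
    with pytest.raises(ValidationError):
        coexpr.build_tf_lnc_network(edges, set(), lnc_ids)


def test_network_overlap_set_algebra(rng):
    assert coexpr.network_overlap({("a", "b")}, {("a", "b")})["overlap_fraction"] == 1.0
    assert coexpr.network_overlap({("a", "b")}, {("c", "d")})["overlap_fraction"] == 0.0
    pool = [(f"x{i}", f"y{i}") for i in range(50)]
    wg = {pool[i] for i in rng.choice(50, 20, replace=False)}
    pe = {pool[i] for i in rng.choice(50, 25, replace=False)}
    out = coexpr.network_overlap(wg, pe)
    assert out["both"] == len(wg & pe)
    assert out["wgcna_only"] == len(wg - pe)
    assert out["pearson_only"] == len(pe - wg)
    assert out["overlap_fraction"] == pytest.approx(len(wg & pe) / len(wg))
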