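"""Marker panel, SNN dendrogram, trimmed mean, consensus walk, projection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster import hierarchy

from atlaswalk import (
    CorrelationTable,
    ClusterTree,
    GeneratorConfig,
    balance_conditions,
    build_cluster_tree,
    consensus_walk,
    correlate_cells,
    make_reference_atlas,
    normalize_expression,
    pairwise_marker_panel,
    project_labels,
    simulate_cells,
    trimmed_mean,
)
from atlaswalk.consensus import MarkerPanel
from conftest import make_adata


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def sort_and_slice_mean(values, trim):
    v = sorted(values)
    cut = math.floor(trim * len(v))
    kept = v[cut: len(v) - cut]
    return sum(kept) / len(kept)


def brute_force_walk(tree, corr_df, patience, trim):
    """Naive reimplementation of the cut/assign/patience loop."""
    n = len(corr_df)
    types = sorted(corr_df.columns)
    prev, score = None, 0
    for k in range(1, n + patience + 1):
        part = tree.cut(k)
        labels = [None] * n
        for c in set(part.tolist()):
            members = [i for i in range(n) if part[i] == c]
            best, best_val = None, -np.inf
            for t in types:
                vals = [corr_df.iloc[i][t] for i in members
                        if np.isfinite(corr_df.iloc[i][t])]
                val = sort_and_slice_mean(vals, trim) if vals else -np.inf
                if val > best_val:
                    best, best_val = t, val
            for i in members:
                labels[i] = best
        if labels == prev:
            score += 1
        else:
            score = 0
        prev = labels
        if score >= patience:
            return labels
    raise AssertionError("brute-force walk did not terminate")


def random_tree(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    Z = hierarchy.linkage(pts, method="average")
    return ClusterTree(linkage=Z, cell_ids=pd.Index([f"c{i}" for i in range(n)]))


# ---------------------------------------------------------------------------
# trimmed mean
# ---------------------------------------------------------------------------

def test_trimmed_mean_examples():
    assert trimmed_mean([1, 2, 3, 4], 0.25) == pytest.approx(2.5)
    assert trimmed_mean([7.0] * 9, 0.3) == pytest.approx(7.0)
    assert trimmed_mean([1, 5, 9], 0.0) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        trimmed_mean([], 0.25)
    with pytest.raises(ValueError):
        trimmed_mean([1, 2], 0.5)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    values=st.lists(st.floats(-100, 100), min_size=1, max_size=40),
    trim=st.floats(0, 0.49),
)
def test_trimmed_mean_matches_sort_and_slice(values, trim):
    assert trimmed_mean(values, trim) == pytest.approx(
        sort_and_slice_mean(values, trim), abs=1e-9
    )


# ---------------------------------------------------------------------------
# marker panel
# ---------------------------------------------------------------------------

def planted_marker_data(seed=0):
    """Two types, each with 5 exclusive marker genes on a flat background."""
    rng = np.random.default_rng(seed)
    n_per, n_genes = 30, 40
    X = rng.poisson(2.0, size=(2 * n_per, n_genes)).astype(float)
    markers_a = [f"g{j}" for j in range(5)]
    markers_b = [f"g{j}" for j in range(5, 10)]
    X[:n_per, 0:5] += 50
    X[n_per:, 5:10] += 50
    labels = pd.Series(
        ["A"] * n_per + ["B"] * n_per, index=[f"c{i}" for i in range(2 * n_per)]
    )
    return make_adata(X), labels, markers_a + markers_b


def test_panel_recovers_planted_markers():
    adata, labels, markers = planted_marker_data()
    panel = pairwise_marker_panel(adata, labels, top_k=30)
    assert set(markers) <= set(panel.genes)
    assert len(panel.genes) <= 30  # single pair
    assert set(panel.provenance.columns) == {"gene", "type_a", "type_b", "rank"}


def test_panel_union_bound_three_types():
    rng = np.random.default_rng(1)
    X = rng.poisson(3.0, size=(90, 50)).astype(float)
    labels = pd.Series(["A"] * 30 + ["B"] * 30 + ["C"] * 30,
                       index=[f"c{i}" for i in range(90)])
    panel = pairwise_marker_panel(make_adata(X), labels, top_k=10)
    assert len(panel.genes) <= 3 * 10


def test_panel_requires_two_types_and_warns_on_tiny_type():
    adata, labels, _ = planted_marker_data()
    with pytest.raises(ValueError):
        pairwise_marker_panel(adata, labels[labels == "A"])
    labels3 = labels.copy()
    labels3.iloc[:2] = "C"  # 2-cell type: every pair with C is skipped
    with pytest.warns(UserWarning, match="skipped"):
        pairwise_marker_panel(adata, labels3, top_k=10)


# ---------------------------------------------------------------------------
# cluster tree
# ---------------------------------------------------------------------------

def test_tree_root_and_leaf_cuts():
    adata, labels, markers = planted_marker_data()
    tree = build_cluster_tree(adata, MarkerPanel(genes=markers), n_neighbors=10)
    n = adata.n_obs
    assert len(set(tree.cut(1))) == 1
    assert len(set(tree.cut(n))) == n
    # nestedness: cut(k+1) refines cut(k)
    for k in (2, 5, 9):
        fine, coarse = tree.cut(k + 1), tree.cut(k)
        mapping = {}
        for f, c in zip(fine, coarse):
            assert mapping.setdefault(f, c) == c


def test_tree_separates_planted_clouds():
    adata, labels, markers = planted_marker_data()
    tree = build_cluster_tree(adata, MarkerPanel(genes=markers), n_neighbors=10)
    two = tree.cut(2)
    assert len(set(two)) == 2
    assert pd.Series(two).groupby(labels.to_numpy()).nunique().eq(1).all()


def test_tree_clamps_neighbors_with_warning():
    adata, _, markers = planted_marker_data()
    small = adata[:5].copy()
    with pytest.warns(UserWarning, match="clamped"):
        build_cluster_tree(small, MarkerPanel(genes=markers), n_neighbors=50)


# ---------------------------------------------------------------------------
# consensus walk
# ---------------------------------------------------------------------------

def test_single_type_stops_after_patience_plus_one():
    n, patience = 6, 4
    tree = random_tree(n, seed=0)
    corr = CorrelationTable(pd.DataFrame(
        {"only": np.linspace(0.2, 0.9, n)}, index=tree.cell_ids
    ))
    labels = consensus_walk(tree, corr, patience=patience,
                            max_iterations=patience + 1)
    assert (labels["label"] == "only").all()


def test_patience_one_stops_at_first_repeat():
    tree = random_tree(5, seed=1)
    corr = CorrelationTable(pd.DataFrame(
        {"x": [0.9] * 5, "y": [0.1] * 5}, index=tree.cell_ids
    ))
    labels = consensus_walk(tree, corr, patience=1, max_iterations=2)
    assert (labels["label"] == "x").all()


def test_walk_matches_brute_force_on_small_datasets():
    rng = np.random.default_rng(3)
    for trial in range(25):
        n = int(rng.integers(2, 13))
        n_types = int(rng.integers(1, 5))
        tree = random_tree(n, seed=100 + trial)
        corr_df = pd.DataFrame(
            rng.uniform(-1, 1, size=(n, n_types)),
            columns=[f"t{j}" for j in range(n_types)],
            index=tree.cell_ids,
        )
        patience = int(rng.integers(1, 5))
        expected = brute_force_walk(tree, corr_df, patience, 0.25)
        got = consensus_walk(tree, CorrelationTable(corr_df), patience=patience,
                             max_iterations=n + patience)
        assert list(got["label"]) == expected, f"trial {trial}"


def test_walk_terminates_within_bound():
    # adversarial: every type column identical, labels settle immediately;
    # and random tables settle within n_cells + patience
    rng = np.random.default_rng(9)
    for trial in range(10):
        n = int(rng.integers(2, 12))
        tree = random_tree(n, seed=200 + trial)
        corr_df = pd.DataFrame(
            rng.uniform(-1, 1, size=(n, 3)), columns=list("abc"),
            index=tree.cell_ids,
        )
        consensus_walk(tree, CorrelationTable(corr_df), patience=3,
                       max_iterations=n + 3)  # must not raise


def test_walk_recovers_truth_on_separated_types():
    cfg = GeneratorConfig(seed=5, n_types=2, n_genes=120, n_cells_per_type=80,
                          doublet_rate=0.0, dropout_rate=0.0)
    atlas = make_reference_atlas(cfg)
    counts, truth = simulate_cells(atlas, cfg)
    norm = normalize_expression(counts)
    corr = correlate_cells(norm, atlas)
    panel = pairwise_marker_panel(norm, truth.true_labels)
    tree = build_cluster_tree(norm, panel)
    labels = consensus_walk(tree, corr, patience=5)
    assert (labels["label"] == truth.true_labels).all()
    assert (labels["provenance"] == "sketch").all()


def test_walk_requires_full_coverage():
    tree = random_tree(4, seed=2)
    corr = CorrelationTable(pd.DataFrame({"t": [0.5]}, index=["c0"]))
    with pytest.raises(ValueError, match="cover"):
        consensus_walk(tree, corr)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def test_projection_keeps_sketch_labels_and_copies_coincident_points():
    adata, labels, markers = planted_marker_data()
    sketch_ids = labels.index[::2]
    sketch_labels = pd.DataFrame(
        {"label": labels.loc[sketch_ids], "provenance": "sketch"}
    )
    out = project_labels(sketch_labels, adata, MarkerPanel(genes=markers),
                         k_neighbors=1)
    assert (out.loc[sketch_ids, "provenance"] == "sketch").all()
    assert (out.loc[sketch_ids, "label"] == labels.loc[sketch_ids]).all()
    others = labels.index.difference(sketch_ids)
    assert (out.loc[others, "provenance"] == "projected").all()


def test_projection_accuracy_on_planted_types():
    cfg = GeneratorConfig(seed=8, n_types=2, n_genes=120, n_cells_per_type=100,
                          doublet_rate=0.0)
    atlas = make_reference_atlas(cfg)
    counts, truth = simulate_cells(atlas, cfg)
    norm = normalize_expression(counts)
    sketch_ids = norm.obs_names[::2]  # 50% sketched
    sketch_labels = pd.DataFrame(
        {"label": truth.true_labels.loc[sketch_ids], "provenance": "sketch"}
    )
    panel = pairwise_marker_panel(norm, truth.true_labels)
    out = project_labels(sketch_labels, norm, panel)
    others = norm.obs_names.difference(sketch_ids)
    acc = (out.loc[others, "label"] == truth.true_labels.loc[others]).mean()
    assert acc >= 0.95


# ---------------------------------------------------------------------------
# condition balancing
# ---------------------------------------------------------------------------

def _label_frame(counts: dict) -> tuple[pd.Series, pd.Series]:
    labels, conds, idx = [], [], []
    i = 0
    for (t, c), n in counts.items():
        for _ in range(n):
            idx.append(f"cell{i}")
            labels.append(t)
            conds.append(c)
            i += 1
    index = pd.Index(idx)
    return pd.Series(labels, index=index), pd.Series(conds, index=index)


def test_balancing_takes_min_count_per_condition():
    labels, conds = _label_frame({("T", "A"): 2000, ("T", "B"): 1608})
    chosen = balance_conditions(labels, conds, ["T"], seed=0)
    sel = conds.loc[chosen]
    assert (sel == "A").sum() == 1608 and (sel == "B").sum() == 1608


def test_balancing_noop_on_equal_counts_and_min_arithmetic():
    labels, conds = _label_frame({("M", "A"): 10, ("M", "B"): 10})
    assert len(balance_conditions(labels, conds, ["M"], seed=0)) == 20
    labels, conds = _label_frame({("M", "A"): 10, ("M", "B"): 7})
    chosen = balance_conditions(labels, conds, ["M"], seed=0)
    assert len(chosen) == 14
    assert (conds.loc[chosen] == "A").sum() == 7


def test_balancing_errors_when_type_missing_in_a_condition():
    labels, conds = _label_frame({("T", "A"): 5, ("M", "A"): 3, ("M", "B"): 3})
    with pytest.raises(ValueError, match="'T'"):
        balance_conditions(labels, conds, ["T", "M"], seed=0)


def test_balancing_deterministic():
    labels, conds = _label_frame({("T", "A"): 50, ("T", "B"): 30})
    c1 = balance_conditions(labels, conds, ["T"], seed=4)
    c2 = balance_conditions(labels, conds, ["T"], seed=4)
    assert list(c1) == list(c2)
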