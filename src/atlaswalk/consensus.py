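"""Consensus cell-type annotation by iterative dendrogram cuts.

The per-cell atlas correlations are noisy; this module refines them using
the cells' neighbourhood structure. A marker panel is pooled from the top
differentially expressed genes of every pairwise comparison of the retained
types; the cells are embedded in PCA space of those panel genes and linked
into a dendrogram through a shared-nearest-neighbour (SNN) similarity. The
tree is then cut at 1, 2, 3, ... clusters; at each cut every cluster is
assigned the cell type with the maximal 25%-trimmed mean of its members'
correlations, and a consensus score counts how many consecutive cuts leave
the full label vector unchanged. The walk stops as soon as the score
reaches its patience (default 10); because the singleton cut is a fixed
point the walk always terminates within ``n_cells + patience`` iterations.
Labels of the sketched cells are finally projected to the whole dataset by
nearest-neighbour majority vote in the panel PCA space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import trim_mean as _scipy_trim_mean
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .atlas import CorrelationTable, make_label_set
from .scoring import wilcoxon_de

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# marker panel
# ---------------------------------------------------------------------------

@dataclass
class MarkerPanel:
    """Pooled top differentially expressed genes from all pairwise type tests."""

    genes: list[str]
    provenance: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene", "type_a", "type_b", "rank"]
        )
    )

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel genes must be unique")


def pairwise_marker_panel(
    normalized: ad.AnnData,
    labels: pd.Series,
    top_k: int = 30,
    min_frac: float = 0.05,
    min_cells: int = 3,
) -> MarkerPanel:
    """Union of the top ``top_k`` DEGs from each unordered pair of types.

    ``labels`` gives the per-cell type; cells labelled "ambiguous" are
    excluded. Genes are ranked per pair by ascending Wilcoxon p-value
    (ties: larger |log2FC| first, then gene name); a pair in which either
    type has fewer than ``min_cells`` cells is skipped with a warning.
    """
    labels = labels.reindex(normalized.obs_names)
    mask = labels.notna() & (labels != "ambiguous")
    types = sorted(labels[mask].unique())
    if len(types) < 2:
        raise ValueError("need at least 2 retained cell types for a marker panel")
    by_type = {t: normalized.obs_names[(labels == t).to_numpy()] for t in types}

    rows: list[tuple[str, str, str, int]] = []
    seen: dict[str, None] = {}
    for i, ta in enumerate(types):
        for tb in types[i + 1:]:
            if len(by_type[ta]) < min_cells or len(by_type[tb]) < min_cells:
                warnings.warn(
                    f"pair ({ta}, {tb}) skipped: fewer than {min_cells} cells",
                    stacklevel=2,
                )
                continue
            de = wilcoxon_de(normalized, by_type[ta], by_type[tb], min_frac=min_frac)
            de = de.assign(abs_fc=de["log2_fold_change"].abs()).sort_values(
                ["p_value", "abs_fc", "gene"], ascending=[True, False, True]
            )
            for rank, gene in enumerate(de["gene"].head(top_k), start=1):
                rows.append((gene, ta, tb, rank))
                seen.setdefault(gene)
    if not seen:
        raise ValueError("no marker genes found in any pairwise comparison")
    prov = pd.DataFrame(rows, columns=["gene", "type_a", "type_b", "rank"])
    logger.info(
        "marker panel: %d unique genes pooled from %d pairwise tests",
        len(seen), len(prov.groupby(["type_a", "type_b"])),
    )
    return MarkerPanel(genes=list(seen), provenance=prov)


# ---------------------------------------------------------------------------
# SNN dendrogram
# ---------------------------------------------------------------------------

@dataclass
class ClusterTree:
    """Agglomerative dendrogram over sketch cells with nested cuts."""

    linkage: np.ndarray
    cell_ids: pd.Index

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cut(self, k: int) -> np.ndarray:
        """Partition into ``min(k, n_cells)`` clusters (nested in k)."""
        if k < 1:
            raise ValueError("k must be >= 1")
        k = min(k, self.n_cells)
        if self.n_cells == 1:
            return np.zeros(1, dtype=int)
        return hierarchy.cut_tree(self.linkage, n_clusters=k).ravel()


def _panel_pca(
    normalized: ad.AnnData, panel_genes: list[str], n_pcs: int
) -> tuple[np.ndarray, PCA, list[str]]:
    genes = [g for g in panel_genes if g in set(normalized.var_names)]
    if not genes:
        raise ValueError("no panel genes present in the expression matrix")
    X = normalized[:, genes].X
    dense = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    n_comp = max(1, min(n_pcs, dense.shape[0] - 1, dense.shape[1]))
    pca = PCA(n_components=n_comp, svd_solver="full")
    emb = pca.fit_transform(dense)
    return emb, pca, genes


def build_cluster_tree(
    normalized: ad.AnnData,
    panel: MarkerPanel,
    n_neighbors: int = 20,
    n_pcs: int = 20,
    linkage_method: str = "average",
) -> ClusterTree:
    """SNN-similarity dendrogram of the cells in panel-gene PCA space.

    k-nearest neighbours (including self) are found in a PCA embedding of
    the panel genes; the shared-nearest-neighbour similarity of two cells is
    the Jaccard overlap of their neighbour sets, converted to a distance
    ``1 - J`` and agglomerated (average linkage by default).
    """
    if not panel.genes:
        raise ValueError("marker panel is empty")
    if normalized.n_obs < 2:
        raise ValueError("need at least 2 cells to build a tree")
    emb, _, _ = _panel_pca(normalized, panel.genes, n_pcs)
    n = emb.shape[0]
    k = n_neighbors
    if k > n:
        warnings.warn(
            f"n_neighbors={n_neighbors} exceeds the number of cells ({n}); clamped",
            stacklevel=2,
        )
        k = n
    nn = NearestNeighbors(n_neighbors=max(1, k - 1)).fit(emb)
    idx = nn.kneighbors(return_distance=False)  # self excluded by sklearn
    # neighbour sets include the cell itself
    rows = np.concatenate([np.repeat(np.arange(n), idx.shape[1]), np.arange(n)])
    cols = np.concatenate([idx.ravel(), np.arange(n)])
    adj = sp.csr_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n, n)
    )
    adj.sum_duplicates()
    adj.data[:] = 1.0
    inter = (adj @ adj.T).toarray()
    sizes = np.asarray(adj.sum(axis=1)).ravel()
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jaccard = np.where(union > 0, inter / union, 0.0)
    dist = 1.0 - jaccard
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    return ClusterTree(linkage=Z, cell_ids=pd.Index(normalized.obs_names))


# ---------------------------------------------------------------------------
# trimmed mean and the dendrogram walk
# ---------------------------------------------------------------------------

def trimmed_mean(values, trim: float = 0.25) -> float:
    """Mean after dropping ``floor(trim * n)`` values from each tail."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("trimmed_mean of empty input")
    if not 0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    return float(_scipy_trim_mean(values, trim))


def _cluster_type_scores(
    sub: np.ndarray, trim: float
) -> np.ndarray:
    """Trimmed mean per type column of a (members x types) correlation block.

    NaN correlations are ignored; a type with no finite value in the
    cluster scores -inf so it can never win the argmax.
    """
    n_types = sub.shape[1]
    out = np.full(n_types, -np.inf)
    for j in range(n_types):
        col = sub[:, j]
        col = col[np.isfinite(col)]
        if col.size:
            out[j] = _scipy_trim_mean(col, trim)
    return out


def consensus_walk(
    tree: ClusterTree,
    corr: CorrelationTable,
    patience: int = 10,
    trim: float = 0.25,
    max_iterations: int | None = None,
) -> pd.DataFrame:
    """Iterative cluster-level label assignment until consensus.

    For k = 1, 2, 3, ... the tree is cut into k clusters; within each
    cluster the trimmed mean of the member cells' correlations is computed
    per retained type, and every member receives the argmax type (ties to
    the lexicographically first name). If the full label vector equals the
    previous iteration's, the consensus score is incremented, otherwise it
    resets to 0; the walk stops when the score reaches ``patience`` and
    returns the final labels with provenance "sketch". Cuts beyond the
    singleton partition reuse it, so the walk is guaranteed to terminate.
    """
    if patience < 1:
        raise ValueError("patience must be >= 1")
    if not 0 <= trim < 0.5:
        raise ValueError("trim must lie in [0, 0.5)")
    if tree.cell_ids.difference(corr.table.index).size:
        raise ValueError("correlation table does not cover all sketch cells")
    table = corr.table.reindex(tree.cell_ids)
    vals = table.to_numpy(dtype=float)
    type_names = np.asarray(table.columns, dtype=object)
    n = tree.n_cells
    if max_iterations is None:
        max_iterations = n + patience + 1

    prev: np.ndarray | None = None
    score = 0
    for k in range(1, max_iterations + 1):
        part = tree.cut(k)
        labels = np.empty(n, dtype=object)
        for c in np.unique(part):
            members = part == c
            scores = _cluster_type_scores(vals[members], trim)
            labels[members] = type_names[int(np.argmax(scores))]
        if prev is not None and np.array_equal(labels, prev):
            score += 1
        else:
            score = 0
        prev = labels
        if score >= patience:
            logger.info("consensus reached at cut k=%d (patience %d)", k, patience)
            return make_label_set(
                pd.Series(labels, index=tree.cell_ids, name="label"), "sketch"
            )
    raise RuntimeError(
        f"consensus walk did not terminate within {max_iterations} iterations "
        f"(last consensus score {score}, n_cells {n})"
    )


# ---------------------------------------------------------------------------
# projection and condition balancing
# ---------------------------------------------------------------------------

def project_labels(
    sketch_labels: pd.DataFrame,
    normalized_full: ad.AnnData,
    panel: MarkerPanel,
    k_neighbors: int = 5,
    n_pcs: int = 20,
) -> pd.DataFrame:
    """Extend sketch labels to every cell by k-NN majority vote.

    A PCA of the panel genes is fitted on the sketch cells and the remaining
    cells are projected into it; each non-sketch cell takes the majority
    label among its ``k_neighbors`` nearest sketch cells, ties going to the
    label of the closest tied neighbour. Sketch cells keep their own labels;
    provenance records sketch vs projected.
    """
    sketch_ids = sketch_labels.index
    missing = sketch_ids.difference(normalized_full.obs_names)
    if missing.size:
        raise ValueError("sketch cells missing from the full matrix")
    genes = [g for g in panel.genes if g in set(normalized_full.var_names)]
    if not genes:
        raise ValueError("no panel genes present in the full matrix")
    X = normalized_full[:, genes].X
    dense = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    obs = pd.Index(normalized_full.obs_names)
    sketch_pos = obs.get_indexer(sketch_ids)
    other_mask = np.ones(len(obs), dtype=bool)
    other_mask[sketch_pos] = False

    n_comp = max(1, min(n_pcs, len(sketch_pos) - 1, dense.shape[1]))
    pca = PCA(n_components=n_comp, svd_solver="full")
    sk_emb = pca.fit_transform(dense[sketch_pos])
    k = k_neighbors
    if k > len(sketch_pos):
        warnings.warn(
            f"k_neighbors={k_neighbors} exceeds sketch size; clamped", stacklevel=2
        )
        k = len(sketch_pos)

    labels = pd.Series(index=obs, dtype=object, name="label")
    prov = pd.Series(index=obs, dtype=object, name="provenance")
    labels.loc[sketch_ids] = sketch_labels["label"].to_numpy()
    prov.loc[sketch_ids] = "sketch"

    if other_mask.any():
        q_emb = pca.transform(dense[other_mask])
        nn = NearestNeighbors(n_neighbors=k).fit(sk_emb)
        dists, nbrs = nn.kneighbors(q_emb)
        sk_lab = sketch_labels["label"].to_numpy(dtype=object)
        assigned = []
        for drow, nrow in zip(dists, nbrs):
            cand = sk_lab[nrow]
            uniq, cnt = np.unique(cand.astype(str), return_counts=True)
            best = uniq[cnt == cnt.max()]
            if len(best) == 1:
                assigned.append(best[0])
            else:
                # tie: take the tied label whose neighbour is closest
                order = np.argsort(drow, kind="stable")
                tied = set(best)
                pick = next(cand[i] for i in order if str(cand[i]) in tied)
                assigned.append(pick)
        labels.loc[obs[other_mask]] = assigned
        prov.loc[obs[other_mask]] = "projected"
    return pd.DataFrame({"label": labels, "provenance": prov})


def balance_conditions(
    labels: pd.DataFrame | pd.Series,
    conditions: pd.Series,
    target_types: list[str],
    seed: int,
) -> pd.Index:
    """Equalize per-type cell numbers across two (or more) conditions.

    For each target type, the minimum count over conditions is sampled
    without replacement from every condition, so no condition is
    over-represented in downstream differential tests. Deterministic for a
    given seed.
    """
    lab = labels["label"] if isinstance(labels, pd.DataFrame) else labels
    conditions = conditions.reindex(lab.index)
    rng = np.random.default_rng(seed)
    conds = sorted(conditions.dropna().unique())
    chosen: list[np.ndarray] = []
    for t in target_types:
        per_cond = {
            c: lab.index[(lab == t) & (conditions == c)].to_numpy() for c in conds
        }
        empty = [c for c, ids in per_cond.items() if len(ids) == 0]
        if empty:
            raise ValueError(
                f"cell type {t!r} absent in condition(s): {', '.join(map(str, empty))}"
            )
        n = min(len(ids) for ids in per_cond.values())
        for c in conds:
            ids = per_cond[c]
            take = ids if len(ids) == n else rng.choice(ids, size=n, replace=False)
            chosen.append(np.sort(take))
    return pd.Index(np.concatenate(chosen))
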