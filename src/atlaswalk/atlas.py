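"""Reference-atlas handling and per-cell correlation typing.

A reference atlas is a collection of (cell type, source, per-gene expression
profile) entries; the same cell type may appear under several sources. Each
cell of a query dataset is compared with every entry by Pearson correlation
over the shared gene support, the best entry per type is kept, and types
claiming fewer than a minimum fraction of the sketched cells are pruned,
with their cells labelled "ambiguous".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

AMBIGUOUS_LABEL = "ambiguous"

#: column names of a label table
LABEL_COLUMNS = ("label", "provenance")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ReferenceAtlas:
    """Expression profiles of annotated cell types.

    Parameters
    ----------
    type_names
        Cell-type name per entry; names may repeat across sources.
    sources
        Provenance label per entry (which atlas it came from).
    profiles
        ``(n_entries, n_genes)`` nonnegative expression matrix.
    gene_ids
        Gene identifiers shared by all profiles.
    """

    type_names: list[str]
    sources: list[str]
    profiles: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2:
            raise ValueError("profiles must be a 2-D entries x genes array")
        n_entries, n_genes = self.profiles.shape
        if len(self.type_names) != n_entries or len(self.sources) != n_entries:
            raise ValueError("type_names/sources length must match profiles rows")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length must match profiles columns")
        if np.any(self.profiles < 0):
            raise ValueError("atlas profiles must be nonnegative")

    @property
    def n_entries(self) -> int:
        return self.profiles.shape[0]

    def unique_types(self) -> list[str]:
        return sorted(set(self.type_names))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.profiles, columns=self.gene_ids)
        df.insert(0, "source", self.sources)
        df.insert(0, "type_name", self.type_names)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceAtlas":
        if not {"type_name", "source"} <= set(df.columns):
            raise ValueError("atlas table needs 'type_name' and 'source' columns")
        genes = [c for c in df.columns if c not in ("type_name", "source")]
        return cls(
            type_names=df["type_name"].astype(str).tolist(),
            sources=df["source"].astype(str).tolist(),
            profiles=df[genes].to_numpy(dtype=float),
            gene_ids=list(genes),
        )

    @classmethod
    def from_csv(cls, path) -> "ReferenceAtlas":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class HomologMap:
    """Directed gene-identifier translation (source organism -> target)."""

    pairs: pd.DataFrame  # columns: source_id, target_id

    def __post_init__(self) -> None:
        cols = list(self.pairs.columns[:2])
        self.pairs = (
            self.pairs.iloc[:, :2]
            .set_axis(["source_id", "target_id"], axis=1)
            .astype(str)
            .drop_duplicates()
            .reset_index(drop=True)
        )
        del cols

    @classmethod
    def identity(cls, genes) -> "HomologMap":
        return cls(pd.DataFrame({"source_id": list(genes), "target_id": list(genes)}))

    @classmethod
    def from_csv(cls, path) -> "HomologMap":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path) -> None:
        self.pairs.to_csv(path, index=False)


@dataclass
class CorrelationTable:
    """Best Pearson correlation of each cell with each retained cell type.

    ``table`` is cells x unique type names; undefined correlations (zero
    variance on the shared support) are stored as NaN and treated as -inf
    whenever an argmax over types is taken.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.table.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("Pearson correlations must lie in [-1, 1]")
        # lexicographic column order makes argmax tie-breaks deterministic
        self.table = self.table.reindex(sorted(self.table.columns), axis=1)

    @property
    def cell_ids(self) -> pd.Index:
        return self.table.index

    @property
    def type_names(self) -> list[str]:
        return list(self.table.columns)

    def argmax_labels(self) -> pd.Series:
        """Per-cell best type; ties go to the lexicographically first name.

        Cells whose correlations are all undefined get the ambiguous label.
        """
        vals = self.table.to_numpy(dtype=float)
        filled = np.where(np.isnan(vals), -np.inf, vals)
        idx = np.argmax(filled, axis=1)  # first max == lexicographic winner
        labels = np.asarray(self.type_names, dtype=object)[idx]
        all_undef = ~np.isfinite(filled).any(axis=1)
        labels[all_undef] = AMBIGUOUS_LABEL
        return pd.Series(labels, index=self.table.index, name="label")

    def best_correlation(self) -> pd.Series:
        vals = self.table.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            best = np.nanmax(vals, axis=1)
        return pd.Series(best, index=self.table.index, name="best_correlation")


def make_label_set(labels: pd.Series, provenance: str | pd.Series) -> pd.DataFrame:
    """Assemble a label table (index: cell id; columns: label, provenance)."""
    if isinstance(provenance, str):
        provenance = pd.Series(provenance, index=labels.index)
    return pd.DataFrame({"label": labels, "provenance": provenance})


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def translate_homologs(
    atlas: ReferenceAtlas,
    homolog_map: HomologMap,
    target_genes: list[str],
) -> ReferenceAtlas:
    """Re-index an atlas into the query's gene space via a homolog map.

    Several source genes mapping to one target gene are collapsed by their
    mean profile value; a source gene with several targets contributes its
    value to each of them. Target genes with no mapped source gene are
    dropped from the correlation support.
    """
    pairs = homolog_map.pairs
    target_set = set(target_genes)
    atlas_pos = {g: i for i, g in enumerate(atlas.gene_ids)}
    usable = pairs[
        pairs["target_id"].isin(target_set) & pairs["source_id"].isin(atlas_pos)
    ]
    if usable.empty:
        raise ValueError(
            "homolog map yields zero overlapping genes between atlas and target"
        )
    src_idx = usable["source_id"].map(atlas_pos).to_numpy()
    # group source columns by target gene, collapse by mean
    grouped: dict[str, list[int]] = {}
    for s, t in zip(src_idx, usable["target_id"]):
        grouped.setdefault(t, []).append(s)
    kept = [g for g in target_genes if g in grouped]
    cols = np.column_stack(
        [atlas.profiles[:, grouped[g]].mean(axis=1) for g in kept]
    )
    logger.info(
        "homolog translation: %d/%d target genes covered, %d source pairs used",
        len(kept), len(target_genes), len(usable),
    )
    return ReferenceAtlas(
        type_names=list(atlas.type_names),
        sources=list(atlas.sources),
        profiles=cols,
        gene_ids=kept,
    )


def normalize_expression(
    counts: ad.AnnData,
    method: str = "lognorm",
    target_sum: float = 1e4,
) -> ad.AnnData:
    """Per-cell expression normalization before correlation.

    ``lognorm`` (default): scale each cell to ``target_sum`` total counts and
    apply log1p — common practice for UMI data. ``raw`` leaves counts
    untouched; ``rank`` replaces each cell's values by their within-cell
    ranks (average ranks on ties), making the subsequent Pearson correlation
    a Spearman correlation.
    """
    X = counts.X
    dense = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    dense = dense.astype(float)
    totals = dense.sum(axis=1)
    if method == "raw":
        out = dense
    elif method == "lognorm":
        if np.any(totals == 0):
            raise ValueError(
                "cell(s) with zero total counts; remove them with QC first"
            )
        out = np.log1p(dense / totals[:, None] * target_sum)
    elif method == "rank":
        if np.any(totals == 0):
            raise ValueError(
                "cell(s) with zero total counts; remove them with QC first"
            )
        out = rankdata(dense, axis=1).astype(float)
    else:
        raise ValueError(f"unknown normalization method: {method!r}")
    res = ad.AnnData(
        X=out, obs=counts.obs.copy(), var=counts.var.copy(), uns=dict(counts.uns)
    )
    res.uns["normalization"] = {"method": method, "target_sum": target_sum}
    return res


def normalize_atlas(
    atlas: ReferenceAtlas,
    method: str = "lognorm",
    target_sum: float = 1e4,
) -> ReferenceAtlas:
    """Apply the sample's expression transform to the atlas profiles.

    Pearson correlation between a log-normalized cell and a linear-scale
    reference profile is dominated by the profile's largest values; putting
    both sides on the same scale makes the comparison meaningful. Mirrors
    :func:`normalize_expression`: each profile is scaled to ``target_sum``
    and log1p-transformed (``lognorm``), left as-is (``raw``), or rank
    transformed (``rank``).
    """
    P = atlas.profiles
    if method == "raw":
        out = P.copy()
    elif method == "lognorm":
        totals = P.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError("atlas entry with all-zero profile")
        out = np.log1p(P / totals * target_sum)
    elif method == "rank":
        out = rankdata(P, axis=1).astype(float)
    else:
        raise ValueError(f"unknown normalization method: {method!r}")
    return ReferenceAtlas(
        type_names=list(atlas.type_names),
        sources=list(atlas.sources),
        profiles=out,
        gene_ids=list(atlas.gene_ids),
    )


def sketch_sample(counts: ad.AnnData | int, n: int, seed: int) -> np.ndarray:
    """Uniform random subsample of cell indices ("sketch").

    Returns exactly ``min(n, n_cells)`` distinct indices in ascending order,
    deterministically for a given seed. Intended to be applied per condition.
    """
    if n < 1:
        raise ValueError("sketch size must be >= 1")
    n_cells = counts if isinstance(counts, int) else counts.n_obs
    if n >= n_cells:
        return np.arange(n_cells)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_cells, size=n, replace=False))


def correlate_cells(
    normalized: ad.AnnData,
    atlas: ReferenceAtlas,
    min_shared_genes: int = 3,
) -> CorrelationTable:
    """Best Pearson correlation per (cell, cell type) over shared genes.

    Correlations are computed on the intersection of the sample and atlas
    gene spaces; for a type with several atlas entries the best (maximum)
    correlation is kept. Zero-variance vectors yield undefined (NaN)
    correlations, which downstream argmaxes treat as -inf.
    """
    shared = [g for g in normalized.var_names if g in set(atlas.gene_ids)]
    if len(shared) < min_shared_genes:
        raise ValueError(
            f"only {len(shared)} genes shared between sample and atlas "
            f"(need >= {min_shared_genes})"
        )
    X = normalized[:, shared].X
    cells = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    gpos = {g: i for i, g in enumerate(atlas.gene_ids)}
    entries = atlas.profiles[:, [gpos[g] for g in shared]]
    logger.info(
        "correlating %d cells with %d atlas entries over %d shared genes",
        cells.shape[0], entries.shape[0], len(shared),
    )

    def _standardize(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = m - m.mean(axis=1, keepdims=True)
        norm = np.sqrt((c * c).sum(axis=1))
        zero = norm == 0
        norm[zero] = 1.0
        return c / norm[:, None], zero

    zc, cell_zero = _standardize(cells)
    ze, entry_zero = _standardize(entries)
    r = zc @ ze.T  # cells x entries
    r = np.clip(r, -1.0, 1.0)
    r[cell_zero, :] = np.nan
    r[:, entry_zero] = np.nan

    frame = pd.DataFrame(r, index=normalized.obs_names, columns=atlas.type_names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        best = frame.T.groupby(level=0).max(numeric_only=True).T
    return CorrelationTable(best)


def prune_rare_types(
    corr: CorrelationTable,
    min_frac: float = 0.0005,
) -> tuple[CorrelationTable, pd.DataFrame]:
    """Drop cell types claiming fewer than ``min_frac`` of the sketch cells.

    Each cell is first assigned its argmax type; types whose share of these
    initial assignments is strictly below ``min_frac`` are removed from the
    table, and the cells initially assigned to them are labelled
    "ambiguous". Shares are computed over all sketch cells, including the
    prospective ambiguous ones.
    """
    if not 0 <= min_frac <= 1:
        raise ValueError("min_frac must lie in [0, 1]")
    if len(corr.type_names) < 1:
        raise ValueError("correlation table has no cell types")
    initial = corr.argmax_labels()
    n = len(initial)
    shares = initial.value_counts() / n
    removed = [
        t for t in corr.type_names if shares.get(t, 0.0) < min_frac
    ]
    kept = [t for t in corr.type_names if t not in removed]
    if not kept:
        raise ValueError("all cell types fall below the minimum sketch share")
    labels = initial.copy()
    labels[initial.isin(removed)] = AMBIGUOUS_LABEL
    if removed:
        logger.info(
            "pruned %d rare type(s) (%s); %d cell(s) labelled ambiguous",
            len(removed), ", ".join(removed), int((labels == AMBIGUOUS_LABEL).sum()),
        )
    pruned = CorrelationTable(corr.table[kept].copy())
    return pruned, make_label_set(labels, "sketch")
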