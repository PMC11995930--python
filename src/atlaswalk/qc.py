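"""Cell and gene quality-control filters.

Cells are kept only if their UMI total is strictly above ``min_umis``, their
mitochondrial UMI fraction is strictly below ``max_mito_frac``, and — when
detected-genes bounds are set — their number of detected genes lies strictly
inside the open interval. The detected-genes bounds emulate the common
manual thresholding of the detected-genes distribution that removes
putative doublets (too many genes) and dead cells (too few); because that
choice is inherently manual, the pipeline only proposes quantile-based
candidates and requires the bounds to be confirmed explicitly in config.

The mitochondrial fraction is always computed on the raw, unfiltered gene
set, so gene filtering cannot change cell-QC outcomes and the two filters
commute.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import scipy.sparse as sp

from .synthetic import MITO_PREFIX

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCThresholds:
    """Cell/gene filter thresholds.

    ``min_umis`` is a strict lower bound (a cell at exactly ``min_umis``
    UMIs is removed); ``max_mito_frac`` is a strict upper bound on the
    mitochondrial UMI fraction. The default 0.01 reads the threshold as a
    1% fraction; the literal 0.0001 is reachable by configuration.
    """

    min_umis: int = 1000
    max_mito_frac: float = 0.01
    gene_count_bounds: tuple[int, int] | None = None
    min_cells_per_gene: int = 2

    def __post_init__(self) -> None:
        if self.min_umis < 0:
            raise ValueError("min_umis must be >= 0")
        if not 0 <= self.max_mito_frac <= 1:
            raise ValueError("max_mito_frac must lie in [0, 1]")
        if self.gene_count_bounds is not None:
            low, high = self.gene_count_bounds
            if not low < high:
                raise ValueError("gene_count_bounds must satisfy low < high")
        if self.min_cells_per_gene < 0:
            raise ValueError("min_cells_per_gene must be >= 0")


@dataclass
class QCReport:
    n_cells_in: int
    n_cells_out: int
    n_genes_in: int
    n_genes_out: int
    removed_low_umi: int
    removed_high_mito: int
    removed_gene_bounds: int
    mito_filter_applied: bool
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _dense_totals(X) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell UMI totals and detected-gene counts."""
    if sp.issparse(X):
        totals = np.asarray(X.sum(axis=1)).ravel()
        detected = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        X = np.asarray(X)
        totals = X.sum(axis=1)
        detected = (X > 0).sum(axis=1)
    return totals, detected


def filter_cells(
    counts: ad.AnnData,
    thresholds: QCThresholds,
    mito_prefix: str = MITO_PREFIX,
) -> tuple[ad.AnnData, QCReport]:
    """Apply the cell-level QC filters; cell order is preserved.

    If no gene name carries the mitochondrial prefix the mitochondrial
    filter is skipped with a warning rather than silently dropping all
    cells.
    """
    if counts.n_obs == 0 or counts.n_vars == 0:
        raise ValueError("empty count matrix")
    totals, detected = _dense_totals(counts.X)

    keep = totals > thresholds.min_umis
    removed_low_umi = int((~keep).sum())

    mito_mask = np.array(
        [g.startswith(mito_prefix) for g in counts.var_names], dtype=bool
    )
    mito_applied = bool(mito_mask.any())
    removed_high_mito = 0
    if mito_applied:
        X = counts.X
        mito_counts = (
            np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
            if sp.issparse(X)
            else np.asarray(X)[:, mito_mask].sum(axis=1)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
        mito_keep = mito_frac < thresholds.max_mito_frac
        removed_high_mito = int((~mito_keep).sum())
        keep &= mito_keep
    else:
        warnings.warn(
            f"no genes with prefix {mito_prefix!r} found; "
            "mitochondrial filter skipped",
            stacklevel=2,
        )
        logger.warning("mitochondrial filter skipped: no %r genes", mito_prefix)

    removed_gene_bounds = 0
    if thresholds.gene_count_bounds is not None:
        low, high = thresholds.gene_count_bounds
        bounds_keep = (detected > low) & (detected < high)
        removed_gene_bounds = int((~bounds_keep).sum())
        keep &= bounds_keep

    filtered = counts[keep].copy()
    report = QCReport(
        n_cells_in=counts.n_obs,
        n_cells_out=filtered.n_obs,
        n_genes_in=counts.n_vars,
        n_genes_out=counts.n_vars,
        removed_low_umi=removed_low_umi,
        removed_high_mito=removed_high_mito,
        removed_gene_bounds=removed_gene_bounds,
        mito_filter_applied=mito_applied,
        thresholds={
            "min_umis": thresholds.min_umis,
            "max_mito_frac": thresholds.max_mito_frac,
            "gene_count_bounds": list(thresholds.gene_count_bounds)
            if thresholds.gene_count_bounds
            else None,
        },
    )
    logger.info(
        "cell QC: %d -> %d cells (low UMI %d, high mito %d, gene bounds %d)",
        report.n_cells_in, report.n_cells_out,
        removed_low_umi, removed_high_mito, removed_gene_bounds,
    )
    return filtered, report


def filter_genes(counts: ad.AnnData, min_cells_per_gene: int = 2) -> ad.AnnData:
    """Keep genes detected in at least ``min_cells_per_gene`` cells.

    The default of 2 removes exactly the genes quantified in only one cell
    (or none); gene order is preserved.
    """
    X = counts.X
    if sp.issparse(X):
        n_cells = np.asarray((X > 0).sum(axis=0)).ravel()
    else:
        n_cells = (np.asarray(X) > 0).sum(axis=0)
    keep = n_cells >= min_cells_per_gene
    out = counts[:, keep].copy()
    logger.info("gene QC: %d -> %d genes", counts.n_vars, out.n_vars)
    return out


def propose_gene_count_bounds(
    counts: ad.AnnData,
    low_quantile: float,
    high_quantile: float,
) -> tuple[float, float]:
    """Quantiles of detected genes per cell, as candidate doublet/dead bounds.

    Purely advisory: the returned values must be confirmed explicitly in
    the QC configuration before they are applied.
    """
    if not 0 <= low_quantile < high_quantile <= 1:
        raise ValueError("need 0 <= low_quantile < high_quantile <= 1")
    if counts.n_obs < 2:
        raise ValueError("need at least 2 cells to propose bounds")
    _, detected = _dense_totals(counts.X)
    low, high = np.quantile(detected, [low_quantile, high_quantile])
    return float(low), float(high)
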