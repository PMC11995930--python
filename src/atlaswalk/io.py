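"""Readers and writers for the standard on-disk formats.

Count matrices use the 10x-style triplet layout: ``matrix.mtx`` (Matrix
Market integer coordinate, genes x cells, 1-based indices), ``features.tsv``
and ``barcodes.tsv``. Gene sets use GMT (set name, description, genes,
tab-separated, one set per line). All per-cell tables are keyed by barcode
so filtered outputs remain joinable.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .scoring import GeneSet
from .synthetic import SyntheticTruth

logger = logging.getLogger(__name__)


def _dedupe(names: list[str], what: str) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    dups = 0
    for n in names:
        if n in seen:
            seen[n] += 1
            out.append(f"{n}-{seen[n]}")
            dups += 1
        else:
            seen[n] = 0
            out.append(n)
    if dups:
        warnings.warn(f"{dups} duplicate {what} identifier(s) suffixed", stacklevel=3)
        logger.warning("%d duplicate %s identifier(s) suffixed", dups, what)
    return out


def write_counts_10x(counts: ad.AnnData, outdir) -> Path:
    """Write matrix.mtx / features.tsv / barcodes.tsv (genes x cells)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = counts.X
    mat = sp.coo_matrix(X.T if sp.issparse(X) else np.asarray(X).T).astype(np.int64)
    scipy.io.mmwrite(outdir / "matrix.mtx", mat, field="integer")
    (outdir / "features.tsv").write_text(
        "".join(f"{g}\n" for g in counts.var_names)
    )
    (outdir / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in counts.obs_names)
    )
    return outdir


def read_counts_10x(indir) -> ad.AnnData:
    """Read a 10x-style triplet directory into an AnnData (cells x genes)."""
    indir = Path(indir)
    for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (indir / fname).exists():
            raise FileNotFoundError(f"missing {fname} in {indir}")
    mat = scipy.io.mmread(indir / "matrix.mtx")  # genes x cells
    features = [
        line.split("\t")[0]
        for line in (indir / "features.tsv").read_text().splitlines()
        if line
    ]
    barcodes = [
        line.strip() for line in (indir / "barcodes.tsv").read_text().splitlines()
        if line.strip()
    ]
    n_genes, n_cells = mat.shape
    if len(features) != n_genes:
        raise ValueError(
            f"matrix.mtx declares {n_genes} genes but features.tsv has "
            f"{len(features)} lines"
        )
    if len(barcodes) != n_cells:
        raise ValueError(
            f"matrix.mtx declares {n_cells} cells but barcodes.tsv has "
            f"{len(barcodes)} lines"
        )
    features = _dedupe(features, "feature")
    barcodes = _dedupe(barcodes, "barcode")
    X = sp.csr_matrix(mat.T).astype(np.int64)
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(features, name="gene_id")),
    )


def write_truth_tsv(truth: SyntheticTruth, path) -> None:
    truth.cells.to_csv(path, sep="\t")


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_labels_tsv(labels: pd.DataFrame, path, best_correlation=None) -> None:
    """Write a label table (barcode, label, provenance[, best_correlation])."""
    out = labels.copy()
    out.index.name = "barcode"
    if best_correlation is not None:
        out["best_correlation"] = best_correlation.reindex(out.index)
    out.to_csv(path, sep="\t")


def read_labels_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="barcode")


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: one tab-separated gene set per line.

    Lines need at least three fields (name, description, >= 1 gene);
    duplicate genes within a set are removed with a warning.
    """
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
            )
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        uniq = list(dict.fromkeys(genes))
        if len(uniq) != len(genes):
            warnings.warn(
                f"{path}:{lineno}: duplicate genes in set {name!r} removed",
                stacklevel=2,
            )
        sets.append(GeneSet(name=name, genes=uniq, description=desc))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")
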