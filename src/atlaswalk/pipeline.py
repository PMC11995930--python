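"""End-to-end driver: QC -> atlas typing -> consensus walk -> scoring -> KS.

The pipeline consumes two-condition 10x-style count directories, a
reference-atlas CSV, an optional homolog map and a GMT of gene sets, and
writes per-stage artifacts (label tables, differential-expression and GSEA
tables, per-cell scores, the QC report and the resolved configuration)
into an output directory. Every stochastic stage derives its seed from the
single root seed, so identical configurations reproduce identical outputs
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from . import atlas as atlas_mod
from . import consensus, io, qc, scoring

logger = logging.getLogger(__name__)

# fixed offsets deriving stage seeds from the root seed
_SEED_SKETCH = 101
_SEED_BALANCE = 202
_SEED_GSEA = 303


@dataclass
class PipelineConfig:
    counts_dirs: dict[str, str]  # condition name -> 10x triplet directory
    atlas_csv: str
    out_dir: str
    homolog_csv: str | None = None
    gmt_path: str | None = None
    seed: int = 0
    # QC
    min_umis: int = 1000
    max_mito_frac: float = 0.01
    gene_count_bounds: tuple[int, int] | None = None
    min_cells_per_gene: int = 2
    # typing
    normalization: str = "lognorm"
    sketch_n: int = 5000
    min_type_frac: float = 0.0005
    top_k: int = 30
    de_min_frac: float = 0.05
    n_neighbors: int = 20
    n_pcs: int = 20
    trim: float = 0.25
    patience: int = 10
    k_neighbors: int = 5
    # comparison
    balance_types: list[str] | None = None
    n_perm: int = 1000
    gsea_weight: float = 1.0

    def validate(self) -> None:
        if len(self.counts_dirs) < 1:
            raise ValueError("at least one counts directory is required")
        for cond, d in self.counts_dirs.items():
            if not Path(d).is_dir():
                raise ValueError(f"counts directory for condition {cond!r} "
                                 f"not found: {d}")
        if not Path(self.atlas_csv).is_file():
            raise ValueError(f"atlas CSV not found: {self.atlas_csv}")
        if self.homolog_csv and not Path(self.homolog_csv).is_file():
            raise ValueError(f"homolog map not found: {self.homolog_csv}")
        if self.gmt_path and not Path(self.gmt_path).is_file():
            raise ValueError(f"GMT file not found: {self.gmt_path}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["gene_count_bounds"] is not None:
            d["gene_count_bounds"] = list(d["gene_count_bounds"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "gene_count_bounds" in raw and raw["gene_count_bounds"] is not None:
            raw["gene_count_bounds"] = tuple(raw["gene_count_bounds"])
        return cls(**raw)


def annotate_dataset(
    normalized: ad.AnnData,
    ref: atlas_mod.ReferenceAtlas,
    sketch_n: int = 5000,
    seed: int = 0,
    min_type_frac: float = 0.0005,
    top_k: int = 30,
    de_min_frac: float = 0.05,
    n_neighbors: int = 20,
    n_pcs: int = 20,
    trim: float = 0.25,
    patience: int = 10,
    k_neighbors: int = 5,
    condition_key: str | None = None,
    atlas_normalization: str = "lognorm",
) -> tuple[pd.DataFrame, atlas_mod.CorrelationTable, consensus.MarkerPanel | None]:
    """Sketch -> correlate -> prune -> panel -> tree -> walk -> project.

    The atlas profiles are put on the sample's expression scale
    (``atlas_normalization``) before correlating. Sketching is applied per
    condition when ``condition_key`` names an obs column. If pruning leaves
    a single retained type the marker panel and walk are skipped and every
    cell receives that type directly. Returns the full label table, the
    pruned correlation table and the marker panel (None in the single-type
    case).
    """
    ref = atlas_mod.normalize_atlas(ref, method=atlas_normalization)
    if condition_key is not None and condition_key in normalized.obs:
        conds = normalized.obs[condition_key]
        sketch_idx = []
        for ci, cond in enumerate(sorted(conds.unique())):
            pos = np.flatnonzero((conds == cond).to_numpy())
            sub = atlas_mod.sketch_sample(len(pos), sketch_n, seed=seed + _SEED_SKETCH + ci)
            sketch_idx.append(pos[sub])
        sketch_idx = np.sort(np.concatenate(sketch_idx))
    else:
        sketch_idx = atlas_mod.sketch_sample(normalized, sketch_n,
                                             seed=seed + _SEED_SKETCH)
    sketch = normalized[sketch_idx].copy()

    corr = atlas_mod.correlate_cells(sketch, ref)
    corr, initial = atlas_mod.prune_rare_types(corr, min_type_frac)
    if len(corr.type_names) == 1:
        only = corr.type_names[0]
        logger.info("single retained type %r; consensus walk skipped", only)
        prov = pd.Series("projected", index=normalized.obs_names)
        prov.loc[sketch.obs_names] = "sketch"
        labels = pd.DataFrame(
            {"label": pd.Series(only, index=normalized.obs_names), "provenance": prov}
        )
        return labels, corr, None

    panel = consensus.pairwise_marker_panel(
        sketch, initial["label"], top_k=top_k, min_frac=de_min_frac
    )
    tree = consensus.build_cluster_tree(
        sketch, panel, n_neighbors=n_neighbors, n_pcs=n_pcs
    )
    sketch_labels = consensus.consensus_walk(tree, corr, patience=patience, trim=trim)
    labels = consensus.project_labels(
        sketch_labels, normalized, panel, k_neighbors=k_neighbors, n_pcs=n_pcs
    )
    return labels, corr, panel


def _setup_log(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("atlaswalk")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage in order and write artifacts to ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_log(out)
    try:
        return _run(config, out)
    finally:
        logging.getLogger("atlaswalk").removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> Path:
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    # ---- load & QC -------------------------------------------------------
    conditions = sorted(config.counts_dirs)
    parts = []
    for cond in conditions:
        a = io.read_counts_10x(config.counts_dirs[cond])
        a.obs["condition"] = cond
        a.obs_names = [f"{cond}:{b}" for b in a.obs_names]
        parts.append(a)
    counts = ad.concat(parts, join="outer", merge="same") if len(parts) > 1 else parts[0]
    counts.X = counts.X.tocsr().astype(np.int64)

    thresholds = qc.QCThresholds(
        min_umis=config.min_umis,
        max_mito_frac=config.max_mito_frac,
        gene_count_bounds=config.gene_count_bounds,
        min_cells_per_gene=config.min_cells_per_gene,
    )
    filtered, report = qc.filter_cells(counts, thresholds)
    filtered = qc.filter_genes(filtered, config.min_cells_per_gene)
    report.n_genes_out = filtered.n_vars
    report.to_json(out / "qc_report.json")

    # ---- atlas typing on the sketch -------------------------------------
    ref = atlas_mod.ReferenceAtlas.from_csv(config.atlas_csv)
    if config.homolog_csv:
        hmap = atlas_mod.HomologMap.from_csv(config.homolog_csv)
        ref = atlas_mod.translate_homologs(ref, hmap, list(filtered.var_names))
    normalized = atlas_mod.normalize_expression(filtered, method=config.normalization)

    labels, corr, _panel = annotate_dataset(
        normalized,
        ref,
        sketch_n=config.sketch_n,
        seed=config.seed,
        min_type_frac=config.min_type_frac,
        top_k=config.top_k,
        de_min_frac=config.de_min_frac,
        n_neighbors=config.n_neighbors,
        n_pcs=config.n_pcs,
        trim=config.trim,
        patience=config.patience,
        k_neighbors=config.k_neighbors,
        condition_key="condition",
    )
    io.write_labels_tsv(labels, out / "labels.tsv",
                        best_correlation=corr.best_correlation())

    # ---- balanced DE / GSEA / scoring / KS per type -----------------------
    results: list[dict] = []
    gene_sets = io.read_gmt(config.gmt_path) if config.gmt_path else []
    if len(conditions) >= 2 and gene_sets:
        cond_series = normalized.obs["condition"]
        target_types = config.balance_types or _types_in_all_conditions(
            labels["label"], cond_series
        )
        balanced = consensus.balance_conditions(
            labels, cond_series, target_types, seed=config.seed + _SEED_BALANCE
        )
        score_rows = []
        for t in target_types:
            cells_t = balanced[labels.loc[balanced, "label"] == t]
            g1 = [c for c in cells_t if cond_series[c] == conditions[0]]
            g2 = [c for c in cells_t if cond_series[c] == conditions[1]]
            de = scoring.wilcoxon_de(normalized, g1, g2, min_frac=config.de_min_frac)
            ranked = scoring.rank_by_log2fc(de)
            ranked.to_csv(out / f"de_{t}.tsv", sep="\t", index=False)
            for gs in gene_sets:
                try:
                    gr = scoring.gsea_preranked(
                        ranked, gs, weight=config.gsea_weight,
                        n_perm=config.n_perm, seed=config.seed + _SEED_GSEA,
                    )
                except ValueError as exc:
                    logger.warning("GSEA skipped for %s/%s: %s", t, gs.name, exc)
                    continue
                sub = normalized[list(cells_t)]
                scores = scoring.score_cells(sub, gr.leading_edge, name=gs.name)
                d, p = scoring.ks_compare(
                    scores.loc[g1].to_numpy(), scores.loc[g2].to_numpy()
                )
                results.append(
                    {
                        "cell_type": t,
                        "gene_set": gs.name,
                        "es": gr.es,
                        "gsea_p": gr.p_value,
                        "n_leading_edge": len(gr.leading_edge),
                        "ks_D": d,
                        "ks_p": p,
                        "n_cells_per_condition": len(g1),
                    }
                )
                for c, s in scores.items():
                    score_rows.append(
                        {"barcode": c, "cell_type": t, "gene_set": gs.name,
                         "score": s, "condition": cond_series[c]}
                    )
        pd.DataFrame(score_rows).to_csv(out / "scores.tsv", sep="\t", index=False)
    pd.DataFrame(
        results,
        columns=["cell_type", "gene_set", "es", "gsea_p", "n_leading_edge",
                 "ks_D", "ks_p", "n_cells_per_condition"],
    ).to_csv(out / "gsea_ks.tsv", sep="\t", index=False)

    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "n_cells_after_qc": int(report.n_cells_out),
                "n_genes_after_qc": int(report.n_genes_out),
                "retained_types": corr.type_names,
                "n_comparisons": len(results),
            },
            fh,
            indent=2,
        )
    return out


def _types_in_all_conditions(labels: pd.Series, conditions: pd.Series) -> list[str]:
    tab = pd.crosstab(labels, conditions.reindex(labels.index))
    ok = tab.index[(tab > 0).all(axis=1)]
    return sorted(t for t in ok if t != atlas_mod.AMBIGUOUS_LABEL)
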