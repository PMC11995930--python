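"""Ground-truth simulator for reference-based cell typing.

Generates a reference atlas of cell-type expression profiles and UMI count
matrices sampled from it, with the nuisance structure the downstream
analysis has to cope with: lognormal library sizes, per-entry dropout,
doublets formed by averaging two type profiles, and a per-cell
mitochondrial mass fraction carried by dedicated ``mt-`` genes. Two-condition
datasets add a log2 fold-change shift on a chosen signature-gene set in one
condition, giving a known effect size for calibrating the downstream
Kolmogorov-Smirnov comparison.

All randomness flows from a single integer seed; identical configurations
reproduce bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .atlas import ReferenceAtlas

MITO_PREFIX = "mt-"

# fixed sub-stream tags so each draw family is independent of the others
_STREAM_ATLAS = 1
_STREAM_CELLS = 2
_STREAM_COND_A = 3
_STREAM_COND_B = 4


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic dataset generator.

    The defaults describe a small but realistic droplet experiment: four
    well-separated cell types (marker blocks shifted by 4 log2 units), 500
    cells per type, median library size ~5,000 UMIs with moderate spread,
    5% dropout, 2% doublets, and a mitochondrial fraction around 0.5%.
    """

    seed: int
    n_types: int = 4
    n_genes: int = 300
    n_cells_per_type: int | tuple[int, ...] = 500
    mean_profile_scale: float = 1.0
    type_separation: float = 4.0  # log2 fold distance of marker blocks
    n_marker_genes_per_type: int = 10
    library_size_lognormal: tuple[float, float] = (math.log(5000.0), 0.35)
    dropout_rate: float = 0.05
    doublet_rate: float = 0.02
    mito_gene_count: int = 10
    mito_fraction_beta: tuple[float, float] = (2.0, 398.0)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        for name in ("dropout_rate", "doublet_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_profile_scale <= 0:
            raise ValueError("mean_profile_scale must be positive")
        if self.type_separation < 0:
            raise ValueError("type_separation must be nonnegative")
        if min(self.cells_per_type()) < 1:
            raise ValueError("n_cells_per_type entries must be positive")
        if self.mito_gene_count < 0 or self.mito_gene_count >= self.n_genes:
            raise ValueError("mito_gene_count must lie in [0, n_genes)")
        a, b = self.mito_fraction_beta
        if a <= 0 or b <= 0:
            raise ValueError("mito_fraction_beta parameters must be positive")
        n_body = self.n_genes - self.mito_gene_count
        if self.n_types * self.n_marker_genes_per_type > n_body:
            raise ValueError(
                "not enough non-mitochondrial genes for disjoint marker blocks"
            )

    def cells_per_type(self) -> tuple[int, ...]:
        if isinstance(self.n_cells_per_type, (int, np.integer)):
            return (int(self.n_cells_per_type),) * self.n_types
        if len(self.n_cells_per_type) != self.n_types:
            raise ValueError("n_cells_per_type length must equal n_types")
        return tuple(int(c) for c in self.n_cells_per_type)

    def gene_ids(self) -> list[str]:
        body = [f"gene{i:04d}" for i in range(self.n_genes - self.mito_gene_count)]
        mito = [f"{MITO_PREFIX}{i}" for i in range(self.mito_gene_count)]
        return body + mito

    def type_names(self) -> list[str]:
        return [f"type{chr(ord('A') + i) if self.n_types <= 26 else i}"
                for i in range(self.n_types)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_cells_per_type"] = list(self.cells_per_type())
        d["library_size_lognormal"] = list(self.library_size_lognormal)
        d["mito_fraction_beta"] = list(self.mito_fraction_beta)
        return d


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated dataset.

    ``cells`` is indexed by barcode with columns ``true_label``,
    ``is_doublet``, ``condition`` and ``library_size``; ``params`` records
    the full generator configuration (seed included), so the dataset can be
    regenerated identically.
    """

    cells: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"true_label", "is_doublet", "condition", "library_size"}
        if not required <= set(self.cells.columns):
            raise ValueError(f"truth table must have columns {sorted(required)}")

    @property
    def true_labels(self) -> pd.Series:
        return self.cells["true_label"]

    @property
    def is_doublet(self) -> pd.Series:
        return self.cells["is_doublet"]


def make_reference_atlas(config: GeneratorConfig) -> ReferenceAtlas:
    """Build type profiles: shared lognormal baseline + disjoint marker blocks.

    Every type shares a common lognormal baseline; a disjoint block of
    ``n_marker_genes_per_type`` genes is up-shifted by ``2**type_separation``
    for each type, so the separation parameter directly controls how
    distinguishable types are (separation 0 makes all profiles identical).
    """
    rng = np.random.default_rng([config.seed, _STREAM_ATLAS])
    base = rng.lognormal(
        mean=math.log(config.mean_profile_scale), sigma=1.0, size=config.n_genes
    )
    n_mito = config.mito_gene_count
    profiles = np.tile(base, (config.n_types, 1))
    block = config.n_marker_genes_per_type
    for t in range(config.n_types):
        lo = t * block
        profiles[t, lo:lo + block] *= 2.0 ** config.type_separation
    if n_mito:
        # keep mitochondrial baseline modest; per-cell mass is set at sampling
        profiles[:, config.n_genes - n_mito:] *= 0.1
    return ReferenceAtlas(
        type_names=config.type_names(),
        sources=["synthetic"] * config.n_types,
        profiles=profiles,
        gene_ids=config.gene_ids(),
    )


def _sample_counts(
    atlas: ReferenceAtlas,
    config: GeneratorConfig,
    rng: np.random.Generator,
    condition: str,
    barcode_prefix: str,
) -> tuple[ad.AnnData, SyntheticTruth]:
    if atlas.n_entries == 0:
        raise ValueError("empty atlas")
    if len(atlas.gene_ids) != config.n_genes:
        raise ValueError("atlas gene space does not match config.n_genes")
    per_type = config.cells_per_type()
    n_cells = sum(per_type)
    type_idx = np.repeat(np.arange(config.n_types), per_type)

    is_doublet = rng.random(n_cells) < config.doublet_rate
    if config.n_types < 2:
        is_doublet[:] = False
    partner = rng.integers(0, max(config.n_types - 1, 1), size=n_cells)
    partner = np.where(partner >= type_idx, partner + 1, partner)

    mu, sigma = config.library_size_lognormal
    lib = np.maximum(1, np.round(rng.lognormal(mu, sigma, size=n_cells))).astype(int)
    a, b = config.mito_fraction_beta
    mito_frac = rng.beta(a, b, size=n_cells) if config.mito_gene_count else None

    n_genes = config.n_genes
    n_mito = config.mito_gene_count
    body = slice(0, n_genes - n_mito)
    mito = slice(n_genes - n_mito, n_genes)
    X = np.zeros((n_cells, n_genes), dtype=np.int64)
    for i in range(n_cells):
        prof = atlas.profiles[type_idx[i]].astype(float)
        if is_doublet[i]:
            prof = 0.5 * (prof + atlas.profiles[partner[i]])
        p = prof.copy()
        if n_mito:
            f = mito_frac[i]
            body_mass = p[body].sum()
            mito_mass = p[mito].sum()
            p[body] *= (1.0 - f) / body_mass
            p[mito] *= f / mito_mass
        else:
            p /= p.sum()
        X[i] = rng.multinomial(lib[i], p)
    if config.dropout_rate > 0:
        X[rng.random(X.shape) < config.dropout_rate] = 0

    barcodes = [f"{barcode_prefix}{i:06d}" for i in range(n_cells)]
    counts = ad.AnnData(
        X=sp.csr_matrix(X),
        obs=pd.DataFrame({"condition": condition}, index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(atlas.gene_ids, name="gene_id")),
    )
    names = np.asarray(atlas.type_names, dtype=object)
    truth = SyntheticTruth(
        cells=pd.DataFrame(
            {
                "true_label": names[type_idx],
                "is_doublet": is_doublet,
                "condition": condition,
                "library_size": lib,
            },
            index=pd.Index(barcodes, name="barcode"),
        ),
        params=config.to_dict(),
    )
    return counts, truth


def simulate_cells(
    atlas: ReferenceAtlas,
    config: GeneratorConfig,
    condition: str = "A",
    barcode_prefix: str = "cell",
    _stream: int = _STREAM_CELLS,
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Sample a UMI count matrix with known per-cell truth.

    Each cell draws a library size from the lognormal, a mitochondrial mass
    fraction from the Beta, and its counts from a single multinomial over
    its (possibly doublet-averaged) type profile, so that with zero dropout
    every cell's total equals its drawn library size exactly. Dropout then
    zeroes each (cell, gene) entry independently. Doublets average the
    cell's own profile with one other type's and keep the first type as the
    recorded true label, flagged in the truth table.
    """
    rng = np.random.default_rng([config.seed, _stream])
    return _sample_counts(atlas, config, rng, condition, barcode_prefix)


def simulate_condition_pair(
    atlas: ReferenceAtlas,
    config: GeneratorConfig,
    signature_genes: list[str],
    shift_log2fc: float,
) -> tuple[ad.AnnData, ad.AnnData, SyntheticTruth, SyntheticTruth]:
    """Two-condition dataset with a signature-gene shift in condition B.

    Condition B's profile means for ``signature_genes`` are multiplied by
    ``2**shift_log2fc`` before sampling; at shift 0 the two conditions are
    draws from identical distributions.
    """
    gene_pos = {g: i for i, g in enumerate(atlas.gene_ids)}
    missing = [g for g in signature_genes if g not in gene_pos]
    if missing:
        raise ValueError(f"signature genes not in atlas gene space: {missing}")
    rng_a = np.random.default_rng([config.seed, _STREAM_COND_A])
    rng_b = np.random.default_rng([config.seed, _STREAM_COND_B])
    counts_a, truth_a = _sample_counts(atlas, config, rng_a, "A", "A-cell")

    shifted = ReferenceAtlas(
        type_names=list(atlas.type_names),
        sources=list(atlas.sources),
        profiles=atlas.profiles.copy(),
        gene_ids=list(atlas.gene_ids),
    )
    idx = [gene_pos[g] for g in signature_genes]
    shifted.profiles[:, idx] *= 2.0 ** shift_log2fc
    counts_b, truth_b = _sample_counts(shifted, config, rng_b, "B", "B-cell")
    for t in (truth_a, truth_b):
        t.params = dict(t.params, shift_log2fc=shift_log2fc,
                        signature_genes=list(signature_genes))
    return counts_a, counts_b, truth_a, truth_b
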