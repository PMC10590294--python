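"""From a gene-expression count matrix to the samples x features panel.

The analysis consumes a fixed panel of immune features: gene-set signature
scores (immune cell types and T-cell states) plus individual immune genes.
Counts are library-size normalized to log2 CPM, each gene is z-scored
across samples (population SD), and a signature score is the mean of its
member genes' z-scores; a single-gene feature is that gene's z-score.

The panel is fully configurable (GMT); `default_panel` ships a 62-feature
layout — 8 cell-type sets, 5 T-cell-state sets, 49 single genes — with
placeholder gene ids for synthetic runs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "normalize_expression",
    "score_signatures",
    "assemble_feature_matrix",
    "default_panel",
]


def _validate_expression(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample ids in expression matrix")
    if matrix.shape[0] < 1 or matrix.shape[1] < 2:
        raise ValueError("expression matrix needs >= 1 gene and >= 2 samples")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")


def normalize_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2 counts-per-million: log2(1e6 * count / library_size + 1).

    `matrix` is genes x samples of raw counts.  A zero count maps to 0
    exactly, and scaling a sample's counts leaves its CPM unchanged.
    """
    _validate_expression(matrix)
    lib = matrix.sum(axis=0)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return np.log2(1e6 * matrix / lib + 1.0)


def score_signatures(normalized: pd.DataFrame, panel) -> tuple[pd.DataFrame, dict]:
    """Score each panel feature on a normalized genes x samples matrix.

    Each gene row is z-scored across samples with the population SD
    (ddof=0).  A signature feature is the mean of its member genes'
    z-scores; a single-gene feature is that gene's z-score.  Genes absent
    from the matrix or with zero variance are dropped from their sets with
    a warning; a set losing all members yields an all-NaN (missing)
    feature, reported.

    Returns (samples x features DataFrame in panel order, report dict with
    ``missing_genes``, ``constant_genes``, ``missing_features``).
    """
    panel = dict(panel)
    if not panel:
        raise ValueError("empty signature panel")
    if normalized.index.duplicated().any() or normalized.columns.duplicated().any():
        raise ValueError("duplicate gene or sample ids")
    if normalized.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    mu = normalized.mean(axis=1)
    sd = normalized.std(axis=1, ddof=0)
    usable = sd > 0
    z = normalized.sub(mu, axis=0).div(sd.where(usable), axis=0)

    missing_genes: list[str] = []
    constant_genes: list[str] = []
    missing_features: list[str] = []
    cols = {}
    for name, members in panel.items():
        members = [members] if isinstance(members, str) else list(members)
        if not members:
            raise ValueError(f"feature {name!r} has no member genes")
        present = [g for g in members if g in z.index]
        missing_genes += [g for g in members if g not in z.index]
        kept = [g for g in present if usable.get(g, False)]
        constant_genes += [g for g in present if not usable.get(g, False)]
        if not kept:
            missing_features.append(name)
            cols[name] = pd.Series(np.nan, index=normalized.columns)
        else:
            cols[name] = z.loc[kept].mean(axis=0)
    report = {
        "missing_genes": sorted(set(missing_genes)),
        "constant_genes": sorted(set(constant_genes)),
        "missing_features": missing_features,
    }
    if report["missing_genes"]:
        warnings.warn(f"panel genes not in matrix: {report['missing_genes']}")
    if report["constant_genes"]:
        warnings.warn(f"zero-variance genes dropped: {report['constant_genes']}")
    if report["missing_features"]:
        warnings.warn(f"features with no usable genes: {report['missing_features']}")
    return pd.DataFrame(cols, index=normalized.columns), report


def assemble_feature_matrix(
    features: pd.DataFrame, clinical: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Inner-join the feature matrix (samples x features) with the clinical table.

    Both inputs are indexed by sample id.  Returns the joined table plus a
    report of ids dropped from each side; an empty intersection or a
    duplicated sample id raises.
    """
    for name, df in (("features", features), ("clinical", clinical)):
        if df.index.duplicated().any():
            raise ValueError(f"duplicate sample ids in {name} table")
    shared = features.index.intersection(clinical.index)
    if len(shared) == 0:
        raise ValueError("no sample ids shared between features and clinical table")
    joined = features.loc[shared].join(clinical.loc[shared])
    report = {
        "dropped_from_features": sorted(features.index.difference(clinical.index)),
        "dropped_from_clinical": sorted(clinical.index.difference(features.index)),
    }
    return joined, report


_CELL_TYPES = (
    "b_cells", "cd4_t_cells", "cd8_t_cells", "nk_cells",
    "monocytes", "macrophages", "dendritic_cells", "neutrophils",
)
_T_STATES = (
    "t_exhausted", "t_effector", "t_memory", "t_regulatory", "t_cytotoxic",
)


def default_panel(genes_per_set: int = 10, n_single_genes: int = 49) -> dict:
    """A 62-feature panel layout with placeholder gene ids.

    8 immune-cell-type signatures + 5 T-cell-state signatures +
    `n_single_genes` single-gene features.  Intended for synthetic runs;
    real analyses supply their own GMT.
    """
    panel: dict[str, list[str]] = {}
    for name in _CELL_TYPES + _T_STATES:
        panel[name] = [f"{name}_g{i}" for i in range(genes_per_set)]
    for i in range(n_single_genes):
        panel[f"immune_gene_{i:02d}"] = [f"immune_gene_{i:02d}"]
    return panel
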