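"""Flat-file I/O: TSV tables, GMT gene sets, MatrixMarket counts, model files.

Everything the pipeline writes is plain text so runs diff cleanly and
artifacts stay auditable.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .model import CandidateModel

__all__ = [
    "read_table", "write_table",
    "read_gmt", "write_gmt",
    "read_expression", "write_expression_mtx",
    "read_model", "write_model",
]


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path, index=True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_gmt(path) -> dict:
    """GMT: one set per line — name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        name, _desc, *genes = parts
        if name in sets:
            raise ValueError(f"duplicate gene set {name!r}")
        sets[name] = [g for g in genes if g]
    return sets


def write_gmt(gene_sets: dict, path, description: str = "na") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            members = [members] if isinstance(members, str) else list(members)
            fh.write("\t".join([name, description, *members]) + "\n")


def read_expression(path, genes_path=None, samples_path=None) -> pd.DataFrame:
    """Counts as genes x samples, from TSV or MTX (+ row/col name files)."""
    path = Path(path)
    if path.suffix == ".mtx":
        if genes_path is None or samples_path is None:
            raise ValueError("MTX input needs gene and sample name files")
        mat = spio.mmread(path).toarray()
        genes = Path(genes_path).read_text().split()
        samples = Path(samples_path).read_text().split()
        return pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=samples)
    return read_table(path)


def write_expression_mtx(expr: pd.DataFrame, path, genes_path, samples_path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(path), sparse.csr_matrix(expr.to_numpy()))
    Path(genes_path).write_text("\n".join(map(str, expr.index)) + "\n")
    Path(samples_path).write_text("\n".join(map(str, expr.columns)) + "\n")


def write_model(model: CandidateModel, path) -> None:
    """Serialize a fitted candidate as structured plain text (YAML)."""
    payload = {
        "features": list(model.features),
        "C": float(model.C),
        "coefficients": [float(c) for c in model.coef],
        "intercept": float(model.intercept),
        "standardization_mean": [float(m) for m in model.mean],
        "standardization_scale": [float(s) for s in model.scale],
        "cv_auc": float(model.cv_auc),
        "variability_4std": (
            None if model.variability_4std is None else float(model.variability_4std)
        ),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_model(path) -> CandidateModel:
    raw = yaml.safe_load(Path(path).read_text())
    return CandidateModel(
        features=tuple(raw["features"]),
        C=raw["C"],
        coef=tuple(raw["coefficients"]),
        intercept=raw["intercept"],
        mean=tuple(raw["standardization_mean"]),
        scale=tuple(raw["standardization_scale"]),
        cv_auc=raw["cv_auc"],
        variability_4std=raw.get("variability_4std"),
    )
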