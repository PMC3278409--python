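"""Shared I/O: expression matrices, phenotype tables, gene sets, split models.

All on-disk formats are plain text: TSV for matrices and tables (first column
gene/sample ID, tab-separated), GMT for gene sets, JSON for fitted models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "read_duplicate_pairs",
    "write_duplicate_pairs",
    "read_gmt",
    "write_json",
    "read_json",
]


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of continuous expression.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns.
    duplicate_pairs
        Optional list of ``(original, copy)`` sample-ID pairs for samples
        assayed twice (technical replicates).
    """

    values: pd.DataFrame
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup!r}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate sample ID: {dup!r}")
        arr = v.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        cols = set(v.columns)
        for a, b in self.duplicate_pairs:
            if a not in cols or b not in cols:
                raise ValueError(f"duplicate pair ({a!r}, {b!r}) not among samples")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        keep = set(samples)
        pairs = [p for p in self.duplicate_pairs if p[0] in keep and p[1] in keep]
        return ExpressionMatrix(self.values[samples].copy(), pairs)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), list(self.duplicate_pairs))


def read_expression(path, duplicate_pairs=None) -> ExpressionMatrix:
    """Read a TSV expression matrix (gene-ID first column, sample-ID header).

    Raises ``ValueError`` with the offending line/ID for ragged rows,
    non-numeric cells, duplicated gene IDs or an empty file.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # pandas reports the line number
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        where = bad.index[0] if len(bad) else "?"
        raise ValueError(
            f"{path}: non-numeric value in sample {col!r} at gene {where!r}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), list(duplicate_pairs or []))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = df.index.name or "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_duplicate_pairs(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [tuple(row) for row in df.iloc[:, :2].itertuples(index=False)]


def write_duplicate_pairs(pairs, path) -> None:
    pd.DataFrame(pairs, columns=["original", "copy"]).to_csv(path, sep="\t", index=False)


def read_phenotype(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_phenotype(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t")


def read_gmt(path) -> dict[str, dict]:
    """Read a GMT gene-set file: name, description, then member gene IDs."""
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: empty gene set {name!r}")
            sets[name] = {"description": desc, "genes": genes}
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
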