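"""Reading expression tables and preparing TPM / log10-TPM matrices.

The entry formats are deliberately plain: a genes-by-samples count table
(TSV or CSV, first column gene ids, header row sample ids), a two-column
gene-length table (gene id, length in bp) and a sample-design table
(sample id, condition, replicate).  All downstream results are keyed by
gene id, never by row position.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "CountMatrix",
    "GeneLengthTable",
    "SampleDesign",
    "ExpressionMatrix",
    "read_count_matrix",
    "read_gene_lengths",
    "read_sample_design",
    "tpm_normalize",
    "log10_transform",
    "select_replicate_pair",
]

DEFAULT_LOG_FLOOR = 1e-3
"""Default TPM floor applied before log10 so that zeros stay finite."""


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise DataError(f"duplicate {what}: {dups}")


@dataclass
class CountMatrix:
    """Raw read counts, genes x samples."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] < 1 or df.shape[1] < 2:
            raise DataError(
                f"count matrix needs >= 1 gene and >= 2 samples, got {df.shape}"
            )
        _check_unique(df.index, "gene id")
        _check_unique(df.columns, "sample id")
        if not np.issubdtype(df.to_numpy().dtype, np.number):
            raise DataError("counts must be numeric")
        if (df.to_numpy() < 0).any():
            raise DataError("negative counts are not allowed")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class GeneLengthTable:
    """Gene id -> length in base pairs."""

    lengths: pd.Series

    def __post_init__(self) -> None:
        s = self.lengths
        _check_unique(s.index, "gene id")
        if (s.to_numpy() <= 0).any():
            bad = s.index[s.to_numpy() <= 0].tolist()
            raise DataError(f"non-positive gene lengths for: {bad}")


@dataclass
class SampleDesign:
    """Sample id -> (condition, replicate) assignment."""

    table: pd.DataFrame  # index sample_id, columns: condition, replicate

    def __post_init__(self) -> None:
        t = self.table
        for col in ("condition", "replicate"):
            if col not in t.columns:
                raise DataError(f"design table missing column {col!r}")
        _check_unique(t.index, "sample id")
        pairs = list(zip(t["condition"], t["replicate"]))
        if len(pairs) != len(set(pairs)):
            raise DataError("duplicate (condition, replicate) pair in design")

    @property
    def conditions(self) -> list[str]:
        # preserve order of first appearance
        return list(dict.fromkeys(self.table["condition"]))

    def samples_of(self, condition: str) -> list[str]:
        mask = self.table["condition"] == condition
        if not mask.any():
            raise DataError(f"unknown condition {condition!r}")
        return list(self.table.index[mask])

    def replicate_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "replicate"])

    def subset(self, sample_ids) -> "SampleDesign":
        return SampleDesign(self.table.loc[list(sample_ids)].copy())


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values on a declared scale.

    ``scale`` is ``"linear"`` for TPM and ``"log10"`` for log10-TPM; the
    flag gates every operation that is scale-sensitive.
    """

    values: pd.DataFrame
    scale: str = "linear"
    design: SampleDesign | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log10"):
            raise DataError(f"unknown scale {self.scale!r}")
        if self.scale == "linear" and (self.values.to_numpy() < 0).any():
            raise DataError("linear-scale expression must be non-negative")
        _check_unique(self.values.index, "gene id")
        _check_unique(self.values.columns, "sample id")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def require_scale(self, scale: str) -> None:
        if self.scale != scale:
            raise DataError(f"expected {scale}-scale matrix, got {self.scale}")

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(gene_ids)].copy(), self.scale, self.design
        )


def _read_table(path: str | Path, dialect: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if dialect not in ("tsv", "csv"):
        raise DataError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise DataError(f"no data rows in {path}") from None
    if df.shape[0] == 0:
        raise DataError(f"no data rows in {path}")
    return df


def _to_numeric(df: pd.DataFrame, what: str) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise DataError(
                f"non-numeric {what} at gene {row!r}, sample {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        if converted.isna().any():
            row = df.index[converted.isna().to_numpy().argmax()]
            raise DataError(f"missing {what} at gene {row!r}, sample {col!r}")
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def read_count_matrix(path: str | Path, dialect: str | None = None) -> CountMatrix:
    """Read a genes x samples count table; gene order is preserved."""
    df = _to_numeric(_read_table(path, dialect), "count")
    return CountMatrix(df)


def read_gene_lengths(path: str | Path, dialect: str | None = None) -> GeneLengthTable:
    df = _read_table(path, dialect)
    if df.shape[1] < 1:
        raise DataError("gene length table needs a length column")
    lengths = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    if lengths.isna().any():
        bad = df.index[lengths.isna()].tolist()
        raise DataError(f"non-numeric gene length for: {bad}")
    return GeneLengthTable(lengths.astype(float))


def read_sample_design(path: str | Path, dialect: str | None = None) -> SampleDesign:
    df = _read_table(path, dialect)
    return SampleDesign(df)


def tpm_normalize(cm: CountMatrix, gl: GeneLengthTable) -> ExpressionMatrix:
    """Transcripts-per-million normalization.

    Per sample: ``rate_i = count_i / (length_i / 1000)`` and
    ``TPM_i = rate_i / sum(rate) * 1e6`` so every column sums to one
    million.
    """
    missing = [g for g in cm.gene_ids if g not in gl.lengths.index]
    if missing:
        raise DataError(f"missing gene lengths for: {missing[:10]}"
                        + ("..." if len(missing) > 10 else ""))
    lengths_kb = gl.lengths.loc[cm.gene_ids].to_numpy(float) / 1000.0
    counts = cm.counts.to_numpy(float)
    rates = counts / lengths_kb[:, None]
    totals = rates.sum(axis=0)
    if (totals == 0).any():
        bad = [s for s, t in zip(cm.sample_ids, totals) if t == 0]
        raise DataError(f"all-zero sample column(s), TPM undefined: {bad}")
    tpm = rates / totals * 1e6
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=cm.gene_ids, columns=cm.sample_ids),
        scale="linear",
    )


def log10_transform(
    em: ExpressionMatrix, floor: float = DEFAULT_LOG_FLOOR
) -> ExpressionMatrix:
    """log10 of TPM after clamping at ``floor`` (keeps zeros finite)."""
    em.require_scale("linear")
    if floor <= 0:
        raise DataError("floor must be positive")
    vals = np.log10(np.maximum(em.values.to_numpy(float), floor))
    return ExpressionMatrix(
        pd.DataFrame(vals, index=em.values.index, columns=em.values.columns),
        scale="log10",
        design=em.design,
    )


def select_replicate_pair(
    em: ExpressionMatrix, condition: str, floor: float = DEFAULT_LOG_FLOOR
) -> tuple[str, str]:
    """Pick the two replicates of ``condition`` with the highest Pearson
    correlation of log10 expression over all genes.

    Ties are broken toward the lexicographically smallest sample-id pair.
    """
    if em.design is None:
        raise DataError("expression matrix carries no sample design")
    samples = em.design.samples_of(condition)
    if len(samples) < 2:
        raise DataError(
            f"condition {condition!r} has {len(samples)} replicate(s); need >= 2"
        )
    if em.scale == "linear":
        logvals = np.log10(np.maximum(em.values[samples].to_numpy(float), floor))
    else:
        logvals = em.values[samples].to_numpy(float)
    cols = {s: logvals[:, i] for i, s in enumerate(samples)}
    pairs = list(combinations(sorted(samples), 2))
    best = pairs[0]
    best_r = -np.inf
    for a, b in pairs:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = float(np.corrcoef(cols[a], cols[b])[0, 1])
        if np.isnan(r):  # constant replicate column
            continue
        if r > best_r:
            best, best_r = (a, b), r
    return best
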