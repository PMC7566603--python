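"""Pairwise expression noise (squared coefficient of variation).

For gene *i* observed in two samples *j*, *k* the noise is

    eta2_i(jk) = sigma2 / mu2 = 2 (x_ij - x_ik)^2 / (x_ij + x_ik)^2

computed on linear TPM.  Aggregating over genes gives the
transcriptome-wide noise of the sample pair; averaged over the two
within-condition replicate pairs it yields the replicate-noise baseline
that calibrates the overlay dot size: between-condition noise in excess
of this baseline is attributed to differential expression.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .io import ExpressionMatrix, select_replicate_pair

__all__ = [
    "NoiseSummary",
    "gene_pair_noise",
    "transcriptome_noise",
    "replicate_noise_baseline",
]


@dataclass(frozen=True)
class NoiseSummary:
    """Per-gene and aggregate noise for one sample pair."""

    per_gene: pd.Series  # index gene_id, values eta2
    aggregate: float
    mode: str  # "mean" | "sum"
    pair: tuple[str, str]


def gene_pair_noise(x_j, x_k) -> np.ndarray:
    """Per-gene eta2 between two expression vectors (linear TPM).

    Bounded by 2 (attained when one of the two values is zero) and
    symmetric in the pair.
    """
    xj = np.asarray(x_j, dtype=float)
    xk = np.asarray(x_k, dtype=float)
    if xj.shape != xk.shape:
        raise DataError(f"length mismatch: {xj.shape} vs {xk.shape}")
    if np.any(xj < 0) or np.any(xk < 0):
        raise DataError("expression values must be non-negative")
    total = xj + xk
    if np.any(total == 0):
        bad = int(np.argmax(total == 0))
        raise DataError(f"gene at position {bad} is zero in both samples; "
                        "eta2 undefined (filter low-expression genes first)")
    return 2.0 * (xj - xk) ** 2 / total**2


def transcriptome_noise(per_gene, mode: str = "mean") -> float:
    """Aggregate per-gene noise over the transcriptome (mean or sum)."""
    eta = np.asarray(per_gene, dtype=float)
    if eta.size == 0:
        raise DataError("empty noise vector")
    if mode == "mean":
        return float(eta.mean())
    if mode == "sum":
        return float(eta.sum())
    raise DataError(f"unknown aggregation mode {mode!r}")


def pair_noise_summary(
    em: ExpressionMatrix, pair: tuple[str, str], mode: str = "mean"
) -> NoiseSummary:
    """NoiseSummary for one sample pair of a linear-scale matrix."""
    em.require_scale("linear")
    a, b = pair
    eta = gene_pair_noise(em.values[a].to_numpy(), em.values[b].to_numpy())
    per_gene = pd.Series(eta, index=em.values.index, name="eta2")
    return NoiseSummary(per_gene, transcriptome_noise(eta, mode), mode, (a, b))


def replicate_noise_baseline(
    em: ExpressionMatrix,
    comparison: tuple[str, str],
    pairs: dict[str, tuple[str, str]] | None = None,
    mode: str = "mean",
) -> float:
    """Average within-condition replicate noise over the two compared
    conditions.

    ``pairs`` may pin the replicate pair per condition; otherwise the
    best-correlated pair is selected per condition.
    """
    em.require_scale("linear")
    out = []
    for cond in comparison:
        pair = pairs[cond] if pairs is not None else select_replicate_pair(em, cond)
        out.append(pair_noise_summary(em, pair, mode).aggregate)
    return float(np.mean(out))
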