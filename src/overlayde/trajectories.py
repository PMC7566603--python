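"""Response metrics over a time series: correlation decay from an
anchor condition and PC1-PC2 expression trajectories, computed for the
whole transcriptome or for DE / non-DE gene subsets.

These mirror the downstream validation of overlay DE calls: the DE
subset should carry the transcriptome-wide response (correlation decay,
long PC trajectory) while the non-DE remainder stays close to the
anchor.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DataError
from .io import ExpressionMatrix, log10_transform

__all__ = ["TrajectoryResult", "correlation_trajectory", "pc_trajectory"]


@dataclass
class TrajectoryResult:
    """Correlation and PC-path summaries for one gene subset."""

    subset: str
    correlations: pd.Series | None  # index condition/time label
    pc_path: pd.DataFrame | None  # index condition, columns PC1, PC2
    explained: np.ndarray | None  # variance fractions, all components


def _as_log10(em: ExpressionMatrix) -> ExpressionMatrix:
    return log10_transform(em) if em.scale == "linear" else em


def _subset_matrix(em: ExpressionMatrix, subset) -> pd.DataFrame:
    if subset is None:
        return em.values
    subset = list(subset)
    if not subset:
        raise DataError("empty gene subset")
    missing = [g for g in subset if g not in em.values.index]
    if missing:
        raise DataError(f"subset genes absent from matrix: {missing[:5]}")
    return em.values.loc[subset]


def correlation_trajectory(
    em: ExpressionMatrix,
    subset=None,
    anchor: str | None = None,
) -> pd.Series:
    """Pearson correlation of log10 expression between the anchor
    condition and every condition, averaged over matched replicates.

    Replicates are matched by replicate label (anchor replicate k vs
    target replicate k), so the anchor correlates with itself at
    exactly 1.
    """
    if em.design is None:
        raise DataError("expression matrix carries no sample design")
    em = _as_log10(em)
    vals = _subset_matrix(em, subset)
    conds = em.design.conditions
    anchor = anchor if anchor is not None else conds[0]
    if anchor not in conds:
        raise DataError(f"anchor {anchor!r} not among conditions {conds}")

    anchor_reps = {
        em.design.replicate_of(s): s for s in em.design.samples_of(anchor)
    }
    out = {}
    for cond in conds:
        rs = []
        for s in em.design.samples_of(cond):
            rep = em.design.replicate_of(s)
            if rep not in anchor_reps:
                continue
            a = vals[anchor_reps[rep]].to_numpy(float)
            b = vals[s].to_numpy(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                raise DataError(
                    f"constant expression vector (condition {cond!r}); "
                    "correlation undefined"
                )
            rs.append(float(np.corrcoef(a, b)[0, 1]))
        if not rs:
            raise DataError(f"no replicate of {cond!r} matches an anchor replicate")
        out[cond] = float(np.mean(rs))
    return pd.Series(out, name="pearson_r")


def pc_trajectory(
    em: ExpressionMatrix,
    subset=None,
    anchor: str | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PC scores of the samples (observations) over subset genes
    (variables), averaged over replicates per condition.

    The matrix is mean-centered, not variance-scaled.  Sign convention:
    each component is flipped so the anchor's averaged score is <= 0.
    Returns (per-condition PC1/PC2 path, explained-variance fractions of
    all components).
    """
    if em.design is None:
        raise DataError("expression matrix carries no sample design")
    em = _as_log10(em)
    vals = _subset_matrix(em, subset)
    if vals.shape[0] < 2:
        raise DataError("need >= 2 genes for a PC decomposition")
    conds = em.design.conditions
    if len(conds) < 2:
        raise DataError("need >= 2 conditions/time points")
    anchor = anchor if anchor is not None else conds[0]

    X = vals.to_numpy(float).T  # samples x genes
    n_comp = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)  # samples x components
    scores = pd.DataFrame(scores, index=vals.columns)

    path = scores.groupby(
        em.design.table.loc[scores.index, "condition"].to_numpy()
    ).mean()
    path = path.loc[conds]  # preserve condition order
    for comp in path.columns:
        if path.loc[anchor, comp] > 0:
            path[comp] = -path[comp]
    keep = path.iloc[:, : min(2, path.shape[1])].copy()
    keep.columns = [f"PC{i + 1}" for i in range(keep.shape[1])]
    return keep, pca.explained_variance_ratio_
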