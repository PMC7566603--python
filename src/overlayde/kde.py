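"""Kernel-density p-values for overlay DE calls.

The null cloud is the union of the two within-condition replicate
scatters: with X1 the concatenation of the replicate-1 log10-TPM
vectors of both conditions and X2 the replicate-2 concatenation, the
cloud is the 2m points (X1[j], X2[j]).  A diagonal-bandwidth 2D
Gaussian mixture over those points estimates the null density f, and a
gene's p-value asks how plausibly its between-condition point belongs
to that cloud.  Three readings are offered:

``cdf``        the lower-orthant mass F(x1, x2) of the mixture,
``two_sided``  2 * min(F, 1 - F),
``hdr``        the estimated probability that a draw from f has density
               at most the density at the point (near 1 deep inside the
               cloud, near 0 for outliers; Monte-Carlo estimate).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .errors import DataError
from .io import ExpressionMatrix
from .overlay import COMBOS, OverlayResult, _pairs_for

__all__ = [
    "KdeModel",
    "DEReport",
    "build_kde_model",
    "estimate_bandwidth",
    "kde_cdf",
    "kde_pdf",
    "de_pvalues",
    "apply_cutoffs",
    "log2_fold_changes",
]


@dataclass(frozen=True)
class KdeModel:
    """Equal-weight Gaussian mixture over the null-cloud points."""

    x1: np.ndarray  # first coordinate of the 2m cloud points
    x2: np.ndarray
    h1: float  # bandwidth (std dev) per dimension
    h2: float
    method: str = "silverman"

    def __post_init__(self) -> None:
        if self.x1.shape != self.x2.shape or self.x1.ndim != 1:
            raise DataError("cloud coordinate vectors must be equal-length 1D")
        if self.h1 <= 0 or self.h2 <= 0:
            raise DataError("bandwidths must be positive")

    @property
    def n_points(self) -> int:
        return self.x1.size


@dataclass
class DEReport:
    """Per-gene DE table: overlay flag, p-value, fold change, final call."""

    table: pd.DataFrame  # columns de_overlay, p, log2_fold_change, de_final
    meta: dict = field(default_factory=dict)

    @property
    def de_final_genes(self) -> list[str]:
        return list(self.table.index[self.table["de_final"]])

    @classmethod
    def from_overlay(
        cls,
        result: OverlayResult,
        em_linear: ExpressionMatrix | None = None,
        comparison: tuple[str, str] | None = None,
    ) -> "DEReport":
        table = pd.DataFrame(index=result.table.index)
        table["de_overlay"] = result.table["de"]
        table["p"] = np.nan
        if em_linear is not None and comparison is not None:
            table["log2_fold_change"] = log2_fold_changes(em_linear, comparison)
        else:
            table["log2_fold_change"] = np.nan
        table["de_final"] = table["de_overlay"]
        return cls(table, meta={"dot_size": result.dot_size})


def log2_fold_changes(
    em_linear: ExpressionMatrix, comparison: tuple[str, str]
) -> pd.Series:
    """log2 of (mean TPM in condition 2 / mean TPM in condition 1)."""
    em_linear.require_scale("linear")
    if em_linear.design is None:
        raise DataError("expression matrix carries no sample design")
    cond1, cond2 = comparison
    m1 = em_linear.values[em_linear.design.samples_of(cond1)].mean(axis=1)
    m2 = em_linear.values[em_linear.design.samples_of(cond2)].mean(axis=1)
    with np.errstate(divide="ignore"):
        return pd.Series(np.log2(m2 / m1), index=em_linear.values.index)


def _sheather_jones(x: np.ndarray) -> float:
    """Univariate Sheather-Jones solve-the-equation plug-in bandwidth."""
    n = x.size
    sd = x.std(ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    lam = min(sd, iqr / 1.349) if iqr > 0 else sd
    if lam <= 0:
        raise DataError("zero variance in a dimension")

    def _pair_diffs(h):
        # pairwise differences in manageable chunks
        d = (x[:, None] - x[None, :]) / h
        return d

    def _phi4(t):
        return (t**4 - 6 * t**2 + 3) * stats.norm.pdf(t)

    def _phi6(t):
        return (t**6 - 15 * t**4 + 45 * t**2 - 15) * stats.norm.pdf(t)

    a = 0.920 * lam * n ** (-1 / 7)
    b = 0.912 * lam * n ** (-1 / 9)
    sda = np.sum(_phi4(_pair_diffs(a))) / (n * (n - 1) * a**5)
    tdb = -np.sum(_phi6(_pair_diffs(b))) / (n * (n - 1) * b**7)
    if sda <= 0 or tdb <= 0:
        return sd * n ** (-1 / 5)  # fall back to a normal-reference rule

    def _sd_alpha(h):
        alpha = 1.357 * (sda / tdb) ** (1 / 7) * h ** (5 / 7)
        return np.sum(_phi4(_pair_diffs(alpha))) / (n * (n - 1) * alpha**5)

    def _objective(h):
        s = _sd_alpha(h)
        if s <= 0:
            return np.inf
        return h - (1.0 / (2 * np.sqrt(np.pi) * n * s)) ** 0.2

    h0 = sd * n ** (-1 / 5)
    lo, hi = h0 / 20, h0 * 20
    try:
        return float(brentq(_objective, lo, hi))
    except ValueError:
        return float(h0)


def estimate_bandwidth(points, method: str = "silverman") -> tuple[float, float]:
    """Per-dimension bandwidth for a diagonal 2D kernel.

    ``silverman``: h_d = sd_d * n^(-1/6) (the d=2 Silverman rule, unit
    prefactor); ``plugin``: univariate Sheather-Jones per dimension.
    """
    xy = np.asarray(points, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise DataError("points must be an (n, 2) array")
    n = xy.shape[0]
    if n < 10:
        raise DataError(f"need >= 10 points to estimate a bandwidth, got {n}")
    sds = xy.std(axis=0, ddof=1)
    if (sds == 0).any():
        raise DataError("zero variance in a dimension")
    if method == "silverman":
        h = sds * n ** (-1 / 6)
        return float(h[0]), float(h[1])
    if method == "plugin":
        return _sheather_jones(xy[:, 0]), _sheather_jones(xy[:, 1])
    raise DataError(f"unknown bandwidth method {method!r}")


def build_kde_model(
    em: ExpressionMatrix,
    comparison: tuple[str, str],
    pairs: dict[str, tuple[str, str]] | None = None,
    method: str = "silverman",
) -> KdeModel:
    """Null-cloud KDE from the two within-condition replicate scatters."""
    em.require_scale("log10")
    cond1, cond2 = comparison
    pairs = _pairs_for(em, comparison, pairs)
    r1c1, r2c1 = pairs[cond1]
    r1c2, r2c2 = pairs[cond2]
    x1 = np.concatenate(
        [em.values[r1c1].to_numpy(float), em.values[r1c2].to_numpy(float)]
    )
    x2 = np.concatenate(
        [em.values[r2c1].to_numpy(float), em.values[r2c2].to_numpy(float)]
    )
    h1, h2 = estimate_bandwidth(np.column_stack([x1, x2]), method=method)
    return KdeModel(x1=x1, x2=x2, h1=h1, h2=h2, method=method)


def kde_cdf(p, model: KdeModel) -> float | np.ndarray:
    """Lower-orthant mixture CDF F(p1, p2).

    For a diagonal bandwidth this is the mean over cloud points of the
    product of two univariate normal CDFs.
    """
    pt = np.asarray(p, dtype=float)
    single = pt.ndim == 1
    pt = pt.reshape(-1, 2)
    f = np.empty(pt.shape[0])
    for i, (p1, p2) in enumerate(pt):
        f[i] = float(
            np.mean(
                stats.norm.cdf((p1 - model.x1) / model.h1)
                * stats.norm.cdf((p2 - model.x2) / model.h2)
            )
        )
    return float(f[0]) if single else f


def kde_pdf(p, model: KdeModel) -> float | np.ndarray:
    """Mixture density at one or many 2D points."""
    pt = np.asarray(p, dtype=float)
    single = pt.ndim == 1
    pt = pt.reshape(-1, 2)
    f = np.empty(pt.shape[0])
    for i, (p1, p2) in enumerate(pt):
        f[i] = float(
            np.mean(
                stats.norm.pdf((p1 - model.x1) / model.h1)
                * stats.norm.pdf((p2 - model.x2) / model.h2)
            )
            / (model.h1 * model.h2)
        )
    return float(f[0]) if single else f


def _hdr_pvalues(
    points: np.ndarray, model: KdeModel, n_mc: int, seed: int
) -> np.ndarray:
    """P(f(X) <= f(point)) for X drawn from the fitted mixture."""
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, model.n_points, size=n_mc)
    draws = np.column_stack(
        [
            model.x1[idx] + rng.normal(scale=model.h1, size=n_mc),
            model.x2[idx] + rng.normal(scale=model.h2, size=n_mc),
        ]
    )
    f_draws = np.asarray(kde_pdf(draws, model))
    f_pts = np.asarray(kde_pdf(points, model)).reshape(-1)
    return np.array([float(np.mean(f_draws <= f0)) for f0 in f_pts])


def de_pvalues(
    report: DEReport,
    model: KdeModel,
    em: ExpressionMatrix,
    comparison: tuple[str, str],
    mode: str = "cdf",
    combo: str = "first",
    pairs: dict[str, tuple[str, str]] | None = None,
    n_mc: int = 4000,
    seed: int = 0,
) -> DEReport:
    """Attach a null-cloud p-value to every gene.

    The between-condition point defaults to the replicate-1 pairing
    (cond1-rep1, cond2-rep1); ``combo="all"`` evaluates all four
    pairings and keeps the maximum p (most conservative).
    """
    if mode not in ("cdf", "two_sided", "hdr"):
        raise DataError(f"unknown p-value mode {mode!r}")
    em.require_scale("log10")
    pairs = _pairs_for(em, comparison, pairs)
    cond1, cond2 = comparison
    combos = COMBOS if combo == "all" else ((1, 1),)

    p_all = []
    for a, b in combos:
        s1 = pairs[cond1][a - 1]
        s2 = pairs[cond2][b - 1]
        pts = np.column_stack(
            [
                em.values.loc[report.table.index, s1].to_numpy(float),
                em.values.loc[report.table.index, s2].to_numpy(float),
            ]
        )
        if mode == "hdr":
            p = _hdr_pvalues(pts, model, n_mc=n_mc, seed=seed)
        else:
            f = np.asarray(kde_cdf(pts, model)).reshape(-1)
            p = f if mode == "cdf" else 2.0 * np.minimum(f, 1.0 - f)
        p_all.append(p)
    p = np.max(np.vstack(p_all), axis=0)

    table = report.table.copy()
    table["p"] = p
    meta = dict(report.meta)
    meta.update(
        {
            "p_mode": mode,
            "p_combo": combo,
            "bandwidth_method": model.method,
            "bandwidth": [model.h1, model.h2],
        }
    )
    return DEReport(table, meta)


def apply_cutoffs(
    report: DEReport,
    p_cutoff: float | None = None,
    fold_cutoff: float | None = None,
) -> DEReport:
    """Final DE call: overlay flag AND optional p / fold-change cutoffs.

    ``de_final = de_overlay and (p < p_cutoff) and (|log2FC| >=
    log2(fold_cutoff))`` with unset cutoffs skipped; tightening cutoffs
    can only shrink the DE set.
    """
    table = report.table.copy()
    de = table["de_overlay"].to_numpy(bool).copy()
    if p_cutoff is not None:
        if not 0.0 <= p_cutoff <= 1.0:
            raise DataError("p_cutoff must lie in [0, 1]")
        if table["p"].isna().all():
            raise DataError("p-values absent; run de_pvalues first")
        de &= table["p"].to_numpy(float) < p_cutoff
    if fold_cutoff is not None:
        if fold_cutoff < 1.0:
            raise DataError("fold_cutoff must be >= 1")
        de &= np.abs(table["log2_fold_change"].to_numpy(float)) >= np.log2(fold_cutoff)
    table["de_final"] = de
    meta = dict(report.meta)
    meta.update({"p_cutoff": p_cutoff, "fold_cutoff": fold_cutoff})
    return DEReport(table, meta)
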