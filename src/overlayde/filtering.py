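"""Low-expression filtering driven by distribution fits.

Bulk transcriptome TPM values are well described by heavy-tailed
positive distributions (lognormal, Burr XII, Pareto, log-logistic,
Weibull).  The best family is chosen by AIC from maximum-likelihood
fits; the lower tail of the data typically carries an excess of noisy,
weakly expressed genes relative to the fitted bulk, and the lowest
point below the fitted mode where the empirical density crosses the
fitted density is taken as the expression cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError, FitError
from .io import ExpressionMatrix

__all__ = [
    "FitResult",
    "FilterSpec",
    "FAMILIES",
    "fit_family",
    "select_best_family",
    "lower_tail_threshold",
    "filter_low_expression",
]

#: free-parameter count per family (location is pinned, see fit_family)
FAMILIES: dict[str, int] = {
    "lognormal": 2,
    "pareto": 1,
    "burr": 3,
    "loglogistic": 2,
    "weibull": 2,
}


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one distribution family."""

    family: str
    params: dict[str, float]
    loglik: float
    aic: float
    n: int

    def frozen(self):
        """Rebuild the frozen scipy distribution for this fit."""
        p = self.params
        if self.family == "lognormal":
            return stats.lognorm(p["sigma"], scale=np.exp(p["mu"]))
        if self.family == "pareto":
            return stats.pareto(p["b"], scale=p["scale"])
        if self.family == "burr":
            return stats.burr12(p["c"], p["d"], scale=p["scale"])
        if self.family == "loglogistic":
            return stats.fisk(p["c"], scale=p["scale"])
        if self.family == "weibull":
            return stats.weibull_min(p["c"], scale=p["scale"])
        raise FitError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class FilterSpec:
    """Expression cutoff in TPM units plus the membership rule.

    ``mean`` keeps genes whose mean TPM across all samples exceeds the
    threshold; ``all``/``any`` require every / at least one sample to
    exceed it.
    """

    threshold: float
    rule: str = "mean"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise DataError("filter threshold must be positive")
        if self.rule not in ("mean", "all", "any"):
            raise DataError(f"unknown filter rule {self.rule!r}")


def _validate_values(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 10:
        raise FitError(f"need >= 10 values to fit, got {x.size}")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise FitError("all values must be positive and finite")
    if np.ptp(x) == 0:
        raise FitError("zero-variance sample")
    return x


def fit_family(values, family: str) -> FitResult:
    """Deterministic maximum-likelihood fit of one family.

    Locations are pinned (at zero, or at ``min(values)`` for Pareto) so
    the free parameters are shape/scale only; optimizer-based fits start
    from moment-style guesses and are therefore reproducible.
    """
    x = _validate_values(values)
    n = x.size
    if family not in FAMILIES:
        raise FitError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")

    if family == "lognormal":
        logs = np.log(x)
        mu = float(logs.mean())
        sigma = float(logs.std(ddof=0))  # ML variance
        params = {"mu": mu, "sigma": sigma}
    elif family == "pareto":
        xm = float(x.min())
        b = float(n / np.sum(np.log(x / xm)))
        params = {"b": b, "scale": xm}
    elif family == "weibull":
        c, _, scale = stats.weibull_min.fit(x, floc=0)
        params = {"c": float(c), "scale": float(scale)}
    elif family == "loglogistic":
        c, _, scale = stats.fisk.fit(x, floc=0)
        params = {"c": float(c), "scale": float(scale)}
    else:  # burr (type XII), shape pair (c, d) plus scale
        c, d, _, scale = stats.burr12.fit(
            x, 1.5, 1.0, floc=0, scale=float(np.median(x))
        )
        params = {"c": float(c), "d": float(d), "scale": float(scale)}

    k = FAMILIES[family]
    fit = FitResult(family, params, loglik=0.0, aic=0.0, n=n)
    loglik = float(fit.frozen().logpdf(x).sum())
    if not np.isfinite(loglik):
        raise FitError(f"{family} fit has non-finite likelihood on these data")
    return FitResult(family, params, loglik=loglik, aic=2 * k - 2 * loglik, n=n)


def select_best_family(values, families=None) -> FitResult:
    """Fit each candidate family and return the one with minimal AIC.

    Ties go to the family with fewer free parameters, then to the
    lexicographically first name.
    """
    families = list(families) if families is not None else sorted(FAMILIES)
    if not families:
        raise FitError("need at least one candidate family")
    fits: list[FitResult] = []
    failures: dict[str, str] = {}
    for fam in families:
        try:
            fits.append(fit_family(values, fam))
        except FitError as exc:
            failures[fam] = str(exc)
    if not fits:
        detail = "; ".join(f"{fam}: {msg}" for fam, msg in failures.items())
        raise FitError(f"all distribution fits failed ({detail})")
    return min(fits, key=lambda f: (f.aic, FAMILIES[f.family], f.family))


def lower_tail_threshold(values, fit: FitResult, grid_size: int = 2048) -> FilterSpec:
    """Derive the low-expression cutoff from the lower-tail density crossing.

    Both densities are compared in log10-expression space: the empirical
    density is a Gaussian KDE (Silverman bandwidth) of log10 values, the
    fitted density is the model pdf transformed to log10 coordinates.
    The threshold is the lowest point below the fitted mode where the
    two curves cross (empirical minus fitted changes sign), mapped back
    to TPM.  With no crossing below the mode the minimum value is
    returned, i.e. nothing is filtered.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 50:
        raise FitError(f"need >= 50 values for a stable density estimate, got {x.size}")
    if np.any(x <= 0):
        raise FitError("all values must be positive")
    y = np.log10(x)
    if np.ptp(y) == 0:
        raise FitError("zero-variance sample")

    kde = stats.gaussian_kde(y, bw_method="silverman")
    dist = fit.frozen()
    ln10 = np.log(10.0)

    ys = np.linspace(y.min(), y.max(), grid_size)
    fitted = dist.pdf(10.0**ys) * 10.0**ys * ln10
    mode_idx = int(np.argmax(fitted))
    if mode_idx == 0:  # fitted density decreasing from the left edge
        return FilterSpec(threshold=float(x.min()), rule="mean")

    empirical = kde(ys[: mode_idx + 1])
    diff = empirical - fitted[: mode_idx + 1]
    sign = np.sign(diff)
    crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if crossings.size == 0:
        return FilterSpec(threshold=float(x.min()), rule="mean")
    i = int(crossings[0])
    # linear interpolation of the sign change position
    y0, y1 = ys[i], ys[i + 1]
    d0, d1 = diff[i], diff[i + 1]
    y_cross = y0 + (y1 - y0) * (d0 / (d0 - d1))
    return FilterSpec(threshold=float(10.0**y_cross), rule="mean")


def filter_low_expression(em: ExpressionMatrix, spec: FilterSpec) -> ExpressionMatrix:
    """Drop genes below the TPM threshold under the given membership rule."""
    em.require_scale("linear")
    vals = em.values.to_numpy(float)
    if spec.rule == "mean":
        keep = vals.mean(axis=1) > spec.threshold
    elif spec.rule == "all":
        keep = (vals > spec.threshold).all(axis=1)
    else:  # any
        keep = (vals > spec.threshold).any(axis=1)
    if not keep.any():
        raise DataError(
            f"no genes pass filter (threshold {spec.threshold} TPM, rule {spec.rule})"
        )
    return ExpressionMatrix(em.values.loc[keep].copy(), em.scale, em.design)
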