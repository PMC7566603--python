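"""Scatter-overlay differential-expression calling.

Each gene is a dot of radius ``dot_size`` (in log10-TPM data units) in
a 2D expression scatter.  The between-replicate scatters of the two
compared conditions form the null cloud; a gene is differentially
expressed when, in every one of the four replicate-by-replicate
between-condition scatters, its dot does not overlap any dot of the
null cloud.  Two dots overlap when their center distance is at most
``2 * dot_size`` (touching counts).

The dot size is the method's single tuning knob.  It is swept over a
grid and chosen as the smallest size at which the between-condition
noise of the *non*-DE genes drops to the within-condition replicate
noise baseline: at that point everything left in the non-DE set
scatters no more than replicates do.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import DataError
from .io import ExpressionMatrix, log10_transform, select_replicate_pair
from .noise import gene_pair_noise, transcriptome_noise

__all__ = [
    "ScatterCloud",
    "OverlayResult",
    "SweepTable",
    "DotSizeSelection",
    "DEFAULT_DOT_SIZE_GRID",
    "build_replicate_cloud",
    "build_condition_points",
    "is_overlapped",
    "call_de",
    "sweep_dot_sizes",
    "select_dot_size",
]

DEFAULT_DOT_SIZE_GRID: tuple[float, ...] = (
    0.001, 0.002, 0.003, 0.004, 0.005, 0.006, 0.007, 0.008, 0.009, 0.015,
)

_METRIC_P = {"euclidean": 2.0, "chebyshev": np.inf}

COMBOS: tuple[tuple[int, int], ...] = ((1, 1), (1, 2), (2, 1), (2, 2))
"""The four replicate-by-replicate pairings of two conditions."""


@dataclass(frozen=True)
class ScatterCloud:
    """One labeled set of 2D points (one point per gene) in log10-TPM."""

    points: pd.DataFrame  # index gene_id, columns u, v
    label: str

    def __post_init__(self) -> None:
        if list(self.points.columns) != ["u", "v"]:
            raise DataError("cloud points need columns ['u', 'v']")
        if len(self.points) and not np.all(
            np.isfinite(self.points.to_numpy(dtype=float))
        ):
            raise DataError("cloud coordinates must be finite")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def xy(self) -> np.ndarray:
        return self.points.to_numpy(dtype=float).reshape(-1, 2)


@dataclass
class OverlayResult:
    """Per-gene overlap flags (one per combination) and the DE call."""

    dot_size: float
    table: pd.DataFrame  # columns overlap_11.. overlap_22 (bool), de (bool)

    @property
    def de_count(self) -> int:
        return int(self.table["de"].sum())

    @property
    def de_genes(self) -> list[str]:
        return list(self.table.index[self.table["de"]])


@dataclass
class SweepTable:
    """Dot-size sweep: DE count and DE / non-DE noise per size."""

    rows: pd.DataFrame  # columns dot_size, de_count, de_noise, nonde_noise


@dataclass(frozen=True)
class DotSizeSelection:
    """Outcome of the replicate-noise dot-size calibration.

    ``qualified`` is False when no swept size brought the non-DE noise
    down to the baseline and the largest size was returned instead.
    """

    dot_size: float
    qualified: bool
    baseline: float


def _pairs_for(
    em: ExpressionMatrix,
    conditions: tuple[str, str] | list[str],
    pairs: dict[str, tuple[str, str]] | None,
) -> dict[str, tuple[str, str]]:
    out = {}
    for cond in conditions:
        if pairs is not None and cond in pairs:
            out[cond] = tuple(pairs[cond])
        else:
            out[cond] = select_replicate_pair(em, cond)
    return out


def build_replicate_cloud(
    em: ExpressionMatrix,
    condition: str,
    pair: tuple[str, str] | None = None,
) -> ScatterCloud:
    """Replicate-1 vs replicate-2 log10-TPM scatter for one condition."""
    em.require_scale("log10")
    if pair is None:
        pair = select_replicate_pair(em, condition)
    a, b = pair
    pts = pd.DataFrame(
        {"u": em.values[a].to_numpy(float), "v": em.values[b].to_numpy(float)},
        index=em.values.index,
    )
    return ScatterCloud(pts, label=f"replicate_cloud[{condition}]")


def build_condition_points(
    em: ExpressionMatrix,
    cond1: str,
    cond2: str,
    pairs: dict[str, tuple[str, str]] | None = None,
) -> dict[tuple[int, int], ScatterCloud]:
    """The four between-condition scatters, one per replicate pairing.

    Combination ``(a, b)`` plots cond1-replicate-a against
    cond2-replicate-b.
    """
    em.require_scale("log10")
    pairs = _pairs_for(em, (cond1, cond2), pairs)
    out: dict[tuple[int, int], ScatterCloud] = {}
    for a, b in COMBOS:
        s1 = pairs[cond1][a - 1]
        s2 = pairs[cond2][b - 1]
        pts = pd.DataFrame(
            {"u": em.values[s1].to_numpy(float), "v": em.values[s2].to_numpy(float)},
            index=em.values.index,
        )
        out[(a, b)] = ScatterCloud(pts, label=f"combo({a},{b})")
    return out


def _nearest_distances(
    query_xy: np.ndarray, cloud_xy: np.ndarray, metric: str
) -> np.ndarray:
    """Distance from each query point to its nearest cloud point."""
    if metric not in _METRIC_P:
        raise DataError(f"unknown metric {metric!r}")
    if cloud_xy.shape[0] == 0:
        return np.full(query_xy.shape[0], np.inf)
    tree = cKDTree(cloud_xy)
    dist, _ = tree.query(query_xy, k=1, p=_METRIC_P[metric])
    return np.asarray(dist, dtype=float)


def is_overlapped(
    p, cloud: ScatterCloud, dot_size: float, metric: str = "euclidean"
) -> bool:
    """True when the dot at ``p`` overlaps (or touches) any cloud dot."""
    if dot_size <= 0:
        raise DataError("dot_size must be positive")
    if len(cloud) == 0:
        return False
    d = _nearest_distances(np.asarray(p, float).reshape(1, 2), cloud.xy, metric)
    return bool(d[0] <= 2.0 * dot_size)


def _combo_distances(
    combo_clouds: dict[tuple[int, int], ScatterCloud],
    rep_clouds: tuple[ScatterCloud, ScatterCloud],
    metric: str = "euclidean",
) -> tuple[pd.Index, dict[tuple[int, int], np.ndarray]]:
    """Nearest null-cloud distance for every gene in every combination.

    Overlap at any dot size *s* is then just ``distance <= 2 s``, which
    makes the dot-size sweep a set of threshold comparisons on one
    distance computation and makes DE sets nested across sizes by
    construction.
    """
    genes = rep_clouds[0].points.index
    for cloud in (rep_clouds[1], *combo_clouds.values()):
        if not genes.equals(cloud.points.index):
            raise DataError("gene-set mismatch between clouds")
    null_xy = np.vstack([rep_clouds[0].xy, rep_clouds[1].xy])
    dists = {
        combo: _nearest_distances(cloud.xy, null_xy, metric)
        for combo, cloud in combo_clouds.items()
    }
    return genes, dists


def call_de(
    combo_clouds: dict[tuple[int, int], ScatterCloud],
    rep_clouds: tuple[ScatterCloud, ScatterCloud],
    dot_size: float,
    metric: str = "euclidean",
) -> OverlayResult:
    """DE call at one dot size.

    A gene is DE iff in all four combinations its between-condition
    point overlaps no point of the union of the two replicate clouds.
    Genes are not excluded from the null cloud when testing their own
    combination points.
    """
    if dot_size <= 0:
        raise DataError("dot_size must be positive")
    genes, dists = _combo_distances(combo_clouds, rep_clouds, metric)
    table = pd.DataFrame(index=genes)
    de = np.ones(len(genes), dtype=bool)
    for (a, b), d in sorted(dists.items()):
        overlapped = d <= 2.0 * dot_size
        table[f"overlap_{a}{b}"] = overlapped
        de &= ~overlapped
    table["de"] = de
    return OverlayResult(dot_size=dot_size, table=table)


def _combo_noise(
    em_linear: ExpressionMatrix,
    pairs: dict[str, tuple[str, str]],
    cond1: str,
    cond2: str,
) -> dict[tuple[int, int], np.ndarray]:
    """Per-gene between-condition eta2 for each replicate combination."""
    out = {}
    for a, b in COMBOS:
        s1 = pairs[cond1][a - 1]
        s2 = pairs[cond2][b - 1]
        out[(a, b)] = gene_pair_noise(
            em_linear.values[s1].to_numpy(), em_linear.values[s2].to_numpy()
        )
    return out


def _subset_noise(
    combo_eta: dict[tuple[int, int], np.ndarray], mask: np.ndarray
) -> float:
    """Mean eta2 of the masked genes, averaged over the 4 combinations."""
    if not mask.any():
        return float("nan")
    return float(np.mean([transcriptome_noise(eta[mask]) for eta in combo_eta.values()]))


def sweep_dot_sizes(
    em: ExpressionMatrix,
    comparison: tuple[str, str],
    grid=DEFAULT_DOT_SIZE_GRID,
    metric: str = "euclidean",
    pairs: dict[str, tuple[str, str]] | None = None,
    floor: float = 1e-3,
) -> SweepTable:
    """DE count and DE / non-DE between-condition noise per dot size.

    ``em`` is a linear-scale (TPM) matrix; overlap runs on its log10
    transform, noise on the TPM values.  Returns one row per grid size.
    """
    em.require_scale("linear")
    grid = [float(s) for s in grid]
    if not grid:
        raise DataError("empty dot-size grid")
    if any(s <= 0 for s in grid) or sorted(grid) != grid:
        raise DataError("dot-size grid must be positive and sorted ascending")
    cond1, cond2 = comparison
    pairs = _pairs_for(em, comparison, pairs)
    em_log = log10_transform(em, floor=floor)
    rep_clouds = (
        build_replicate_cloud(em_log, cond1, pairs[cond1]),
        build_replicate_cloud(em_log, cond2, pairs[cond2]),
    )
    combo_clouds = build_condition_points(em_log, cond1, cond2, pairs)
    _, dists = _combo_distances(combo_clouds, rep_clouds, metric)
    combo_eta = _combo_noise(em, pairs, cond1, cond2)

    rows = []
    for s in grid:
        de = np.ones(len(em.values), dtype=bool)
        for d in dists.values():
            de &= d > 2.0 * s
        rows.append(
            {
                "dot_size": s,
                "de_count": int(de.sum()),
                "de_noise": _subset_noise(combo_eta, de),
                "nonde_noise": _subset_noise(combo_eta, ~de),
            }
        )
    return SweepTable(pd.DataFrame(rows))


def select_dot_size(sweep: SweepTable, baseline: float) -> DotSizeSelection:
    """Smallest swept size whose non-DE noise is at or below the
    replicate baseline; falls back to the largest size (unqualified)
    when none reaches it."""
    rows = sweep.rows
    if rows.empty:
        raise DataError("empty sweep table")
    if baseline < 0:
        raise DataError("baseline must be non-negative")
    ok = rows["nonde_noise"] <= baseline
    if ok.any():
        return DotSizeSelection(
            dot_size=float(rows.loc[ok, "dot_size"].iloc[0]),
            qualified=True,
            baseline=float(baseline),
        )
    return DotSizeSelection(
        dot_size=float(rows["dot_size"].iloc[-1]),
        qualified=False,
        baseline=float(baseline),
    )
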