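"""Static overlay plot: replicate clouds, condition points, DE genes.

Dots are drawn with their radius in *data* units (log10-TPM), matching
the geometry the overlap test uses, so the rendered figure shows the
exact configuration the caller decided on.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.collections import EllipseCollection  # noqa: E402
import numpy as np  # noqa: E402

from .errors import DataError
from .overlay import OverlayResult, ScatterCloud

__all__ = ["render_overlay"]

_REP_COLOR = "#9e9e9e"
_NONDE_COLOR = "#f5a623"  # orange
_DE_COLOR = "#2e9e4f"  # green


def _add_dots(ax, xy: np.ndarray, dot_size: float, color: str, gid: str) -> None:
    if xy.shape[0] == 0:
        return
    coll = EllipseCollection(
        widths=2 * dot_size,
        heights=2 * dot_size,
        angles=0,
        units="xy",
        offsets=xy,
        offset_transform=ax.transData,
        facecolors=color,
        edgecolors="none",
        alpha=0.8,
    )
    coll.set_gid(gid)
    ax.add_collection(coll)


def render_overlay(
    rep_clouds: tuple[ScatterCloud, ScatterCloud],
    combo_clouds: dict,
    result: OverlayResult,
    dot_size: float,
    path: str | Path,
) -> Path:
    """Write an SVG/PNG overlay figure.

    Replicate clouds are grey, non-DE condition points orange, DE genes
    green; glyph groups carry stable SVG ids (``rep-cloud-1``,
    ``rep-cloud-2``, ``combo-<a><b>-nonde``, ``combo-<a><b>-de``).
    """
    path = Path(path)
    if not path.parent.exists():
        raise DataError(f"output directory does not exist: {path.parent}")
    de_mask = result.table["de"].to_numpy(bool)

    fig, ax = plt.subplots(figsize=(6, 6))
    for i, cloud in enumerate(rep_clouds, start=1):
        _add_dots(ax, cloud.xy, dot_size, _REP_COLOR, f"rep-cloud-{i}")
    for (a, b), cloud in sorted(combo_clouds.items()):
        xy = cloud.xy
        _add_dots(ax, xy[~de_mask], dot_size, _NONDE_COLOR, f"combo-{a}{b}-nonde")
        _add_dots(ax, xy[de_mask], dot_size, _DE_COLOR, f"combo-{a}{b}-de")

    all_xy = np.vstack(
        [c.xy for c in rep_clouds] + [c.xy for c in combo_clouds.values()]
    )
    pad = 0.1 + 2 * dot_size
    ax.set_xlim(all_xy[:, 0].min() - pad, all_xy[:, 0].max() + pad)
    ax.set_ylim(all_xy[:, 1].min() - pad, all_xy[:, 1].max() + pad)
    ax.set_aspect("equal")
    ax.set_xlabel("log10(TPM)")
    ax.set_ylabel("log10(TPM)")
    ax.set_title(
        f"overlay at dot size {dot_size:g} — {int(de_mask.sum())} DE genes"
    )
    fig.savefig(path)
    plt.close(fig)
    return path
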