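"""Normalized-cell heatmaps, difference maps and pole-proximity statistics.

Positions from many cells are pooled in normalized coordinates (l, w) and
binned into a 2D histogram; for track data one spatial sample per track
(its first localization) is used so long tracks are not over-weighted.
Maps can be restricted to the immobile or mobile fraction via the D*
threshold, and an immobile-minus-mobile difference map (each map first
normalized to unit mass) highlights where chromosome-bound molecules are
over- or under-represented.

The *exterior fraction* is the share of localizations whose folded
long-axis coordinate min(l, 1-l) is within ``cutoff`` (default 0.25) of
the nearest pole; a uniform distribution gives exactly 0.5 at the default
cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CellGeometry, normalize_xy

__all__ = [
    "Heatmap",
    "build_heatmap",
    "difference_map",
    "long_axis_profile",
    "exterior_fraction",
    "project_and_exterior",
    "fold",
]

DEFAULT_BINS = (50, 25)  # (long axis, short axis)


@dataclass
class Heatmap:
    """2D histogram of pooled normalized positions."""

    counts: np.ndarray
    bins_l: np.ndarray
    bins_w: np.ndarray
    n_cells: int
    length_window: tuple[float, float] | None = None
    mobility_class: str = "all"

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        """Counts normalized to unit total mass."""
        t = self.total
        return self.counts / t if t > 0 else self.counts


def fold(l) -> np.ndarray:
    """Folded long-axis coordinate min(l, 1 - l), pooling both cell ends."""
    l = np.asarray(l, dtype=float)
    return np.minimum(l, 1.0 - l)


def build_heatmap(
    positions: pd.DataFrame,
    cells: dict | CellGeometry,
    length_window: tuple[float, float] | None = None,
    mobility_class: str = "all",
    bins: tuple[int, int] = DEFAULT_BINS,
    dstar_threshold: float = 0.16,
) -> Heatmap:
    """Pool normalized positions from many cells into a heatmap.

    Parameters
    ----------
    positions
        Localization table with ``x_um, y_um`` and optionally ``cell_id``,
        ``track_id`` and ``D_star``.  If ``track_id`` is present, only the
        first localization of each track contributes.
    cells
        Either one :class:`CellGeometry` shared by all rows or a mapping
        ``cell_id -> CellGeometry``.
    length_window
        Keep only cells whose length lies in ``[lo, hi]`` μm (used to select
        single- vs double-nucleoid cells).
    mobility_class
        ``"all"``, ``"immobile"`` or ``"mobile"``; the latter two require a
        ``D_star`` column and use the inclusive threshold convention.
    """
    df = positions
    if "track_id" in df.columns:
        df = df.sort_values("frame", kind="stable") if "frame" in df.columns else df
        keys = [c for c in ("cell_id", "track_id") if c in df.columns]
        df = df.groupby(keys, as_index=False, sort=False).first()
    if mobility_class != "all":
        if "D_star" not in df.columns:
            raise ValueError("mobility_class selection requires a D_star column")
        imm = df["D_star"] <= dstar_threshold
        df = df[imm] if mobility_class == "immobile" else df[~imm]

    def cell_of(cid) -> CellGeometry:
        return cells if isinstance(cells, CellGeometry) else cells[cid]

    ls, ws = [], []
    n_cells = 0
    if "cell_id" in df.columns and not isinstance(cells, CellGeometry):
        groups = df.groupby("cell_id")
    else:
        groups = [(0, df)]
    for cid, grp in groups:
        cell = cell_of(cid)
        if length_window is not None and not (
            length_window[0] <= cell.length <= length_window[1]
        ):
            continue
        l, w = normalize_xy(grp[["x_um", "y_um"]].to_numpy(), cell)
        ls.append(l)
        ws.append(w)
        n_cells += 1
    edges_l = np.linspace(0.0, 1.0, bins[0] + 1)
    edges_w = np.linspace(0.0, 1.0, bins[1] + 1)
    if not ls:
        warnings.warn("no cells in the selection; empty heatmap", RuntimeWarning)
        counts = np.zeros((bins[0], bins[1]))
    else:
        counts, _, _ = np.histogram2d(
            np.concatenate(ls), np.concatenate(ws), bins=(edges_l, edges_w)
        )
    return Heatmap(
        counts=counts,
        bins_l=edges_l,
        bins_w=edges_w,
        n_cells=n_cells,
        length_window=length_window,
        mobility_class=mobility_class,
    )


def difference_map(h_immobile: Heatmap, h_mobile: Heatmap) -> np.ndarray:
    """Unit-normalized immobile minus mobile map; sums to zero."""
    if h_immobile.counts.shape != h_mobile.counts.shape or not np.allclose(
        h_immobile.bins_l, h_mobile.bins_l
    ):
        raise ValueError("heatmaps must share identical binning")
    return h_immobile.normalized() - h_mobile.normalized()


def long_axis_profile(heatmap: Heatmap) -> np.ndarray:
    """Marginal of the heatmap over the long axis (sums to the total)."""
    return heatmap.counts.sum(axis=1)


def short_axis_profile(heatmap: Heatmap) -> np.ndarray:
    return heatmap.counts.sum(axis=0)


def exterior_fraction(l, cutoff: float = 0.25) -> float:
    """Fraction of positions with folded long-axis coordinate <= cutoff."""
    if not 0.0 < cutoff < 0.5:
        raise ValueError(f"cutoff must be in (0, 0.5), got {cutoff}")
    lf = fold(l)
    if len(lf) == 0:
        raise ValueError("no positions")
    return float(np.mean(lf <= cutoff))


def folded_profile(l, bins: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of the folded long-axis coordinate on [0, 0.5]."""
    counts, edges = np.histogram(fold(l), bins=bins, range=(0.0, 0.5))
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, counts


def project_and_exterior(
    source, axis: str = "long", cutoff: float = 0.25
) -> tuple[np.ndarray, float]:
    """Axis profile plus exterior fraction.

    ``source`` is either a :class:`Heatmap` (profile from bin marginals,
    exterior fraction from folded bin centres) or an array of normalized
    long-axis coordinates.
    """
    if not 0.0 < cutoff < 0.5:
        raise ValueError(f"cutoff must be in (0, 0.5), got {cutoff}")
    if isinstance(source, Heatmap):
        if axis == "long":
            profile = long_axis_profile(source)
            centers = 0.5 * (source.bins_l[1:] + source.bins_l[:-1])
            total = profile.sum()
            frac = float(profile[fold(centers) <= cutoff].sum() / total) if total else np.nan
        elif axis == "short":
            profile = short_axis_profile(source)
            frac = np.nan
        else:
            raise ValueError(f"unknown axis {axis!r}")
        return profile, frac
    l = np.asarray(source, dtype=float)
    counts, _ = np.histogram(l, bins=50, range=(0.0, 1.0))
    return counts, exterior_fraction(l, cutoff)
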