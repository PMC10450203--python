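"""Spherocylindrical cell and prolate-spheroid nucleoid geometry.

Coordinate conventions used throughout the package:

* **Physical** coordinates are in micrometres, with the origin at the cell
  centre and ``x`` along the long (pole-to-pole) axis.  The cell boundary is
  a spherocylinder: a cylinder of length ``L - W`` capped by hemispheres of
  radius ``W/2``.
* **Normalized** coordinates ``(l, w)`` lie in ``[0, 1]``; ``l = 0`` and
  ``l = 1`` are the poles, ``w = 0.5`` is the long axis.  The folded
  coordinate ``l_folded = min(l, 1 - l)`` pools both cell ends, so a uniform
  distribution has exactly half of its mass within ``l_folded <= 0.25``.

The nucleoid is modelled as a prolate spheroid with long semi-axis
``L/2 - pole_gap`` (a 150 nm nucleoid-to-pole separation by default) and
short semi-axis ``0.75 * W/2``, matching the 75% length/width shrink used to
estimate the nucleoid area from the cell outline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "CellGeometry",
    "NormalizedPosition",
    "GeometryError",
    "OutOfCellError",
    "normalize_position",
    "normalize_xy",
    "denormalize_xy",
    "sample_uniform",
    "sample_uniform_area",
    "spherocylinder_area",
]


class GeometryError(ValueError):
    """Invalid cell geometry (e.g. length not exceeding width)."""


class OutOfCellError(ValueError):
    """A physical position lies outside the cell boundary."""


@dataclass(frozen=True)
class CellGeometry:
    """Spherocylindrical cell with an inset prolate-spheroid nucleoid.

    Parameters
    ----------
    length
        Pole-to-pole cell length L in micrometres.
    width
        Cell diameter W in micrometres; must satisfy ``L > W > 0``.
    pole_gap
        Separation between the nucleoid tip and the cell pole along the long
        axis (micrometres).
    nucleoid_shrink
        ``(length_scale, width_scale)`` used both for the nucleoid-area
        estimate in 2D and for the nucleoid short semi-axis in 3D.
    """

    length: float
    width: float
    pole_gap: float = 0.150
    nucleoid_shrink: tuple[float, float] = (0.75, 0.75)

    def __post_init__(self) -> None:
        if not (self.length > self.width > 0):
            raise GeometryError(
                f"need length > width > 0, got L={self.length}, W={self.width}"
            )
        if self.pole_gap < 0 or 2 * self.pole_gap >= self.length:
            raise GeometryError(
                f"need 0 <= 2*pole_gap < length, got pole_gap={self.pole_gap}"
            )

    # -- derived dimensions -------------------------------------------------

    @property
    def radius(self) -> float:
        return self.width / 2.0

    @property
    def nucleoid_semi_long(self) -> float:
        """Long semi-axis of the nucleoid spheroid (μm)."""
        return self.length / 2.0 - self.pole_gap

    @property
    def nucleoid_semi_short(self) -> float:
        """Short semi-axis of the nucleoid spheroid (μm)."""
        return self.nucleoid_shrink[1] * self.radius

    @property
    def volume(self) -> float:
        """Cell volume (μm³): cylinder plus two hemispherical caps."""
        r = self.radius
        return np.pi * r**2 * (self.length - self.width) + 4.0 / 3.0 * np.pi * r**3

    @property
    def nucleoid_volume(self) -> float:
        a, b = self.nucleoid_semi_long, self.nucleoid_semi_short
        return 4.0 / 3.0 * np.pi * a * b * b

    # -- membership ---------------------------------------------------------

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        """Boolean mask of points inside the cell boundary.

        ``points`` has shape ``(..., 2)`` or ``(..., 3)``; 2D points are
        treated as lying in the mid-plane (z = 0).
        """
        p = np.atleast_2d(np.asarray(points, dtype=float))
        half_cyl = self.length / 2.0 - self.radius
        dx = np.maximum(np.abs(p[..., 0]) - half_cyl, 0.0)
        rad2 = dx**2 + p[..., 1] ** 2
        if p.shape[-1] == 3:
            rad2 = rad2 + p[..., 2] ** 2
        mask = rad2 <= (self.radius + tol) ** 2
        return mask if np.asarray(points).ndim > 1 else bool(mask[0])

    def contains_nucleoid(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of 3D points inside the nucleoid spheroid."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        a, b = self.nucleoid_semi_long, self.nucleoid_semi_short
        q = (p[..., 0] / a) ** 2 + (p[..., 1] / b) ** 2
        if p.shape[-1] == 3:
            q = q + (p[..., 2] / b) ** 2
        mask = q <= 1.0
        return mask if np.asarray(points).ndim > 1 else bool(mask[0])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "length_um": self.length,
            "width_um": self.width,
            "pole_gap_um": self.pole_gap,
            "nucleoid_shrink": list(self.nucleoid_shrink),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellGeometry":
        return cls(
            length=float(d["length_um"]),
            width=float(d["width_um"]),
            pole_gap=float(d.get("pole_gap_um", 0.150)),
            nucleoid_shrink=tuple(d.get("nucleoid_shrink", (0.75, 0.75))),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, text: str) -> "CellGeometry":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class NormalizedPosition:
    """Position in cell-normalized coordinates; see module docstring."""

    l: float
    w: float

    @property
    def l_folded(self) -> float:
        return min(self.l, 1.0 - self.l)


def normalize_position(
    point, cell: CellGeometry, tol: float = 1e-3
) -> NormalizedPosition:
    """Map a physical 2D point (μm, origin at cell centre) to ``(l, w)``.

    Raises :class:`OutOfCellError` if the point is outside the boundary by
    more than ``tol`` μm (default 1e-3 μm, i.e. 1 nm).
    """
    x, y = float(point[0]), float(point[1])
    if not cell.contains((x, y), tol=tol):
        axis = "x" if abs(x) > cell.length / 2 else "y"
        raise OutOfCellError(
            f"point ({x:.4f}, {y:.4f}) μm outside cell "
            f"L={cell.length}, W={cell.width} (offending coordinate: {axis})"
        )
    l = (x + cell.length / 2.0) / cell.length
    w = (y + cell.width / 2.0) / cell.width
    return NormalizedPosition(l=l, w=w)


def normalize_xy(points: np.ndarray, cell: CellGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized physical → normalized map (no containment check)."""
    p = np.asarray(points, dtype=float)
    l = (p[..., 0] + cell.length / 2.0) / cell.length
    w = (p[..., 1] + cell.width / 2.0) / cell.width
    return l, w


def denormalize_xy(l, w, cell: CellGeometry) -> np.ndarray:
    """Inverse of :func:`normalize_xy`; returns stacked ``(..., 2)`` array."""
    x = np.asarray(l, dtype=float) * cell.length - cell.length / 2.0
    y = np.asarray(w, dtype=float) * cell.width - cell.width / 2.0
    return np.stack([x, y], axis=-1)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_uniform(
    region: str,
    cell: CellGeometry,
    n: int,
    seed=None,
    project: bool = False,
) -> np.ndarray:
    """Rejection-sample ``n`` points uniformly in a 3D cell region.

    Parameters
    ----------
    region
        ``"cell"`` (spherocylinder) or ``"nucleoid"`` (prolate spheroid).
    project
        If true, drop the z dimension and return 2D points; the long-axis
        coordinate is preserved exactly.
    seed
        Integer seed or :class:`numpy.random.Generator`.
    """
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    rng = _as_rng(seed)
    if region == "cell":
        half = (cell.length / 2.0, cell.radius, cell.radius)
        inside = cell.contains
    elif region == "nucleoid":
        half = (cell.nucleoid_semi_long, cell.nucleoid_semi_short, cell.nucleoid_semi_short)
        inside = cell.contains_nucleoid
    else:
        raise ValueError(f"unknown region {region!r}")
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        m = max(int((n - filled) * 2.2), 64)
        cand = rng.uniform(-1.0, 1.0, size=(m, 3)) * np.asarray(half)
        keep = cand[inside(cand)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out[:, :2] if project else out


def spherocylinder_area(length: float, width: float) -> float:
    """2D footprint area of a spherocylinder (rectangle + disc)."""
    r = width / 2.0
    return (length - width) * width + np.pi * r**2


def sample_uniform_area(
    cell: CellGeometry,
    n: int,
    seed=None,
    shrink: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Sample ``n`` points uniformly in the (optionally shrunk) 2D footprint.

    With ``shrink=(0.75, 0.75)`` this is the nucleoid-area estimate used for
    co-localization nulls: the cell outline scaled to 75% in both length and
    width.  Uniform-in-area sampling, not a projection of the 3D volume.
    """
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    rng = _as_rng(seed)
    sl, sw = shrink
    half = (sl * cell.length / 2.0, sw * cell.radius)
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(int((n - filled) * 1.6), 64)
        cand = rng.uniform(-1.0, 1.0, size=(m, 2)) * np.asarray(half)
        # membership of the anisotropically scaled footprint
        unscaled = cand / np.asarray([sl, sw])
        keep = cand[cell.contains(unscaled)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out
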