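"""Synthetic-data generators.

Two generators live here:

* :func:`simulate_cell` — the four-population Monte-Carlo model of RNAP
  localizations in a single cell: molecules are split into *mobile*
  (uniform in the nucleoid), *rrn*-bound (Gaussian clusters on the
  pole-proximal nucleoid periphery, one cluster centre per rrn operon),
  *small-cluster* (Gaussian clusters at uniform nucleoid positions with
  exponentially distributed sizes) and *noise* (uniform in the whole cell
  volume).  The 3D positions are projected to 2D, mimicking fixed-cell
  PALM point patterns.

* :func:`simulate_tracks` — a two-species Brownian track generator for the
  mobility pipeline: per-track species membership is Bernoulli, steps are
  Gaussian with per-axis variance ``2 D dt``, and an independent Gaussian
  localization error is added to every localization.  The expected apparent
  diffusion coefficient of a species is ``D_true + sigma_loc**2 / dt``.

A small frame renderer (:func:`render_frames`) turns localization lists
into Poisson-noisy image stacks for exercising the detection/fitting code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .geometry import CellGeometry, sample_uniform

__all__ = [
    "ClusterSizeModel",
    "SimulationConfig",
    "TrackSimConfig",
    "RRN_OFFSETS_KB",
    "ARM_LENGTH_KB",
    "STRAIN_OPERONS",
    "PlacementError",
    "sample_cluster_sizes",
    "place_rrn_sites",
    "simulate_cell",
    "simulate_cells",
    "simulate_tracks",
    "tracks_to_dataframe",
    "render_frames",
    "wt_config",
    "delta5_config",
    "delta6_config",
]

#: Genomic distance of each rrn operon from oriC, kb (MG1655 annotation).
RRN_OFFSETS_KB = {
    "rrnC": 42.0,
    "rrnA": 110.0,
    "rrnB": 265.0,
    "rrnE": 306.0,
    "rrnD": 497.0,
    "rrnH": 940.0,
    "rrnG": 1196.0,
}

#: Half of the 4.64 Mb chromosome: length of one replication arm, kb.
ARM_LENGTH_KB = 2320.0

#: Operons retained on the chromosome in each strain.
STRAIN_OPERONS = {
    "WT": ["rrnC", "rrnA", "rrnB", "rrnE", "rrnD", "rrnH", "rrnG"],
    "D5": ["rrnC", "rrnB"],
    "D6": ["rrnE"],
}


class PlacementError(RuntimeError):
    """rrn ring placement failed to satisfy the separation constraint."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class ClusterSizeModel:
    """Exponential cluster-size law ``y = a * exp(-b x)``.

    Sizes are drawn by the inverse transform
    ``X = -(1/b) * ln(1 - b u / a)`` with ``u ~ U(0, 1)``; draws with
    ``b u / a >= 1`` are rejected and redrawn, and sizes are rounded to the
    nearest integer and clamped to at least one molecule.
    """

    a: float = 1.0 / 15.0
    b: float = 1.0 / 15.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"need a, b > 0, got a={self.a}, b={self.b}")


def sample_cluster_sizes(model: ClusterSizeModel, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` integer cluster sizes from the exponential size law."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    acceptance = min(model.a / model.b, 1.0)
    if acceptance < 0.01:
        raise ValueError(
            f"inverse transform accepts only {acceptance:.2%} of draws "
            f"(a={model.a}, b={model.b}); unbounded rejection"
        )
    rng = _as_rng(seed)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(int((n - filled) / acceptance * 1.5), 32)
        u = rng.random(m)
        u = u[model.b * u / model.a < 1.0]
        x = -(1.0 / model.b) * np.log1p(-model.b * u / model.a)
        take = min(len(x), n - filled)
        out[filled : filled + take] = x[:take]
        filled += take
    return np.maximum(np.rint(out), 1).astype(int)


def genomic_offset_to_axis(
    offset_kb, cell: CellGeometry, arm_length_kb: float = ARM_LENGTH_KB
) -> np.ndarray:
    """Map genomic distance from oriC to an unsigned long-axis coordinate.

    Linear ori–ter map: oriC (offset 0) sits at the pole-proximal tip of the
    nucleoid, the terminus (offset = arm length) at mid-cell.
    """
    a = cell.nucleoid_semi_long
    return a * (1.0 - np.asarray(offset_kb, dtype=float) / arm_length_kb)


def place_rrn_sites(
    cell: CellGeometry,
    rrn_offsets_kb,
    arm_length_kb: float = ARM_LENGTH_KB,
    min_sep: float = 0.070,
    seed=None,
    max_proposals: int = 10_000,
) -> np.ndarray:
    """Place one 3D cluster centre per rrn operon on the nucleoid surface.

    Each operon's long-axis coordinate is fixed by the genomic-distance map;
    candidate azimuths on the resulting ring around the nucleoid periphery
    are proposed until all pairwise distances are at least ``min_sep``.  All
    sites of one nucleoid share the same (randomly chosen) pole end, since
    oriC is a single pole-proximal locus.
    """
    offsets = np.asarray(rrn_offsets_kb, dtype=float)
    if np.any(offsets < 0) or np.any(offsets > arm_length_kb):
        raise ValueError("offsets must lie in [0, arm_length_kb]")
    if min_sep < 0:
        raise ValueError("min_sep must be >= 0")
    rng = _as_rng(seed)
    a, b = cell.nucleoid_semi_long, cell.nucleoid_semi_short
    pole_sign = 1.0 if rng.random() < 0.5 else -1.0
    xs = pole_sign * genomic_offset_to_axis(offsets, cell, arm_length_kb)
    centers: list[np.ndarray] = []
    for x in xs:
        rho = b * np.sqrt(max(1.0 - (x / a) ** 2, 0.0))
        for _ in range(max_proposals):
            phi = rng.uniform(0.0, 2.0 * np.pi)
            cand = np.array([x, rho * np.cos(phi), rho * np.sin(phi)])
            if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
                centers.append(cand)
                break
        else:
            raise PlacementError(
                f"no placement with separation >= {min_sep} μm after "
                f"{max_proposals} proposals (ring radius {rho:.3f} μm)"
            )
    return np.asarray(centers)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the four-population Monte-Carlo cell model."""

    n_molecules: int = 1800
    f_immobile: float = 0.48
    f_rrn_of_immobile: float = 0.60
    rrn_offsets_kb: tuple[float, ...] = tuple(
        RRN_OFFSETS_KB[o] for o in STRAIN_OPERONS["WT"]
    )
    arm_length_kb: float = ARM_LENGTH_KB
    min_operon_sep: float = 0.070
    cluster_sigma: float = 0.040
    noise_fraction: float = 0.10
    cluster_size_model: ClusterSizeModel = field(default_factory=ClusterSizeModel)
    cell: CellGeometry = field(default_factory=lambda: CellGeometry(3.0, 1.0))
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("f_immobile", "f_rrn_of_immobile", "noise_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")

    @property
    def n_operons_per_nucleoid(self) -> int:
        return len(self.rrn_offsets_kb)

    def population_counts(self) -> dict[str, int]:
        """Exact molecule counts per population (they sum to n_molecules)."""
        n_imm = round(self.f_immobile * self.n_molecules)
        n_rrn = round(self.f_rrn_of_immobile * n_imm)
        n_small = n_imm - n_rrn
        n_mob_total = self.n_molecules - n_imm
        n_noise = round(self.noise_fraction * n_mob_total)
        n_mobile = n_mob_total - n_noise
        return {
            "rrn": n_rrn,
            "small_cluster": n_small,
            "mobile": n_mobile,
            "noise": n_noise,
        }

    def to_dict(self) -> dict:
        return {
            "n_molecules": self.n_molecules,
            "f_immobile": self.f_immobile,
            "f_rrn_of_immobile": self.f_rrn_of_immobile,
            "rrn_offsets_kb": list(self.rrn_offsets_kb),
            "arm_length_kb": self.arm_length_kb,
            "min_operon_sep": self.min_operon_sep,
            "cluster_sigma": self.cluster_sigma,
            "noise_fraction": self.noise_fraction,
            "cluster_size_model": {"a": self.cluster_size_model.a, "b": self.cluster_size_model.b},
            "cell": self.cell.to_dict(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "cluster_size_model" in d:
            d["cluster_size_model"] = ClusterSizeModel(**d["cluster_size_model"])
        if "cell" in d:
            d["cell"] = CellGeometry.from_dict(d["cell"])
        if "rrn_offsets_kb" in d:
            d["rrn_offsets_kb"] = tuple(d["rrn_offsets_kb"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict())

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(text))


def wt_config(**overrides) -> SimulationConfig:
    """Wild-type condition: 1800 molecules, seven chromosomal rrn operons."""
    cfg = SimulationConfig(
        n_molecules=1800,
        rrn_offsets_kb=tuple(RRN_OFFSETS_KB[o] for o in STRAIN_OPERONS["WT"]),
    )
    return replace(cfg, **overrides)


def delta5_config(**overrides) -> SimulationConfig:
    """Δ5 condition: 1800 molecules, only rrnC and rrnB remain."""
    cfg = SimulationConfig(
        n_molecules=1800,
        rrn_offsets_kb=tuple(RRN_OFFSETS_KB[o] for o in STRAIN_OPERONS["D5"]),
    )
    return replace(cfg, **overrides)


def delta6_config(**overrides) -> SimulationConfig:
    """Δ6 condition: 1200 molecules, only rrnE remains."""
    cfg = SimulationConfig(
        n_molecules=1200,
        rrn_offsets_kb=tuple(RRN_OFFSETS_KB[o] for o in STRAIN_OPERONS["D6"]),
    )
    return replace(cfg, **overrides)


def _gaussian_cluster_members(
    center: np.ndarray, n: int, sigma: float, cell: CellGeometry, rng
) -> np.ndarray:
    """Isotropic 3D Gaussian around a centre; out-of-cell draws regenerated."""
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        m = max((n - filled) * 2, 8)
        cand = center + rng.normal(0.0, sigma, size=(m, 3))
        keep = cand[cell.contains(cand)]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def simulate_cell(config: SimulationConfig, seed=None) -> pd.DataFrame:
    """Simulate one cell; returns 2D localizations with population labels.

    Columns: ``x_um, y_um, population`` where population is one of
    ``rrn | small_cluster | mobile | noise``.  Exactly
    ``config.n_molecules`` rows.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    counts = config.population_counts()
    cell = config.cell
    parts: list[tuple[str, np.ndarray]] = []

    # rrn-bound molecules: clusters on the pole-proximal nucleoid periphery
    if counts["rrn"] > 0 and config.n_operons_per_nucleoid > 0:
        sites = place_rrn_sites(
            cell,
            config.rrn_offsets_kb,
            config.arm_length_kb,
            config.min_operon_sep,
            seed=rng,
        )
        alloc = rng.multinomial(
            counts["rrn"], np.full(len(sites), 1.0 / len(sites))
        )
        for site, k in zip(sites, alloc):
            if k:
                parts.append(
                    ("rrn", _gaussian_cluster_members(site, k, config.cluster_sigma, cell, rng))
                )

    # small non-rrn clusters throughout the nucleoid
    if counts["small_cluster"] > 0:
        remaining = counts["small_cluster"]
        while remaining > 0:
            size = min(int(sample_cluster_sizes(config.cluster_size_model, 1, rng)[0]), remaining)
            center = sample_uniform("nucleoid", cell, 1, seed=rng)[0]
            parts.append(
                ("small_cluster", _gaussian_cluster_members(center, size, config.cluster_sigma, cell, rng))
            )
            remaining -= size

    # mobile molecules uniform in the nucleoid; noise uniform in the cell
    if counts["mobile"] > 0:
        parts.append(("mobile", sample_uniform("nucleoid", cell, counts["mobile"], seed=rng)))
    if counts["noise"] > 0:
        parts.append(("noise", sample_uniform("cell", cell, counts["noise"], seed=rng)))

    labels = np.concatenate([[p] * len(xyz) for p, xyz in parts])
    xyz = np.concatenate([xyz for _, xyz in parts])
    return pd.DataFrame(
        {"x_um": xyz[:, 0], "y_um": xyz[:, 1], "population": labels}
    )


def simulate_cells(config: SimulationConfig, n_cells: int, seed=None) -> pd.DataFrame:
    """Simulate ``n_cells`` independent cells; adds a ``cell_id`` column."""
    rng = _as_rng(config.seed if seed is None else seed)
    frames = []
    for i in range(n_cells):
        df = simulate_cell(config, seed=rng)
        df.insert(0, "cell_id", i)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Brownian track generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrackSimConfig:
    """Two-species Brownian track generator parameters.

    ``D_immobile_true`` is the true diffusion coefficient of the
    chromosome-bound species (0 for rigidly bound); the *apparent* D* of that
    species is ``D_immobile_true + loc_error_sigma**2 / dt``.
    """

    n_tracks: int = 10_000
    f_immobile: float = 0.482
    D_immobile_true: float = 0.0
    D_mobile_true: float = 0.28
    loc_error_sigma: float = 0.035
    dt: float = 0.015
    track_length_mean: float = 8.0
    track_length_min: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.D_mobile_true <= 0:
            raise ValueError("D_mobile_true must be positive")
        if self.D_immobile_true < 0 or self.loc_error_sigma < 0:
            raise ValueError("diffusion/noise parameters must be non-negative")
        if self.track_length_min < 5:
            raise ValueError("tracks need at least 5 localizations")

    @property
    def apparent_D_immobile(self) -> float:
        return self.D_immobile_true + self.loc_error_sigma**2 / self.dt

    @property
    def apparent_D_mobile(self) -> float:
        return self.D_mobile_true + self.loc_error_sigma**2 / self.dt


def _track_lengths(config: TrackSimConfig, n: int, rng) -> np.ndarray:
    """Photobleaching-limited lengths: geometric, truncated at the minimum."""
    extra_mean = max(config.track_length_mean - config.track_length_min, 1e-9)
    p = 1.0 / (1.0 + extra_mean)
    return config.track_length_min + rng.geometric(p, size=n) - 1


def simulate_tracks(config: TrackSimConfig, seed=None):
    """Generate two-species Brownian tracks with localization error.

    Returns
    -------
    positions : list of (L_i, 2) arrays
        Localized positions of each track (μm), one frame apart.
    immobile : (n_tracks,) bool array
        Ground-truth species label per track.
    """
    rng = _as_rng(config.seed if seed is None else seed)
    n = config.n_tracks
    if n == 0:
        return [], np.zeros(0, dtype=bool)
    immobile = rng.random(n) < config.f_immobile
    d_true = np.where(immobile, config.D_immobile_true, config.D_mobile_true)
    lengths = _track_lengths(config, n, rng)
    positions = []
    for i in range(n):
        L = lengths[i]
        steps = rng.normal(0.0, np.sqrt(2.0 * d_true[i] * config.dt), size=(L - 1, 2))
        pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        pos += rng.normal(0.0, config.loc_error_sigma, size=pos.shape)
        positions.append(pos)
    return positions, immobile


def simulate_track_array(config: TrackSimConfig, seed=None):
    """Vectorized variant with constant track length ``track_length_min``.

    Returns ``(positions (n, L, 2), immobile (n,) bool)``; used where large
    numbers of short tracks are needed (mobility-recovery experiments).
    """
    rng = _as_rng(config.seed if seed is None else seed)
    n, L = config.n_tracks, config.track_length_min
    immobile = rng.random(n) < config.f_immobile
    d_true = np.where(immobile, config.D_immobile_true, config.D_mobile_true)
    steps = rng.normal(0.0, 1.0, size=(n, L - 1, 2)) * np.sqrt(
        2.0 * d_true * config.dt
    )[:, None, None]
    pos = np.concatenate([np.zeros((n, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    if config.loc_error_sigma > 0:
        pos = pos + rng.normal(0.0, config.loc_error_sigma, size=pos.shape)
    return pos, immobile


def tracks_to_dataframe(positions, immobile=None, dt: float = 0.015) -> pd.DataFrame:
    """Long-format track table: track_id, frame, x_um, y_um [, species]."""
    recs = []
    for tid, pos in enumerate(positions):
        for f, (x, y) in enumerate(pos):
            recs.append((tid, f, x, y))
    df = pd.DataFrame(recs, columns=["track_id", "frame", "x_um", "y_um"])
    if immobile is not None:
        df["species"] = np.asarray(
            ["immobile" if immobile[t] else "mobile" for t in df["track_id"]]
        )
    return df


# ---------------------------------------------------------------------------
# Frame renderer
# ---------------------------------------------------------------------------


def render_frames(
    localizations: pd.DataFrame,
    shape: tuple[int, int],
    psf_sigma: float = 0.13,
    pixel: float = 0.1,
    photons: float = 1000.0,
    background: float = 0.0,
    seed=None,
    poisson_noise: bool = True,
) -> np.ndarray:
    """Render localizations into an image stack of integrated 2D Gaussians.

    ``localizations`` needs columns ``frame, x_um, y_um``; pixel (row, col)
    ``(i, j)`` spans ``[j*pixel, (j+1)*pixel] x [i*pixel, (i+1)*pixel]`` in
    (x, y).  Emitters are integrated over each pixel via erf differences,
    scaled to ``photons`` total counts, background added, and Poisson shot
    noise applied.
    """
    from scipy.special import erf

    if pixel <= 0:
        raise ValueError("pixel size must be positive")
    ny, nx = shape
    n_frames = int(localizations["frame"].max()) + 1 if len(localizations) else 0
    stack = np.zeros((n_frames, ny, nx))
    xe = np.arange(nx + 1) * pixel
    ye = np.arange(ny + 1) * pixel
    s = psf_sigma * np.sqrt(2.0)
    for frame, grp in localizations.groupby("frame"):
        img = stack[int(frame)]
        for _, row in grp.iterrows():
            fx = 0.5 * (erf((xe[1:] - row.x_um) / s) - erf((xe[:-1] - row.x_um) / s))
            fy = 0.5 * (erf((ye[1:] - row.y_um) / s) - erf((ye[:-1] - row.y_um) / s))
            img += photons * np.outer(fy, fx)
    stack += background
    if poisson_noise:
        rng = _as_rng(seed)
        stack = rng.poisson(stack).astype(float)
    return stack


def write_tiff_stack(path, stack: np.ndarray) -> None:
    """Write a rendered image stack to a (multi-page) TIFF file."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_tiff_stack(path) -> np.ndarray:
    """Read an image stack written by :func:`write_tiff_stack`."""
    import tifffile

    arr = np.asarray(tifffile.imread(path), dtype=float)
    return arr[None] if arr.ndim == 2 else arr
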