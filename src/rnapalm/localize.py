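"""Spot detection and sub-pixel localization by elliptical Gaussian fitting.

Candidate molecules are found on a difference-of-Gaussians (bandpass)
filtered frame as local maxima above an intensity threshold expressed in
standard deviations over the mean; each candidate is refined by
least-squares fitting of a free 2D elliptical Gaussian plus offset in a
fixed window.  Non-converging fits are dropped and window positions
clipped at the image border are skipped (counted via logging).

For diffraction-limited FISH foci, a short stack is averaged into a single
frame before the same detection and fitting is applied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, maximum_filter
from scipy.optimize import least_squares

__all__ = ["detect_and_fit", "detect_foci", "merge_repeats", "localize_stack"]

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_UM = 0.1


def _gauss2d(params, yy, xx):
    amp, x0, y0, sx, sy, off = params
    return amp * np.exp(
        -((xx - x0) ** 2) / (2 * sx**2) - ((yy - y0) ** 2) / (2 * sy**2)
    ) + off


def detect_and_fit(
    image: np.ndarray,
    bandpass: tuple[float, float] = (1.0, 3.0),
    threshold_k: float = 4.0,
    fit_window: int = 7,
    pixel_size: float = DEFAULT_PIXEL_UM,
) -> pd.DataFrame:
    """Detect and localize spots in one frame.

    Returns a table with ``x_um, y_um, intensity, sigma_x_um, sigma_y_um,
    offset`` (positions relative to the image origin; pixel (0, 0) spans
    ``[0, pixel_size]`` on both axes).
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite-valued")
    s_small, s_large = bandpass
    if not s_small < s_large:
        raise ValueError("bandpass requires sigma_small < sigma_large")
    dog = gaussian_filter(img, s_small) - gaussian_filter(img, s_large)
    thr = dog.mean() + threshold_k * dog.std()
    peaks = (dog == maximum_filter(dog, size=3)) & (dog > thr)
    half = fit_window // 2
    rows, cols = np.nonzero(peaks)
    recs = []
    n_clipped = 0
    for r, c in zip(rows, cols):
        if r < half or c < half or r >= img.shape[0] - half or c >= img.shape[1] - half:
            n_clipped += 1
            continue
        win = img[r - half : r + half + 1, c - half : c + half + 1]
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
        lo = win.min()
        p0 = (win.max() - lo, 0.0, 0.0, 1.0, 1.0, lo)
        try:
            res = least_squares(
                lambda p: (_gauss2d(p, yy, xx) - win).ravel(),
                p0,
                bounds=(
                    (0.0, -half, -half, 0.3, 0.3, -np.inf),
                    (np.inf, half, half, 2.0 * half, 2.0 * half, np.inf),
                ),
                max_nfev=200,
            )
        except ValueError:
            continue
        if not res.success:
            continue
        amp, dx, dy, sx, sy, off = res.x
        if amp <= 0:
            continue
        recs.append(
            {
                "x_um": (c + 0.5 + dx) * pixel_size,
                "y_um": (r + 0.5 + dy) * pixel_size,
                "intensity": amp,
                "sigma_x_um": sx * pixel_size,
                "sigma_y_um": sy * pixel_size,
                "offset": off,
            }
        )
    if n_clipped:
        logger.info("skipped %d candidates with windows clipped at the border", n_clipped)
    df = pd.DataFrame(
        recs,
        columns=["x_um", "y_um", "intensity", "sigma_x_um", "sigma_y_um", "offset"],
    )
    # a maximum plateau (emitter on a pixel boundary) yields duplicate fits:
    # keep the brightest of any fits closer than one pixel
    if len(df) > 1:
        df = df.sort_values("intensity", ascending=False).reset_index(drop=True)
        kept: list[int] = []
        for i in range(len(df)):
            xi, yi = df.x_um[i], df.y_um[i]
            if all(
                np.hypot(xi - df.x_um[j], yi - df.y_um[j]) > pixel_size
                for j in kept
            ):
                kept.append(i)
        df = df.loc[kept].reset_index(drop=True)
    return df


def localize_stack(stack: np.ndarray, **kwargs) -> pd.DataFrame:
    """Frame-by-frame :func:`detect_and_fit`; adds a ``frame`` column."""
    frames = []
    for i, img in enumerate(stack):
        df = detect_and_fit(img, **kwargs)
        df.insert(0, "frame", i)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def detect_foci(frames: np.ndarray, **kwargs) -> pd.DataFrame:
    """Detect diffraction-limited foci on the average of a short stack.

    ``frames`` is a ``(n_frames, H, W)`` stack (20 exposures in the FISH
    protocol); returns one row per focus with centroid and amplitude.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("need a non-empty (n_frames, H, W) stack")
    avg = stack.mean(axis=0)
    df = detect_and_fit(avg, **kwargs)
    return df.rename(columns={"intensity": "amplitude"})[
        ["x_um", "y_um", "amplitude"]
    ]


def merge_repeats(
    localizations: pd.DataFrame, radius: float = 0.100
) -> pd.DataFrame:
    """Merge repeated localizations of one molecule in flanking frames.

    A localization within ``radius`` μm of one in the immediately preceding
    frame is treated as the same (blinking/long-on) molecule and dropped,
    keeping the first record; chains across several consecutive frames
    collapse to a single record with a ``n_repeats`` count.
    """
    df = localizations.sort_values("frame", kind="stable").reset_index(drop=True)
    keep = np.ones(len(df), dtype=bool)
    counts = np.ones(len(df), dtype=int)
    # map: index in df of the record a merged chain roots at
    prev_frame: dict[int, int] = {}  # row -> root row, for previous frame rows
    by_frame = {int(f): grp for f, grp in df.groupby("frame")}
    roots: dict[int, int] = {}
    for f in sorted(by_frame):
        grp = by_frame[f]
        prev = by_frame.get(f - 1)
        if prev is None or prev.empty:
            continue
        pxy = prev[["x_um", "y_um"]].to_numpy()
        for i, row in grp.iterrows():
            d = np.hypot(pxy[:, 0] - row.x_um, pxy[:, 1] - row.y_um)
            j = int(np.argmin(d))
            if d[j] <= radius:
                prev_idx = prev.index[j]
                root = roots.get(prev_idx, prev_idx)
                keep[i] = False
                counts[root] += 1
                roots[i] = root
    out = df[keep].copy()
    out["n_repeats"] = counts[keep]
    return out.reset_index(drop=True)
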