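"""Detection of diffraction-limited RNA spots in 3D.

Each transcript appears as a near-Gaussian blob a few voxels wide.  The
detector finds candidate local maxima on the band-passed volume, refines
each to subpixel precision with a least-squares 3D Gaussian fit (falling
back to an intensity-weighted centroid when the fit does not converge),
computes the integrated intensity ("mass") over the fit window, discards
candidates below ``min_mass``, and enforces a minimum center-to-center
separation keeping the higher-mass spot.

``min_mass`` is the single most consequential parameter: the minimum
integrated intensity a spot must have to be counted as a transcript.  To
help choose it, :func:`categorize_spots` bins detections into three
intensity intervals around user-chosen lower/upper bounds and
:func:`render_detection_overlay` draws the bins in different colors over
the filtered image, so borderline spots can be inspected directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw
from scipy import optimize
from skimage.feature import peak_local_max

from .filtering import ParameterError
from .image_model import Volume, max_project

SPOT_COLUMNS = [
    "channel", "z", "y", "x", "mass", "peak",
    "sigma_z", "sigma_y", "sigma_x", "fallback", "region_id",
]


def empty_spot_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "channel": pd.Series(dtype=str),
            "z": pd.Series(dtype=float),
            "y": pd.Series(dtype=float),
            "x": pd.Series(dtype=float),
            "mass": pd.Series(dtype=float),
            "peak": pd.Series(dtype=float),
            "sigma_z": pd.Series(dtype=float),
            "sigma_y": pd.Series(dtype=float),
            "sigma_x": pd.Series(dtype=float),
            "fallback": pd.Series(dtype=bool),
            "region_id": pd.Series(dtype=int),
        }
    )


@dataclass(frozen=True)
class DetectionParams:
    spot_radius: int = 3          # fit-window half-size, voxels
    min_mass: float = 0.5         # minimum integrated window intensity
    separation: float = 3.0       # minimum center-to-center distance, voxels
    percentile_floor: float = 99.0  # local-max prefilter percentile
    report_bounds: tuple[float, float] | None = None  # default (0.8, 1.2)*min_mass

    def __post_init__(self):
        if self.spot_radius < 1:
            raise ParameterError(f"spot_radius must be >= 1, got {self.spot_radius}")
        if self.min_mass < 0:
            raise ParameterError(f"min_mass must be >= 0, got {self.min_mass}")
        if self.separation < 1:
            raise ParameterError(f"separation must be >= 1, got {self.separation}")

    @property
    def interval_bounds(self) -> tuple[float, float]:
        if self.report_bounds is not None:
            return self.report_bounds
        return (0.8 * self.min_mass, 1.2 * self.min_mass)


def _gauss_nd(coords, amp, offset, centers, sigmas):
    q = np.zeros(coords[0].shape, dtype=np.float64)
    for c, c0, s in zip(coords, centers, sigmas):
        q += (c - c0) ** 2 / (2.0 * s**2)
    return amp * np.exp(-q) + offset


def _fit_gaussian(window: np.ndarray, origin: np.ndarray, spot_radius: int):
    """Least-squares Gaussian fit within a window.

    Returns (center, sigmas, peak, ok).  Axes of extent 1 are excluded from
    the fit (their sigma is reported as NaN, center fixed at the plane).
    """
    axes = [i for i in range(window.ndim) if window.shape[i] > 1]
    coords = np.meshgrid(
        *[np.arange(s, dtype=np.float64) for s in window.shape], indexing="ij"
    )
    flat = window.ravel()
    fit_coords = [coords[i].ravel() for i in axes]
    amp0 = float(flat.max() - flat.min())
    off0 = float(flat.min())
    # init center at the window's global max
    peak_idx = np.unravel_index(np.argmax(window), window.shape)
    c0 = [float(peak_idx[i]) for i in axes]
    s0 = [1.5] * len(axes)
    p0 = np.array([amp0 if amp0 > 0 else 1e-6, off0] + c0 + s0)
    n = len(axes)
    lb = np.array([0.0, -np.inf] + [-1.0] * n + [0.1] * n)
    ub = np.array(
        [np.inf, np.inf]
        + [window.shape[i] for i in axes]
        + [4.0 * spot_radius] * n
    )

    def resid(p):
        amp, off = p[0], p[1]
        centers = p[2 : 2 + n]
        sigmas = p[2 + n :]
        return _gauss_nd(fit_coords, amp, off, centers, sigmas) - flat

    try:
        res = optimize.least_squares(
            resid, p0, bounds=(lb, ub), max_nfev=100, method="trf"
        )
        ok = res.success
        p = res.x
    except Exception:
        ok = False
        p = p0
    centers_fit = p[2 : 2 + n]
    sigmas_fit = p[2 + n :]
    # reject non-physical widths
    if ok and not all(0.5 <= s <= 2.0 * spot_radius for s in sigmas_fit):
        ok = False
    center = np.array(peak_idx, dtype=np.float64)
    sigmas = np.full(window.ndim, np.nan)
    if ok:
        for i, ax in enumerate(axes):
            center[ax] = centers_fit[i]
            sigmas[ax] = sigmas_fit[i]
        peak = float(p[0] + p[1])
    else:
        # intensity-weighted centroid fallback
        w = np.clip(window - window.min(), 0, None)
        tot = w.sum()
        if tot > 0:
            for ax in axes:
                center[ax] = float((w * coords[ax]).sum() / tot)
        peak = float(window.max())
    return center + origin, sigmas, peak, ok


def detect_spots(
    v: Volume | np.ndarray, p: DetectionParams, channel: str = ""
) -> pd.DataFrame:
    """Locate spots on a band-passed volume; returns a spot table.

    Deterministic: a pure function of the input array and parameters.
    """
    data = v.data if isinstance(v, Volume) else np.asarray(v, dtype=np.float64)
    if data.ndim == 2:
        data = data[np.newaxis]
    if min(s for s in data.shape if s > 1) <= p.spot_radius:
        raise ParameterError(
            f"spot_radius {p.spot_radius} too large for volume shape {data.shape}"
        )
    if data.size == 0 or data.max() <= 0:
        return empty_spot_table()

    floor = float(np.percentile(data, p.percentile_floor))
    floor = max(floor, np.finfo(float).tiny)
    cand = peak_local_max(
        data, min_distance=1, threshold_abs=floor, exclude_border=False
    )
    if len(cand) == 0:
        return empty_spot_table()
    # deterministic candidate order
    cand = cand[np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0]))]

    rows = []
    r = p.spot_radius
    for zc, yc, xc in cand:
        idx = []
        origin = []
        for c, size in zip((zc, yc, xc), data.shape):
            if size == 1:
                lo, hi = 0, 1
            else:
                lo = max(0, c - r)
                hi = min(size, c + r + 1)
            idx.append(slice(lo, hi))
            origin.append(lo)
        window = data[tuple(idx)]
        mass = float(window.sum())
        if mass < p.min_mass:  # gate before the fit: mass is fit-independent
            continue
        center, sigmas, peak, ok = _fit_gaussian(
            window, np.array(origin, dtype=np.float64), r
        )
        center = np.clip(center, 0, np.array(data.shape) - 1)
        rows.append(
            dict(
                channel=channel, z=center[0], y=center[1], x=center[2],
                mass=mass, peak=peak,
                sigma_z=sigmas[0], sigma_y=sigmas[1], sigma_x=sigmas[2],
                fallback=not ok, region_id=0,
            )
        )
    if not rows:
        return empty_spot_table()
    spots = pd.DataFrame(rows)

    # separation: keep the higher-mass spot; ties by (z, y, x) lexicographic
    order = np.lexsort(
        (spots["x"].values, spots["y"].values, spots["z"].values, -spots["mass"].values)
    )
    pts = spots[["z", "y", "x"]].values
    taken: list[np.ndarray] = []
    taken_idx: list[int] = []
    for i in order:
        pt = pts[i]
        if taken:
            d = np.linalg.norm(np.asarray(taken) - pt, axis=1)
            if bool((d < p.separation).any()):  # exactly-at-separation pairs retained
                continue
        taken.append(pt)
        taken_idx.append(i)
    return spots.iloc[sorted(taken_idx)].reset_index(drop=True)


@dataclass
class IntervalReport:
    """Spots binned by mass relative to (lower, upper) for threshold QC."""

    lower: float
    upper: float
    below: pd.DataFrame
    within: pd.DataFrame
    above: pd.DataFrame

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.below), len(self.within), len(self.above))


def categorize_spots(spots: pd.DataFrame, lower: float, upper: float) -> IntervalReport:
    """Partition a spot table into mass < lower, lower <= mass < upper, mass >= upper."""
    if lower > upper:
        raise ParameterError(f"lower bound {lower} exceeds upper bound {upper}")
    m = spots["mass"].values if len(spots) else np.array([])
    below = spots[m < lower] if len(spots) else spots
    within = spots[(m >= lower) & (m < upper)] if len(spots) else spots
    above = spots[m >= upper] if len(spots) else spots
    return IntervalReport(lower=lower, upper=upper, below=below, within=within, above=above)


_BIN_COLORS = {"below": (80, 140, 255), "within": (255, 220, 40), "above": (255, 60, 60)}


def _to_rgb8(img2d: np.ndarray) -> Image.Image:
    lo, hi = float(img2d.min()), float(img2d.max())
    scaled = np.zeros_like(img2d) if hi == lo else (img2d - lo) / (hi - lo)
    g = (scaled * 255).astype(np.uint8)
    return Image.merge("RGB", [Image.fromarray(g)] * 3)


def render_detection_overlay(
    v: Volume | np.ndarray, report: IntervalReport, out_path: str | Path,
    radius: int = 4,
) -> Path:
    """Max projection with bin-colored circles at spot (y, x) plus a count
    legend; byte-deterministic PNG."""
    img = _to_rgb8(max_project(v))
    draw = ImageDraw.Draw(img)
    for name, spots in (("below", report.below), ("within", report.within),
                        ("above", report.above)):
        color = _BIN_COLORS[name]
        for _, s in spots.iterrows():
            y, x = s["y"], s["x"]
            draw.ellipse([x - radius, y - radius, x + radius, y + radius],
                         outline=color)
    legend = (
        f"mass<{report.lower:g}: {len(report.below)}  "
        f"[{report.lower:g},{report.upper:g}): {len(report.within)}  "
        f">={report.upper:g}: {len(report.above)}"
    )
    draw.text((2, 2), legend, fill=(255, 255, 255))
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    img.save(out_path, format="PNG")
    return out_path
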