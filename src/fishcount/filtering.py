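"""Band-pass filtering of transcript channels.

Single-molecule FISH spots are diffraction-limited: a few voxels wide.
Cellular autofluorescence and uneven illumination vary on a much larger
scale.  The band-pass used here is the classical Gaussian pair: subtract a
wide Gaussian blur (high-pass, removes the slowly varying background) and
then blur with a narrow Gaussian (low-pass, smooths shot noise at the spot
scale).  Negative values after the high-pass are clipped to zero so the
integrated spot intensity ("mass") stays non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .image_model import Volume


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class FilterParams:
    """sigma_high: background scale (voxels); sigma_low: spot scale (voxels)."""

    sigma_high: float = 10.0
    sigma_low: float = 1.0
    truncate: float = 4.0
    # optional per-axis (z,y,x) overrides; isotropic in voxel units otherwise
    per_axis_sigma_high: tuple[float, float, float] | None = None
    per_axis_sigma_low: tuple[float, float, float] | None = None

    def __post_init__(self):
        if not (self.sigma_high > self.sigma_low > 0):
            raise ParameterError(
                f"require sigma_high > sigma_low > 0; got "
                f"{self.sigma_high} and {self.sigma_low}"
            )


def _as_volume(v: Volume | np.ndarray) -> tuple[np.ndarray, Volume | None]:
    if isinstance(v, Volume):
        return np.asarray(v.data, dtype=np.float64), v
    return np.asarray(v, dtype=np.float64), None


def _wrap(out: np.ndarray, src: Volume | None) -> Volume | np.ndarray:
    return replace(src, data=out) if src is not None else out


def _blur(data: np.ndarray, sigma, truncate: float) -> np.ndarray:
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), (data.ndim,))
    # degenerate axes (z extent 1) get sigma 0 so 2D inputs behave as 2D
    sig = np.where(np.array(data.shape) == 1, 0.0, sig)
    return ndimage.gaussian_filter(data, sigma=sig, truncate=truncate, mode="reflect")


def gaussian_high_pass(
    v: Volume | np.ndarray, sigma_high: float, truncate: float = 4.0,
    per_axis: tuple[float, float, float] | None = None,
) -> Volume | np.ndarray:
    """``clip(v - G(v; sigma_high), 0)``: removes background below the cutoff scale."""
    if per_axis is None and not sigma_high > 0:
        raise ParameterError(f"sigma_high must be > 0, got {sigma_high}")
    data, src = _as_volume(v)
    bg = _blur(data, per_axis if per_axis is not None else sigma_high, truncate)
    return _wrap(np.clip(data - bg, 0.0, None), src)


def gaussian_low_pass(
    v: Volume | np.ndarray, sigma_low: float, truncate: float = 4.0,
    per_axis: tuple[float, float, float] | None = None,
) -> Volume | np.ndarray:
    """Gaussian blur at the spot scale; mass-preserving up to boundary effects."""
    if per_axis is None and not sigma_low > 0:
        raise ParameterError(f"sigma_low must be > 0, got {sigma_low}")
    data, src = _as_volume(v)
    return _wrap(_blur(data, per_axis if per_axis is not None else sigma_low, truncate), src)


def bandpass(v: Volume | np.ndarray, p: FilterParams) -> Volume | np.ndarray:
    """High-pass then low-pass; the order is fixed and the result is what
    spot detection consumes."""
    hp = gaussian_high_pass(v, p.sigma_high, p.truncate, p.per_axis_sigma_high)
    return gaussian_low_pass(hp, p.sigma_low, p.truncate, p.per_axis_sigma_low)
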