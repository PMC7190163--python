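"""Synthetic multi-channel experiments with full ground truth.

The generator renders what the pipeline expects to see in a real
RNAscope/immunostain field of view, but with every latent variable known:

* a nuclei (DAPI) channel of smooth 2D blobs extruded over z, optionally
  including deliberately *touching* nucleus pairs whose ridge saddle sits
  an exactly specified depth below the two peaks — the quantity the
  segmentation's ``min_depth`` control acts on;
* zero or more cell-marker channels rendered as bright regions over the
  nuclei of their cell type;
* transcript channels rendered as PSF-shaped Gaussian spots at
  Poisson-distributed counts per nucleus (nascent mode: inside the
  nucleus), over a smooth background gradient with additive Gaussian
  noise.

Touching pairs are built from a separable profile whose two peaks have
value exactly ``A`` on grid pixels and whose ridge dips to exactly
``A - d`` at the midpoint, so the rendered saddle depth equals the
requested ``d`` to floating-point precision after normalization.

The DAPI channel is rendered noise-free: nuclear counterstains are orders
of magnitude brighter than their background, and the segmentation tests
target saddle geometry rather than noise robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .image_model import ChannelRole, ChannelSpec, Experiment, Volume
from .segmentation import LabelMap


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CellType:
    name: str               # also the marker channel name; "" = unlabeled
    fraction: float
    transcript_means: dict = field(default_factory=dict)  # channel -> mean count


@dataclass(frozen=True)
class FixtureParams:
    image_shape: tuple[int, int, int] = (24, 320, 320)
    n_nuclei: int = 6
    nucleus_radius: tuple[float, float] = (16.0, 20.0)
    touching_pairs: int = 0
    saddle_depth: float = 1e-5        # on the normalized [0,1] scale
    cell_types: tuple = (
        CellType("GFP", 0.5, {"HES1": 8.0}),
        CellType("mCherry", 0.5, {"HES1": 2.0}),
    )
    transcript_channels: tuple = ("HES1",)
    psf_sigma: tuple[float, float, float] = (1.0, 1.5, 1.5)  # (z,y,x) voxels
    spot_peak: float = 0.5
    spot_min_separation: float = 6.0  # voxels, 3D; ~3.3 sigma of the
    # effective (PSF + low-pass) in-plane width, so spots stay resolvable
    noise_sigma: float = 0.01
    background: float = 0.1           # smooth gradient amplitude
    marker_amplitude: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.saddle_depth <= 1):
            raise GenerationError("saddle depth must lie in [0,1]")
        if 2 * self.touching_pairs > self.n_nuclei:
            raise GenerationError("touching pairs exceed nucleus budget")


@dataclass
class GroundTruth:
    label_map: LabelMap                       # true 2D nucleus labels
    cell_types: dict[int, str]                # nucleus id -> type name
    spots: pd.DataFrame                       # channel,z,y,x,nucleus_id,mass
    spot_counts: dict[str, dict[int, int]]    # channel -> id -> count
    params: FixtureParams


def expected_spot_mass(
    peak: float, psf_sigma: tuple[float, float, float], spot_radius: int
) -> float:
    """Analytic integrated intensity of a rendered PSF spot over the
    (2r+1)^3 detection window (continuous-integral approximation)."""
    from math import erf, pi, sqrt

    mass = peak
    for s in psf_sigma:
        mass *= sqrt(2 * pi) * s * erf((spot_radius + 0.5) / (s * sqrt(2)))
    return mass


def _z_profile(nz: int, sigma_frac: float = 0.35) -> np.ndarray:
    """Per-slice extrusion weights, exactly 1.0 at the central slice so
    the max projection reproduces the 2D render bit-for-bit."""
    zc = (nz - 1) // 2
    z = np.arange(nz, dtype=np.float64)
    return np.exp(-((z - zc) ** 2) / (2.0 * (sigma_frac * max(nz, 2)) ** 2 + 1e-12))


def _pair_profile(x: np.ndarray, x0: float, half_sep: float, sigma: float,
                  depth: float) -> np.ndarray:
    """1D ridge profile: peaks of exactly 1 at x0 +- half_sep, dip to
    exactly 1 - depth at x0, Gaussian falloff outside the peaks."""
    u = np.abs(x - x0)
    inside = u <= half_sep
    h = np.where(
        inside,
        1.0 - 0.5 * depth * (1.0 + np.cos(np.pi * (x - x0) / half_sep)),
        np.exp(-((u - half_sep) ** 2) / (2.0 * sigma**2)),
    )
    return h


def _render_nuclei(p: FixtureParams, rng: np.random.Generator):
    """Place nuclei, render the 2D DAPI image, and build the true labels.

    Returns (dapi_2d, label_map, centers, radii).  Pairs are rendered at
    amplitude 1 (the global maximum, so the normalized saddle depth equals
    ``p.saddle_depth`` exactly); singles at 0.8.
    """
    nz, ny, nx = p.image_shape
    n_pair_nuclei = 2 * p.touching_pairs
    n_single = p.n_nuclei - n_pair_nuclei
    img = np.zeros((ny, nx), dtype=np.float64)
    blob_values = []  # per nucleus: dense blob image for argmax labeling
    centers = []
    radii = []

    placed: list[tuple[float, float, float]] = []  # (y, x, clearance radius)

    def try_place(clearance, tries=400):
        margin = clearance + 2
        if 2 * margin >= min(ny, nx):
            raise GenerationError("image too small for the requested nuclei")
        for _ in range(tries):
            y = rng.uniform(margin, ny - margin)
            x = rng.uniform(margin, nx - margin)
            if all(np.hypot(y - py, x - px) >= clearance + pc for py, px, pc in placed):
                return y, x
        raise GenerationError("could not place nuclei without unintended overlap")

    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)

    # touching pairs: separable ridge profile with exact saddle depth
    for _ in range(p.touching_pairs):
        r = rng.uniform(*p.nucleus_radius)
        sigma = r / 2.0
        half_sep = float(int(round(1.6 * r)))  # integer so peaks sit on pixels
        y0, x0 = try_place(half_sep + 3 * sigma)
        y0, x0 = float(round(y0)), float(round(x0))
        placed.append((y0, x0, half_sep + 3 * sigma))
        h = _pair_profile(xx[0], x0, half_sep, sigma, p.saddle_depth)
        g = np.exp(-((yy[:, 0] - y0) ** 2) / (2.0 * sigma**2))
        blob = g[:, np.newaxis] * h[np.newaxis, :]
        img = np.maximum(img, blob)
        for side in (-1.0, 1.0):
            cx = x0 + side * half_sep
            centers.append((y0, cx))
            radii.append(r)
            half = np.where(side * (xx - x0) >= 0, blob, 0.0)
            blob_values.append(half)

    # isolated nuclei: anisotropic Gaussian blobs at amplitude 0.8
    for _ in range(n_single):
        r = rng.uniform(*p.nucleus_radius)
        sy = r / 2.0 * rng.uniform(0.85, 1.15)
        sx = r / 2.0 * rng.uniform(0.85, 1.15)
        y0, x0 = try_place(3.5 * max(sy, sx))
        placed.append((y0, x0, 3.5 * max(sy, sx)))
        blob = 0.8 * np.exp(
            -((yy - y0) ** 2) / (2 * sy**2) - ((xx - x0) ** 2) / (2 * sx**2)
        )
        img = np.maximum(img, blob)
        centers.append((y0, x0))
        radii.append(r)
        blob_values.append(blob)

    # true labels: argmax blob where the winning blob is bright enough
    stack = np.stack(blob_values)
    winner = np.argmax(stack, axis=0)
    peak_per_nucleus = stack.max(axis=(1, 2))
    best = stack.max(axis=0)
    cutoff = 0.25 * peak_per_nucleus[winner]
    labels = np.where(best >= cutoff, winner + 1, 0).astype(np.int32)
    return img, LabelMap(labels), centers, radii, stack, peak_per_nucleus


def _sample_spot_positions(
    nucleus_blob: np.ndarray, peak: float, n: int, nz: int, min_sep: float,
    rng: np.random.Generator, tries_per_spot: int = 400,
) -> list[tuple[float, float, float]]:
    """Uniform positions in the bright core of a nucleus (blob >= 0.7 of
    its peak, where any reasonable foreground threshold keeps the pixel),
    pairwise 3D separation enforced."""
    core = np.argwhere(nucleus_blob >= 0.7 * peak)
    if len(core) == 0:
        raise GenerationError("nucleus core empty; radius too small")
    zlo, zhi = 2.0, nz - 3.0
    pts: list[tuple[float, float, float]] = []
    for _ in range(n):
        for _ in range(tries_per_spot):
            y, x = core[rng.integers(len(core))] + rng.uniform(-0.5, 0.5, 2)
            z = rng.uniform(zlo, max(zhi, zlo))
            cand = (z, float(y), float(x))
            if all(
                np.sqrt((z - q[0]) ** 2 + (y - q[1]) ** 2 + (x - q[2]) ** 2) >= min_sep
                for q in pts
            ):
                pts.append(cand)
                break
        else:
            raise GenerationError(
                "could not place transcript spots at the requested separation"
            )
    return pts


def _render_spots(
    shape: tuple[int, int, int],
    positions: list[tuple[float, float, float]],
    peak: float,
    psf: tuple[float, float, float],
) -> np.ndarray:
    nz, ny, nx = shape
    vol = np.zeros(shape, dtype=np.float64)
    sz, sy, sx = psf
    rz, ry, rx = (int(np.ceil(4 * s)) for s in psf)
    for z0, y0, x0 in positions:
        zi = np.arange(max(0, int(z0) - rz), min(nz, int(z0) + rz + 1))
        yi = np.arange(max(0, int(y0) - ry), min(ny, int(y0) + ry + 1))
        xi = np.arange(max(0, int(x0) - rx), min(nx, int(x0) + rx + 1))
        gz = np.exp(-((zi - z0) ** 2) / (2 * sz**2))
        gy = np.exp(-((yi - y0) ** 2) / (2 * sy**2))
        gx = np.exp(-((xi - x0) ** 2) / (2 * sx**2))
        vol[np.ix_(zi, yi, xi)] += peak * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    return vol


def generate_experiment(p: FixtureParams) -> tuple[Experiment, GroundTruth]:
    """Render a full synthetic field of view plus its ground truth.

    Deterministic: identical params (including seed) give identical
    output.
    """
    rng = np.random.default_rng(p.seed)
    nz, ny, nx = p.image_shape

    dapi2d, truth_labels, centers, radii, blob_stack, blob_peaks = _render_nuclei(p, rng)
    zprof = _z_profile(nz)
    dapi = zprof[:, None, None] * dapi2d[None, :, :]

    # cell-type assignment per nucleus
    n = len(centers)
    type_of: dict[int, str] = {}
    order = rng.permutation(n)
    counts_per_type = []
    remaining = n
    for i, ct in enumerate(p.cell_types):
        k = round(ct.fraction * n) if i < len(p.cell_types) - 1 else remaining
        k = min(k, remaining)
        counts_per_type.append(k)
        remaining -= k
    pos = 0
    for ct, k in zip(p.cell_types, counts_per_type):
        for j in order[pos : pos + k]:
            type_of[int(j) + 1] = ct.name
        pos += k

    # marker channels: bright disks over their type's nuclei
    marker_names = [ct.name for ct in p.cell_types if ct.name]
    channels: dict[str, Volume] = {}
    specs = [ChannelSpec("DAPI", ChannelRole.NUCLEI)]
    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    for mname in marker_names:
        img = np.zeros((ny, nx), dtype=np.float64)
        for nid, tname in type_of.items():
            if tname != mname:
                continue
            (y0, x0), r = centers[nid - 1], radii[nid - 1]
            d2 = (yy - y0) ** 2 + (xx - x0) ** 2
            img = np.maximum(img, p.marker_amplitude * np.exp(-d2 / (2 * (1.1 * r) ** 2)))
        vol = zprof[:, None, None] * img[None, :, :]
        vol = vol + rng.normal(0.0, p.noise_sigma, vol.shape)
        channels[mname] = Volume(np.clip(vol, 0, None))
        specs.append(ChannelSpec(mname, ChannelRole.CELL_MARKER))

    # transcript channels: Poisson counts per nucleus, spots in the core
    mean_of = {ct.name: ct.transcript_means for ct in p.cell_types}
    spot_rows = []
    spot_counts: dict[str, dict[int, int]] = {}
    for tch in p.transcript_channels:
        positions_all: list[tuple[float, float, float]] = []
        spot_counts[tch] = {}
        for nid in range(1, n + 1):
            mean = mean_of.get(type_of[nid], {}).get(tch, 0.0)
            k = int(rng.poisson(mean)) if mean > 0 else 0
            pts = _sample_spot_positions(
                blob_stack[nid - 1], blob_peaks[nid - 1], k, nz,
                p.spot_min_separation, rng,
            )
            spot_counts[tch][nid] = k
            for z, y, x in pts:
                spot_rows.append(
                    dict(channel=tch, z=z, y=y, x=x, nucleus_id=nid,
                         mass=expected_spot_mass(p.spot_peak, p.psf_sigma, 3))
                )
            positions_all.extend(pts)
        vol = _render_spots(p.image_shape, positions_all, p.spot_peak, p.psf_sigma)
        gy = np.linspace(0.0, 1.0, ny)[None, :, None]
        gx = np.linspace(0.0, 1.0, nx)[None, None, :]
        vol = vol + p.background * (0.5 * gy + 0.5 * gx)
        vol = vol + rng.normal(0.0, p.noise_sigma, vol.shape)
        channels[tch] = Volume(np.clip(vol, 0, None))
        specs.append(ChannelSpec(tch, ChannelRole.TRANSCRIPT))

    channels["DAPI"] = Volume(dapi)
    exp = Experiment(id=f"synthetic_seed{p.seed}", channels=channels, specs=specs)
    truth = GroundTruth(
        label_map=truth_labels,
        cell_types=type_of,
        spots=pd.DataFrame(
            spot_rows, columns=["channel", "z", "y", "x", "nucleus_id", "mass"]
        ),
        spot_counts=spot_counts,
        params=p,
    )
    return exp, truth


def generate_spot_field(
    n_spots: int = 100,
    shape: tuple[int, int, int] = (16, 160, 160),
    peak: float = 0.5,
    psf_sigma: tuple[float, float, float] = (1.0, 1.5, 1.5),
    noise_sigma: float = 0.01,
    background: float = 0.1,
    min_separation: float = 6.0,
    seed: int = 1,
) -> tuple[np.ndarray, pd.DataFrame]:
    """A bare transcript volume: ``n_spots`` identical PSF spots at random
    positions with enforced pairwise separation, over a background
    gradient plus Gaussian noise.  Peak SNR = peak / noise_sigma."""
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    pts: list[tuple[float, float, float]] = []
    for _ in range(n_spots):
        for _ in range(2000):
            z = rng.uniform(2, nz - 3)
            y = rng.uniform(8, ny - 9)
            x = rng.uniform(8, nx - 9)
            if all(
                np.sqrt((z - q[0]) ** 2 + (y - q[1]) ** 2 + (x - q[2]) ** 2)
                >= min_separation
                for q in pts
            ):
                pts.append((z, y, x))
                break
        else:
            raise GenerationError("spot field too crowded for the separation")
    vol = _render_spots(shape, pts, peak, psf_sigma)
    gy = np.linspace(0.0, 1.0, ny)[None, :, None]
    gx = np.linspace(0.0, 1.0, nx)[None, None, :]
    vol = vol + background * (0.5 * gy + 0.5 * gx)
    vol = np.clip(vol + rng.normal(0.0, noise_sigma, vol.shape), 0, None)
    truth = pd.DataFrame(pts, columns=["z", "y", "x"])
    return vol, truth


# ---------------------------------------------------------------------------
# scoring


def match_spots(
    detected: pd.DataFrame, truth: pd.DataFrame, gate: float = 2.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hungarian matching of detected to true spot centers; pairs farther
    than ``gate`` voxels are not matched.  Returns (det_idx, true_idx,
    distances)."""
    if len(detected) == 0 or len(truth) == 0:
        return np.array([], int), np.array([], int), np.array([])
    d = np.linalg.norm(
        detected[["z", "y", "x"]].values[:, None, :]
        - truth[["z", "y", "x"]].values[None, :, :],
        axis=2,
    )
    cost = np.where(d <= gate, d, 1e6)
    ri, ci = linear_sum_assignment(cost)
    ok = d[ri, ci] <= gate
    return ri[ok], ci[ok], d[ri, ci][ok]


def score_spots(detected: pd.DataFrame, truth: pd.DataFrame, gate: float = 2.0) -> dict:
    di, ti, dist = match_spots(detected, truth, gate)
    n_match = len(di)
    recall = n_match / len(truth) if len(truth) else 1.0
    precision = n_match / len(detected) if len(detected) else (1.0 if not len(truth) else 0.0)
    rmse = float(np.sqrt(np.mean(dist**2))) if n_match else float("nan")
    return dict(recall=recall, precision=precision, rmse=rmse, n_matched=n_match)


def match_regions(pred: LabelMap, truth: LabelMap) -> dict[int, int]:
    """Greedy IoU matching of predicted regions to true nuclei."""
    pairs = []
    for pid in pred.ids:
        pm = pred.labels == pid
        for tid in truth.ids:
            tm = truth.labels == tid
            inter = np.logical_and(pm, tm).sum()
            if inter == 0:
                continue
            union = np.logical_or(pm, tm).sum()
            pairs.append((inter / union, int(pid), int(tid)))
    pairs.sort(reverse=True)
    used_p, used_t, out = set(), set(), {}
    for iou, pid, tid in pairs:
        if pid in used_p or tid in used_t:
            continue
        out[pid] = tid
        used_p.add(pid)
        used_t.add(tid)
    return out


def score_against_truth(
    spots: pd.DataFrame,
    labels: LabelMap,
    assignments_df: pd.DataFrame,
    truth: GroundTruth,
    transcript_channel: str | None = None,
    gate: float = 2.0,
) -> dict:
    """Compare full pipeline outputs against fixture ground truth."""
    tch = transcript_channel or truth.params.transcript_channels[0]
    tspots = truth.spots[truth.spots["channel"] == tch]
    spot_metrics = score_spots(spots, tspots, gate)

    mapping = match_regions(labels, truth.label_map)
    ious = []
    for pid, tid in mapping.items():
        pm = labels.labels == pid
        tm = truth.label_map.labels == tid
        ious.append(np.logical_and(pm, tm).sum() / np.logical_or(pm, tm).sum())
    region_count_error = labels.n_regions - truth.label_map.n_regions

    type_correct = 0
    count_errors = []
    for _, row in assignments_df.iterrows():
        pid = int(row["nucleus_id"])
        tid = mapping.get(pid)
        if tid is None:
            continue
        true_type = truth.cell_types[tid] or "unassigned"
        if row["cell_type"] == true_type:
            type_correct += 1
        count_errors.append(
            abs(int(row[f"count_{tch}"]) - truth.spot_counts[tch][tid])
        )
    n_assigned = len(assignments_df)
    return dict(
        **spot_metrics,
        region_count_error=int(region_count_error),
        mean_iou=float(np.mean(ious)) if ious else 0.0,
        matched_regions=len(mapping),
        assignment_accuracy=(type_correct / n_assigned) if n_assigned else 0.0,
        total_count_error=int(sum(count_errors)),
    )
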