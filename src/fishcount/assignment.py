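"""Cell-type assignment and per-nucleus transcript counting.

Each immunostain (cell-marker) channel is max-projected, smoothed and
thresholded into a binary "marker-positive" mask.  A nucleus is called
positive for a marker when at least ``min_overlap_fraction`` of its area
lies inside that mask; multi-positive nuclei are reported as such, and
nuclei positive for nothing are retained as "unassigned".

Transcript counting has two modes:

* ``nascent`` — transcripts at the gene locus are nuclear, so each spot's
  (y, x) is looked up directly in the nucleus label map.
* ``mature`` — processed mRNA fills the cytoplasm, so each nucleus is
  expanded into a cell territory inside the marker mask (geodesic
  nearest-nucleus partition) and spots are looked up in territories.

Spots falling in the background are counted separately, never dropped:
total spots always equals the sum of per-region counts plus background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .filtering import ParameterError
from .segmentation import LabelMap, SegmentationError, filter_small_regions


@dataclass(frozen=True)
class AssignmentParams:
    marker_threshold: dict = field(default_factory=dict)  # channel -> [0,1]
    default_marker_threshold: float = 0.5
    min_overlap_fraction: float = 0.5
    mode: str = "nascent"  # {"nascent", "mature"}
    marker_smoothing_sigma: float = 2.0
    min_region_size: int = 50  # specks below this are not marker regions

    def __post_init__(self):
        for ch, t in self.marker_threshold.items():
            if not (0 <= t <= 1):
                raise ParameterError(f"marker_threshold[{ch!r}]={t} outside [0,1]")
        if not (0 <= self.default_marker_threshold <= 1):
            raise ParameterError("default_marker_threshold outside [0,1]")
        if not (0 <= self.min_overlap_fraction <= 1):
            raise ParameterError("min_overlap_fraction outside [0,1]")
        if self.mode not in ("nascent", "mature"):
            raise ParameterError(f"unknown mode {self.mode!r}")

    def threshold_for(self, channel: str) -> float:
        return self.marker_threshold.get(channel, self.default_marker_threshold)


@dataclass
class Assignment:
    nucleus_id: int
    positive_channels: set[str]
    overlap_fraction: dict[str, float]
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def cell_type(self) -> str:
        if not self.positive_channels:
            return "unassigned"
        return "+".join(sorted(self.positive_channels))


def detect_positive_regions(
    marker_2d: np.ndarray,
    threshold: float,
    smoothing_sigma: float = 2.0,
    min_size: int = 50,
) -> np.ndarray:
    """Threshold a normalized marker projection into a binary positivity
    mask; connected specks below ``min_size`` pixels are removed."""
    if not (0 <= threshold <= 1):
        raise ParameterError(f"threshold {threshold} outside [0,1]")
    img = np.asarray(marker_2d, dtype=np.float64)
    sm = ndimage.gaussian_filter(img, smoothing_sigma, mode="reflect") if smoothing_sigma > 0 else img
    mask = sm >= threshold
    if min_size > 0 and mask.any():
        lab, _ = ndimage.label(mask)
        kept = filter_small_regions(LabelMap(lab), min_size)
        mask = kept.labels > 0
    return mask


def assign_nuclei(
    nuclei: LabelMap,
    masks: dict[str, np.ndarray],
    p: AssignmentParams,
) -> list[Assignment]:
    """Call each nucleus positive/negative per marker by area overlap."""
    for ch, m in masks.items():
        if m.shape != nuclei.labels.shape:
            raise SegmentationError(
                f"marker mask {ch!r} shape {m.shape} != labels {nuclei.labels.shape}"
            )
    ids = nuclei.ids
    areas = np.bincount(nuclei.labels.ravel(), minlength=int(nuclei.labels.max()) + 1)
    out = []
    overlaps = {
        ch: np.bincount(
            nuclei.labels.ravel(),
            weights=np.asarray(m, dtype=float).ravel(),
            minlength=int(nuclei.labels.max()) + 1,
        )
        for ch, m in masks.items()
    }
    for i in ids:
        fr = {ch: float(overlaps[ch][i] / areas[i]) for ch in masks}
        pos = {ch for ch, f in fr.items() if f >= p.min_overlap_fraction}
        out.append(Assignment(nucleus_id=int(i), positive_channels=pos, overlap_fraction=fr))
    return out


def count_spots_per_region(
    spots: pd.DataFrame, regions: LabelMap
) -> tuple[pd.DataFrame, dict[int, int], int]:
    """Assign each spot to the region under its (y, x); z is collapsed
    because segmentation is 2D.

    Returns (spot table with region_id set, per-region counts for every
    region id including zero-count ones, background spot count).
    """
    spots = spots.copy()
    h, w = regions.labels.shape
    counts = {int(i): 0 for i in regions.ids}
    background = 0
    if len(spots):
        yy = np.rint(spots["y"].values).astype(int)
        xx = np.rint(spots["x"].values).astype(int)
        if (yy < 0).any() or (yy >= h).any() or (xx < 0).any() or (xx >= w).any():
            raise SegmentationError("spot coordinates outside the image")
        region_id = regions.labels[yy, xx]
        spots["region_id"] = region_id.astype(int)
        for rid in region_id:
            if rid == 0:
                background += 1
            else:
                counts[int(rid)] += 1
    return spots, counts, background


def expand_cell_territories(
    nuclei: LabelMap, marker_mask: np.ndarray
) -> LabelMap:
    """Partition a marker mask into per-cell territories for mature-mRNA
    counting: each mask pixel joins its geodesically nearest nucleus
    (lower nucleus ID wins ties); mask pixels unreachable from any nucleus
    stay unowned; a nucleus outside the mask keeps its own mask as its
    territory."""
    mask = np.asarray(marker_mask, dtype=bool)
    if mask.shape != nuclei.labels.shape:
        raise SegmentationError("marker mask and label map shapes differ")
    seeds = nuclei.labels.copy()
    if not (seeds > 0).any() or not ((seeds > 0) & mask).any():
        if not (seeds > 0).any():
            warnings.warn("no nuclei to expand", stacklevel=2)
            return LabelMap(np.zeros_like(seeds))
        warnings.warn("no nuclei inside the marker mask", stacklevel=2)
        return LabelMap(seeds)
    territory = seeds.copy()
    domain = mask | (seeds > 0)
    # multi-source geodesic BFS, 4-connectivity, deterministic: at each
    # wavefront step an unclaimed pixel takes the smallest adjacent label
    changed = True
    while changed:
        cur = territory
        padded = np.pad(cur, 1, constant_values=0)
        neigh = np.stack(
            [
                padded[:-2, 1:-1], padded[2:, 1:-1],
                padded[1:-1, :-2], padded[1:-1, 2:],
            ]
        ).astype(np.int64)
        neigh[neigh == 0] = np.iinfo(np.int64).max
        best = neigh.min(axis=0)
        frontier = (cur == 0) & domain & (best < np.iinfo(np.int64).max)
        changed = bool(frontier.any())
        if changed:
            territory = cur.copy()
            territory[frontier] = best[frontier].astype(territory.dtype)
    return LabelMap(territory)


def assignments_table(
    assignments: list[Assignment],
    marker_names: list[str],
    transcript_names: list[str],
    mode: str,
) -> pd.DataFrame:
    rows = []
    for a in sorted(assignments, key=lambda a: a.nucleus_id):
        row = {"nucleus_id": a.nucleus_id, "cell_type": a.cell_type, "mode": mode}
        for ch in marker_names:
            row[f"{ch}_fraction"] = round(a.overlap_fraction.get(ch, 0.0), 6)
            row[f"{ch}_positive"] = ch in a.positive_channels
        for ch in transcript_names:
            row[f"count_{ch}"] = a.counts.get(ch, 0)
        rows.append(row)
    cols = (
        ["nucleus_id", "cell_type", "mode"]
        + [f"{ch}_{s}" for ch in marker_names for s in ("fraction", "positive")]
        + [f"count_{ch}" for ch in transcript_names]
    )
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
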