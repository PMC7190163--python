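"""Persistence: batch result tables, run metadata, and per-step QC images.

Every analysis run writes a metadata file capturing every parameter of
every stage, the channel manifest and any manual segmentation edits, so
the run can be re-established later and reproduce its outputs
bit-for-bit.  Quantification rows accumulate in append-only batch files
(CSV plus a spreadsheet twin for spreadsheet-based post-analysis);
re-writing a sample already present is rejected rather than duplicated.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image, ImageDraw

from . import __version__

STEP_NAMES = ("filtering", "detection", "segmentation", "assignment", "quantification")


class BatchConflictError(RuntimeError):
    pass


class MetadataError(KeyError):
    pass


_REQUIRED_KEYS = ("sample_id", "params", "manifest", "version")


@dataclass
class RunMetadata:
    sample_id: str
    params: dict                      # nested: filter/detect/seg/assign blocks
    manifest: list[dict] = field(default_factory=list)
    edits: dict = field(default_factory=dict)   # {"merge": [[ids]], "delete": [ids]}
    version: str = __version__
    seed: int | None = None
    timestamp: str = ""

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "params": self.params,
            "manifest": self.manifest,
            "edits": self.edits,
            "version": self.version,
            "seed": self.seed,
            "timestamp": self.timestamp,
        }


def save_metadata(meta: RunMetadata, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = meta.to_dict()
    if not doc["timestamp"]:
        doc["timestamp"] = datetime.datetime.now().isoformat(timespec="seconds")
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    return path


def load_metadata(path: str | Path, overrides: dict | None = None) -> RunMetadata:
    """Load a saved run; ``overrides`` uses dotted keys into the params
    block, e.g. ``{"seg.min_depth": 1e-5}``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    for key in _REQUIRED_KEYS:
        if key not in doc:
            raise MetadataError(f"metadata file missing required key {key!r}")
    meta = RunMetadata(
        sample_id=doc["sample_id"],
        params=doc["params"],
        manifest=doc.get("manifest", []),
        edits=doc.get("edits", {}) or {},
        version=doc["version"],
        seed=doc.get("seed"),
        timestamp=doc.get("timestamp", ""),
    )
    for dotted, value in (overrides or {}).items():
        block, _, key = dotted.partition(".")
        if not key or block not in meta.params:
            raise MetadataError(f"unknown override target {dotted!r}")
        meta.params[block][key] = value
    return meta


# ---------------------------------------------------------------------------
# batch results


def write_batch_results(results: pd.DataFrame, batch_path: str | Path) -> Path:
    """Append quantification rows to the cumulative batch CSV (and its
    .xlsx twin).  Prior rows are never rewritten; duplicate
    (sample_id, nucleus_id) pairs are a conflict."""
    batch_path = Path(batch_path)
    batch_path.parent.mkdir(parents=True, exist_ok=True)
    if {"sample_id", "nucleus_id"} - set(results.columns):
        raise ValueError("results must carry sample_id and nucleus_id columns")
    new_keys = list(zip(results["sample_id"], results["nucleus_id"]))
    if len(set(new_keys)) != len(new_keys):
        raise BatchConflictError("duplicate (sample_id, nucleus_id) within the new rows")
    if batch_path.exists():
        try:
            existing = pd.read_csv(batch_path)
        except Exception as e:
            raise BatchConflictError(f"corrupt batch file {batch_path}: {e}") from e
        dup = set(new_keys) & set(zip(existing["sample_id"], existing["nucleus_id"]))
        if dup:
            raise BatchConflictError(
                f"sample rows already present in batch: {sorted(dup)[:5]}"
            )
        if list(existing.columns) != list(results.columns):
            raise BatchConflictError("batch file schema differs from new rows")
        with open(batch_path, "a") as fh:
            results.to_csv(fh, header=False, index=False)
        combined = pd.concat([existing, results], ignore_index=True)
    else:
        results.to_csv(batch_path, index=False)
        combined = results
    _write_xlsx(combined, batch_path.with_suffix(".xlsx"))
    return batch_path


def _write_xlsx(df: pd.DataFrame, path: Path) -> None:
    import openpyxl

    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "results"
    ws.append(list(df.columns))
    for row in df.itertuples(index=False):
        ws.append(list(row))
    # fixed timestamps keep the file deterministic across re-runs
    epoch = datetime.datetime(2000, 1, 1)
    wb.properties.created = epoch
    wb.properties.modified = epoch
    wb.save(path)


# ---------------------------------------------------------------------------
# step images


def _grayscale_rgb(img2d: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(img2d)), float(np.max(img2d))
    g = np.zeros_like(img2d) if hi == lo else (img2d - lo) / (hi - lo)
    g8 = (g * 255).astype(np.uint8)
    return np.stack([g8] * 3, axis=-1)


_COMPOSITE_COLORS = (
    (70, 70, 255), (80, 255, 80), (255, 80, 80), (255, 220, 60), (220, 80, 255),
)


def render_composite(
    channel_images: dict[str, np.ndarray],
    counts_at: list[tuple[float, float, str]],
    out_path: str | Path,
) -> Path:
    """Pseudocolor overlay of every channel's projection with per-nucleus
    count annotations; deterministic PNG."""
    names = list(channel_images)
    shape = channel_images[names[0]].shape
    acc = np.zeros((*shape, 3), dtype=np.float64)
    for i, name in enumerate(names):
        img = channel_images[name]
        lo, hi = float(img.min()), float(img.max())
        g = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
        color = np.array(_COMPOSITE_COLORS[i % len(_COMPOSITE_COLORS)])
        acc += g[..., None] * color[None, None, :]
    arr = np.clip(acc, 0, 255).astype(np.uint8)
    img = Image.fromarray(arr)
    draw = ImageDraw.Draw(img)
    for y, x, text in counts_at:
        draw.text((x, y), text, fill=(255, 255, 255))
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    img.save(out_path, format="PNG")
    return out_path


def save_filter_qc(before: np.ndarray, after: np.ndarray, out_path: str | Path) -> Path:
    """Side-by-side max projections before/after band-pass filtering."""
    left = _grayscale_rgb(before)
    right = _grayscale_rgb(after)
    sep = np.full((left.shape[0], 2, 3), 255, dtype=np.uint8)
    img = Image.fromarray(np.concatenate([left, sep, right], axis=1))
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    img.save(out_path, format="PNG")
    return out_path
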