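"""Orchestration of the full analysis: load -> normalize -> filter ->
detect -> segment (-> correct) -> assign -> count -> report.

Each stage's artifact is cached on disk keyed by a content hash of its
parameters and upstream artifacts, so changing only a downstream
parameter re-runs only downstream stages.  A completed run writes, per
sample: ``spots.csv``, ``regions.csv``, ``assignments.csv``,
``labelmap.tif``, a metadata file, five per-step QC images plus a
pseudocolor composite, and appends its rows to the cumulative batch
files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assignment import (
    AssignmentParams, assign_nuclei, assignments_table, count_spots_per_region,
    detect_positive_regions, expand_cell_territories,
)
from .filtering import FilterParams, bandpass
from .image_model import Experiment, load_experiment, max_project, normalize_experiment
from .reporting import (
    RunMetadata, render_composite, save_filter_qc, save_metadata,
    write_batch_results,
)
from .segmentation import (
    LabelMap, SegmentationParams, correct_segmentation, render_segmentation,
    save_labelmap, segment_nuclei,
)
from .spot_detection import (
    DetectionParams, categorize_spots, detect_spots, render_detection_overlay,
)

log = logging.getLogger("fishcount")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, sample_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for sample {sample_id!r}: {cause}")
        self.stage = stage
        self.sample_id = sample_id
        self.cause = cause


@dataclass
class RunConfig:
    """Union of all stage parameter blocks plus I/O locations."""

    manifest: str | None = None          # path to channel manifest
    out_dir: str = "fishcount_out"
    sample_id: str | None = None
    filter: FilterParams = field(default_factory=FilterParams)
    detect: DetectionParams = field(default_factory=DetectionParams)
    seg: SegmentationParams = field(default_factory=SegmentationParams)
    assign: AssignmentParams = field(default_factory=AssignmentParams)
    edits: dict = field(default_factory=dict)   # {"merge": [[ids]], "delete": [ids]}
    batch_path: str | None = None        # defaults to out_dir/results.csv
    seed: int | None = None
    write_images: bool = True
    write_batch: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(doc)
        try:
            for key, cls_ in (
                ("filter", FilterParams), ("detect", DetectionParams),
                ("seg", SegmentationParams), ("assign", AssignmentParams),
            ):
                if key in kwargs and isinstance(kwargs[key], dict):
                    block = dict(kwargs[key])
                    for tup in ("report_bounds", "per_axis_sigma_high",
                                "per_axis_sigma_low"):
                        if block.get(tup) is not None:
                            block[tup] = tuple(block[tup])
                    kwargs[key] = cls_(**block)
        except TypeError as e:
            raise ConfigError(str(e)) from e
        return cls(**kwargs)

    def params_dict(self) -> dict:
        def block(p):
            d = dataclasses.asdict(p)
            return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

        return {
            "filter": block(self.filter),
            "detect": block(self.detect),
            "seg": block(self.seg),
            "assign": block(self.assign),
        }

    def to_metadata(self, sample_id: str, manifest: list[dict]) -> RunMetadata:
        return RunMetadata(
            sample_id=sample_id,
            params=self.params_dict(),
            manifest=manifest,
            edits=self.edits,
            version=__version__,
            seed=self.seed,
        )

    @classmethod
    def from_metadata(cls, meta: "RunMetadata", **io_kwargs) -> "RunConfig":
        doc = dict(meta.params)
        cfg = cls.from_dict({k: doc[k] for k in ("filter", "detect", "seg", "assign") if k in doc})
        cfg.edits = dict(meta.edits)
        cfg.seed = meta.seed
        cfg.sample_id = meta.sample_id
        for k, v in io_kwargs.items():
            setattr(cfg, k, v)
        return cfg


@dataclass
class RunResult:
    sample_id: str
    spots: dict[str, pd.DataFrame]            # transcript channel -> table
    labels: LabelMap
    territories: LabelMap | None
    assignments: pd.DataFrame
    batch_rows: pd.DataFrame
    background_counts: dict[str, int]
    metadata: RunMetadata
    cache_hits: list[str]
    image_paths: dict[str, Path]
    out_dir: Path


def _hash(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, np.ndarray):
            h.update(p.tobytes())
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


def run(config: RunConfig, experiment: Experiment | None = None) -> RunResult:
    """Execute the full pipeline for one field of view.

    ``experiment`` may be passed directly (e.g. a synthetic fixture);
    otherwise the channel manifest in the config is loaded.
    """
    if experiment is None:
        if config.manifest is None:
            raise ConfigError("config needs a manifest (or pass an experiment)")
        experiment = load_experiment(config.manifest, sample_id=config.sample_id)
    sample_id = config.sample_id or experiment.id
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cache_dir = out_dir / "cache"
    cache_dir.mkdir(exist_ok=True)
    cache_hits: list[str] = []
    images: dict[str, Path] = {}

    def stage(name):
        def deco(fn):
            def wrapped(*a, **kw):
                try:
                    return fn(*a, **kw)
                except Exception as e:  # noqa: BLE001
                    raise StageError(name, sample_id, e) from e
            return wrapped
        return deco

    norm = stage("normalize")(normalize_experiment)(experiment)

    # --- filtering + detection per transcript channel (cached) ------------
    spots_by_channel: dict[str, pd.DataFrame] = {}
    filtered_by_channel: dict[str, np.ndarray] = {}
    for tch in norm.transcript_channels:
        vol = norm.channels[tch].data
        fkey = _hash("bandpass", config.params_dict()["filter"], vol)
        fpath = cache_dir / f"bandpass_{tch}_{fkey}.npy"
        if fpath.exists():
            filtered = np.load(fpath)
            cache_hits.append(f"filtering:{tch}")
            log.info("cache hit: filtering %s", tch)
        else:
            filtered = stage("filtering")(bandpass)(vol, config.filter)
            np.save(fpath, filtered)
        filtered_by_channel[tch] = filtered

        dkey = _hash("detect", config.params_dict()["detect"], filtered)
        dpath = cache_dir / f"spots_{tch}_{dkey}.pkl"
        if dpath.exists():
            spots = pd.read_pickle(dpath)
            cache_hits.append(f"detection:{tch}")
            log.info("cache hit: detection %s", tch)
        else:
            spots = stage("detection")(detect_spots)(filtered, config.detect, channel=tch)
            spots.to_pickle(dpath)
        spots_by_channel[tch] = spots

    # --- segmentation (cached) --------------------------------------------
    nuclei_proj = max_project(norm.channels[norm.nuclei_channel])
    skey = _hash("seg", config.params_dict()["seg"], config.edits, nuclei_proj)
    spath = cache_dir / f"labels_{skey}.npy"
    if spath.exists():
        labels = LabelMap(np.load(spath))
        cache_hits.append("segmentation")
        log.info("cache hit: segmentation")
    else:
        labels = stage("segmentation")(segment_nuclei)(nuclei_proj, config.seg)
        if config.edits.get("merge") or config.edits.get("delete"):
            labels = stage("correction")(correct_segmentation)(
                labels, config.edits.get("merge"), config.edits.get("delete")
            )
        np.save(spath, labels.labels)

    # --- marker masks + assignment ----------------------------------------
    masks = {}
    for mch in norm.marker_channels:
        proj = max_project(norm.channels[mch])
        masks[mch] = stage("assignment")(detect_positive_regions)(
            proj,
            config.assign.threshold_for(mch),
            config.assign.marker_smoothing_sigma,
            config.assign.min_region_size,
        )
    assignments = stage("assignment")(assign_nuclei)(labels, masks, config.assign)

    # --- counting ----------------------------------------------------------
    territories = None
    count_map = labels
    if config.assign.mode == "mature" and masks:
        union = np.zeros(labels.labels.shape, dtype=bool)
        for m in masks.values():
            union |= m
        territories = stage("counting")(expand_cell_territories)(labels, union)
        count_map = territories
    background_counts: dict[str, int] = {}
    for tch, spots in spots_by_channel.items():
        spots, counts, bg = stage("counting")(count_spots_per_region)(spots, count_map)
        spots_by_channel[tch] = spots
        background_counts[tch] = bg
        for a in assignments:
            a.counts[tch] = counts.get(a.nucleus_id, 0)

    assignments_df = assignments_table(
        assignments, norm.marker_channels, norm.transcript_channels,
        config.assign.mode,
    )

    # --- outputs ------------------------------------------------------------
    manifest_doc = [
        {"name": s.name, "role": s.role.value, "path": s.path, "pages": list(s.pages) if s.pages else None}
        for s in norm.specs
    ]
    meta = config.to_metadata(sample_id, manifest_doc)
    all_spots = (
        pd.concat(spots_by_channel.values(), ignore_index=True)
        if spots_by_channel
        else next(iter(spots_by_channel.values()))
    )
    all_spots.to_csv(out_dir / "spots.csv", index=False)
    labels.regions()[["id", "area", "centroid_y", "centroid_x"]].to_csv(
        out_dir / "regions.csv", index=False
    )
    assignments_df.to_csv(out_dir / "assignments.csv", index=False)
    save_labelmap(labels, out_dir / "labelmap.tif")
    save_metadata(meta, out_dir / "metadata.yaml")

    batch_rows = assignments_df.copy()
    batch_rows.insert(0, "sample_id", sample_id)
    if config.write_batch:
        batch_path = Path(config.batch_path or out_dir / "results.csv")
        write_batch_results(batch_rows, batch_path)

    if config.write_images:
        tch0 = norm.transcript_channels[0]
        images["filtering"] = save_filter_qc(
            max_project(norm.channels[tch0].data),
            max_project(filtered_by_channel[tch0]),
            out_dir / f"{sample_id}_filtering.png",
        )
        lo, hi = config.detect.interval_bounds
        report = categorize_spots(spots_by_channel[tch0], lo, hi)
        images["detection"] = render_detection_overlay(
            filtered_by_channel[tch0], report, out_dir / f"{sample_id}_detection.png"
        )
        images["segmentation"] = render_segmentation(
            labels, nuclei_proj, out_dir / f"{sample_id}_segmentation.png"
        )
        assign_underlay = np.zeros(labels.labels.shape)
        for m in masks.values():
            assign_underlay += m.astype(float)
        images["assignment"] = render_segmentation(
            labels, assign_underlay if masks else nuclei_proj,
            out_dir / f"{sample_id}_assignment.png",
        )
        regions = labels.regions()
        count_text = [
            (
                float(r["centroid_y"]), float(r["centroid_x"]),
                ",".join(
                    str(int(assignments_df.loc[assignments_df["nucleus_id"] == r["id"], f"count_{t}"].iloc[0]))
                    for t in norm.transcript_channels
                ),
            )
            for _, r in regions.iterrows()
        ]
        images["quantification"] = render_composite(
            {tch0: max_project(filtered_by_channel[tch0])},
            count_text, out_dir / f"{sample_id}_quantification.png",
        )
        chans = {norm.nuclei_channel: nuclei_proj}
        for mch in norm.marker_channels:
            chans[mch] = max_project(norm.channels[mch])
        for t in norm.transcript_channels:
            chans[t] = max_project(filtered_by_channel[t])
        images["composite"] = render_composite(
            chans, count_text, out_dir / f"{sample_id}_composite.png"
        )

    return RunResult(
        sample_id=sample_id,
        spots=spots_by_channel,
        labels=labels,
        territories=territories,
        assignments=assignments_df,
        batch_rows=batch_rows,
        background_counts=background_counts,
        metadata=meta,
        cache_hits=cache_hits,
        image_paths=images,
        out_dir=out_dir,
    )
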