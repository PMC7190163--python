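"""Multi-channel 3D stack loading, validation and normalization.

A field of view is represented as an :class:`Experiment`: a set of named
:class:`Volume` objects (one per fluorescence channel), each a ``(z, y, x)``
intensity array, together with the :class:`ChannelSpec` manifest declaring
every channel's biological role.  Roles are ``transcript`` (smFISH/RNAscope
signal), ``nuclei`` (the DNA stain used for segmentation, e.g. DAPI) and
``cell_marker`` (immunostains identifying cell types, e.g. GFAP, SATB2).

Axis order is fixed as ``(z, y, x)``, origin top-left, 0-based indices.
Voxel sizes are carried as metadata in micrometres; all downstream length
parameters are expressed in voxels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
import yaml


class ChannelRole(str, enum.Enum):
    TRANSCRIPT = "transcript"
    NUCLEI = "nuclei"
    CELL_MARKER = "cell_marker"


class ManifestError(ValueError):
    """Channel manifest violates the experiment invariants."""


class ValidationError(ValueError):
    """Image data inconsistent with the manifest or with itself."""


@dataclass(frozen=True)
class ChannelSpec:
    """Declaration of one channel: its name, role and where its pages live.

    ``path`` may be shared between specs (one interleaved stack) in which
    case ``pages`` selects this channel's planes.  ``pages=None`` takes the
    whole file.
    """

    name: str
    role: ChannelRole
    path: str | None = None
    pages: tuple[int, int] | None = None  # half-open page interval

    def __post_init__(self):
        object.__setattr__(self, "role", ChannelRole(self.role))


@dataclass
class Volume:
    """A single-channel 3D intensity stack with voxel metadata."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (0.4, 0.285, 0.285)  # (dz,dy,dx) um
    normalized: bool = False

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[np.newaxis]
        if self.data.ndim != 3:
            raise ValidationError(
                f"volume must be 3D (z,y,x); got ndim={self.data.ndim}"
            )
        if self.data.size == 0:
            raise ValidationError("empty volume")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Experiment:
    """One field of view: named volumes plus their channel specs."""

    id: str
    channels: dict[str, Volume]
    specs: list[ChannelSpec] = field(default_factory=list)

    def __post_init__(self):
        validate_specs(self.specs)
        yx = None
        for spec in self.specs:
            if spec.name not in self.channels:
                raise ValidationError(f"spec {spec.name!r} has no loaded volume")
            shape = self.channels[spec.name].shape
            if yx is None:
                yx = shape[1:]
            elif shape[1:] != yx:
                first = self.specs[0].name
                raise ValidationError(
                    f"(y,x) shape mismatch: channel {first!r} is {yx}, "
                    f"channel {spec.name!r} is {shape[1:]}"
                )

    def channels_with_role(self, role: ChannelRole) -> list[str]:
        return [s.name for s in self.specs if s.role == role]

    @property
    def nuclei_channel(self) -> str:
        return self.channels_with_role(ChannelRole.NUCLEI)[0]

    @property
    def transcript_channels(self) -> list[str]:
        return self.channels_with_role(ChannelRole.TRANSCRIPT)

    @property
    def marker_channels(self) -> list[str]:
        return self.channels_with_role(ChannelRole.CELL_MARKER)


def validate_specs(specs: Sequence[ChannelSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ManifestError(f"duplicate channel names in manifest: {names}")
    n_nuclei = sum(s.role == ChannelRole.NUCLEI for s in specs)
    if n_nuclei != 1:
        raise ManifestError(
            f"manifest must declare exactly one nuclei channel, found {n_nuclei}"
        )
    if not any(s.role == ChannelRole.TRANSCRIPT for s in specs):
        raise ManifestError("manifest must declare at least one transcript channel")


def read_manifest(path: str | Path) -> tuple[list[ChannelSpec], tuple[float, float, float], str]:
    """Read a YAML/JSON channel manifest.

    Expected layout::

        sample_id: s1
        voxel_size: [0.4, 0.285, 0.285]
        page_order: zcyx          # or czyx, for interleaved stacks
        channels:
          - {name: DAPI, role: nuclei, path: dapi.tif}
          - {name: HES1, role: transcript, path: stack.tif, pages: [0, 15]}
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    specs = []
    for entry in doc["channels"]:
        pages = entry.get("pages")
        specs.append(
            ChannelSpec(
                name=entry["name"],
                role=entry["role"],
                path=entry.get("path"),
                pages=tuple(pages) if pages is not None else None,
            )
        )
    validate_specs(specs)
    voxel = tuple(doc.get("voxel_size", (0.4, 0.285, 0.285)))
    sample_id = str(doc.get("sample_id", path.stem))
    return specs, voxel, sample_id


def load_experiment(
    manifest: str | Path | Sequence[ChannelSpec],
    base_dir: str | Path | None = None,
    sample_id: str | None = None,
    voxel_size: tuple[float, float, float] = (0.4, 0.285, 0.285),
) -> Experiment:
    """Load a manifest plus TIFF stacks into an :class:`Experiment`.

    Raw integer intensities are preserved; call :func:`normalize` (the
    pipeline does) before filtering so thresholds operate on [0, 1].
    """
    if isinstance(manifest, (str, Path)):
        specs, voxel_size, mid = read_manifest(manifest)
        sample_id = sample_id or mid
        base_dir = Path(base_dir) if base_dir is not None else Path(manifest).parent
    else:
        specs = list(manifest)
        validate_specs(specs)
        base_dir = Path(base_dir) if base_dir is not None else Path(".")
        sample_id = sample_id or "experiment"

    channels: dict[str, Volume] = {}
    for spec in specs:
        if spec.path is None:
            raise ManifestError(f"channel {spec.name!r} has no source path")
        fp = base_dir / spec.path
        if not fp.exists():
            raise FileNotFoundError(f"channel {spec.name!r}: file not found: {fp}")
        data = tifffile.imread(fp)
        data = np.asarray(data)
        if data.ndim == 2:
            data = data[np.newaxis]
        if spec.pages is not None:
            lo, hi = spec.pages
            data = data[lo:hi]
        channels[spec.name] = Volume(data, voxel_size=voxel_size)
    return Experiment(id=sample_id, channels=channels, specs=specs)


def save_experiment(exp: Experiment, out_dir: str | Path) -> dict[str, Path]:
    """Write each channel as a multi-page TIFF; returns name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, vol in exp.channels.items():
        fp = out_dir / f"{exp.id}_{name}.tif"
        tifffile.imwrite(fp, vol.data)
        paths[name] = fp
    return paths


def normalize(v: Volume) -> Volume:
    """Per-channel min-max rescale to [0, 1].

    A constant channel maps to all zeros.  Idempotent: a volume already on
    [0, 1] with min 0 and max 1 is returned unchanged in value.
    """
    data = np.asarray(v.data, dtype=np.float64)
    if not np.isfinite(data).all():
        raise ValidationError("volume contains non-finite values")
    lo = data.min()
    hi = data.max()
    if hi == lo:
        out = np.zeros_like(data)
    else:
        out = (data - lo) / (hi - lo)
    return replace(v, data=out, normalized=True)


def normalize_experiment(exp: Experiment) -> Experiment:
    return Experiment(
        id=exp.id,
        channels={k: normalize(v) for k, v in exp.channels.items()},
        specs=exp.specs,
    )


def max_project(v: Volume | np.ndarray) -> np.ndarray:
    """Maximum-intensity projection along z: ``out[y, x] = max_z v[z, y, x]``."""
    data = v.data if isinstance(v, Volume) else np.asarray(v)
    if data.ndim == 2:
        return data.copy()
    return data.max(axis=0)
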