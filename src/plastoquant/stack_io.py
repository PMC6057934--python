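"""Stack and table I/O.

Reads and writes single-channel confocal z-stacks as grayscale TIFF, carrying
the physical voxel spacing (dz, dy, dx in micrometres) either from ImageJ-style
TIFF metadata or from an explicit override, and serialises per-network
descriptor tables.

Geometry convention used throughout the package: arrays are indexed (z, y, x),
physical coordinates are micrometres with the origin at the corner of voxel
(0, 0, 0), and the centre of voxel (k, j, i) sits at
((k + 0.5) dz, (j + 0.5) dy, (i + 0.5) dx).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .summary import DESCRIPTOR_NAMES, NetworkSummary

CONFIG_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class VoxelImage:
    """A 3D intensity grid with anisotropic physical voxel spacing.

    Parameters
    ----------
    intensities : ndarray, shape (nz, ny, nx)
        Non-negative, finite intensity values.
    spacing : tuple of float
        (dz, dy, dx) voxel spacing in micrometres, all strictly positive.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.intensities)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError(f"expected a 3D stack, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if np.min(arr) < 0:
            raise ValueError("intensities must be non-negative")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cubic micrometres."""
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass
class RunConfig:
    """All tunable pipeline parameters, serialisable as flat YAML.

    Segmentation: ``presmooth_sigma_um`` is a light Gaussian denoising filter
    applied before thresholding (set to zeros to disable),
    ``window_radius_um`` / ``offset_fraction`` drive the local adaptive
    threshold, ``min_component_voxels`` the speck cleanup.
    Graph extraction: ``orientation_threshold_deg`` and
    ``thickness_change_fraction`` flag change points, ``resampling_step_um``
    sets the point-to-point spacing, ``prune_length_um`` removes skeleton
    spurs, ``thinning_z_compression`` is the z step of the thinning grid
    relative to the in-plane step (set to the axial/lateral PSF ratio so the
    blurred tube cross-section is round on that grid; 1 for isotropic data),
    ``smooth_window_um`` is the centreline smoothing window and
    ``curvature_stride_um`` the baseline over which Menger curvature triplets
    are taken.  Statistics: two-sided significance level ``alpha``.
    """

    window_radius_um: float = 0.5
    offset_fraction: float = 0.10
    min_component_voxels: int = 50
    presmooth_sigma_um: tuple[float, float, float] = (0.12, 0.05, 0.05)
    orientation_threshold_deg: float = 20.0
    thickness_change_fraction: float = 0.20
    resampling_step_um: float = 0.05
    prune_length_um: float = 0.3
    min_terminal_um: float = 0.55
    thinning_z_compression: float = 4.0
    smooth_window_um: float = 0.25
    curvature_stride_um: float = 0.4
    tangent_offset_um: float = 0.1
    refine_centerline: bool = True
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        for name in ("window_radius_um", "orientation_threshold_deg",
                     "thickness_change_fraction", "resampling_step_um",
                     "prune_length_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        self.presmooth_sigma_um = tuple(float(s) for s in self.presmooth_sigma_um)
        if any(s < 0 for s in self.presmooth_sigma_um):
            raise ValueError("presmooth sigmas must be >= 0")
        self.seed = int(self.seed)

    def to_yaml(self, path) -> None:
        doc = {"schema_version": CONFIG_SCHEMA_VERSION}
        doc.update(dataclasses.asdict(self))
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        version = doc.pop("schema_version", None)
        if version != CONFIG_SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema_version {version!r}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def read_stack(path, spacing_override: Optional[Sequence[float]] = None,
               channel: Optional[int] = None) -> VoxelImage:
    """Read a grayscale TIFF stack into a :class:`VoxelImage`.

    Spacing is taken from ``spacing_override`` (dz, dy, dx in um) when given,
    else from ImageJ-style TIFF metadata (``spacing`` plus x/y resolution
    tags).  Raises if neither source provides a full spacing, or if the file
    carries multiple channels and no ``channel`` selector was passed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta_spacing = _spacing_from_metadata(tif)
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 4:
        # channel axis: either (z, y, x, c) contiguous samples or (c, z, y, x)
        if channel is None:
            raise ValueError(
                f"{path.name} has {data.shape} samples; pass channel= to select one")
        data = data[..., channel] if data.shape[-1] <= 4 else data[channel]
    if data.ndim != 3:
        raise ValueError(f"cannot interpret TIFF of shape {data.shape} as a z-stack")
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    elif meta_spacing is not None:
        spacing = meta_spacing
    else:
        raise ValueError(
            f"{path.name} carries no voxel spacing metadata; pass spacing_override")
    return VoxelImage(np.ascontiguousarray(data), spacing)


def _spacing_from_metadata(tif) -> Optional[tuple[float, float, float]]:
    ij = tif.imagej_metadata or {}
    dz = ij.get("spacing")
    page = tif.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
    except KeyError:
        return None
    dx = xres[1] / xres[0] if xres[0] else None
    dy = yres[1] / yres[0] if yres[0] else None
    if dz is None or dx is None or dy is None or dx <= 0 or dy <= 0 or dz <= 0:
        return None
    return (float(dz), float(dy), float(dx))


def write_stack(path, image: VoxelImage) -> None:
    """Write a :class:`VoxelImage` as an ImageJ-compatible grayscale TIFF.

    Spacing is stored losslessly in the resolution tags (x, y) and the ImageJ
    ``spacing`` field (z), so ``read_stack(write_stack(x)) == x``.
    """
    dz, dy, dx = image.spacing
    data = image.intensities
    if data.dtype == bool:
        data = data.astype(np.uint8) * 255
    if data.dtype not in (np.uint8, np.uint16, np.float32):
        data = data.astype(np.float32)
    tifffile.imwrite(
        str(path), data, imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


_TABLE_META_COLUMNS = ["group", "source"]


def write_table(records: list[NetworkSummary], path) -> None:
    """Write one CSV row per network: group, source, then the 25 descriptors.

    Column order is fixed by :data:`plastoquant.summary.DESCRIPTOR_NAMES`;
    values are written with 12 significant digits.  All records must share the
    descriptor schema.
    """
    for rec in records:
        missing = set(DESCRIPTOR_NAMES) - set(rec.scalars)
        extra = set(rec.scalars) - set(DESCRIPTOR_NAMES)
        if missing or extra:
            raise ValueError(
                f"heterogeneous descriptor schema for {rec.source!r}: "
                f"missing {sorted(missing)}, extra {sorted(extra)}")
    rows = [
        {"group": r.group, "source": r.source,
         **{k: r.scalars[k] for k in DESCRIPTOR_NAMES}}
        for r in records
    ]
    df = pd.DataFrame(rows, columns=_TABLE_META_COLUMNS + DESCRIPTOR_NAMES)
    df.to_csv(path, index=False, float_format="%.12g")


def read_table(path) -> list[NetworkSummary]:
    """Read a CSV written by :func:`write_table` back into summaries."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        scalars = {k: float(row[k]) for k in DESCRIPTOR_NAMES}
        out.append(NetworkSummary(group=str(row["group"]), source=str(row["source"]),
                                  scalars=scalars))
    return out


def read_summary_json(path) -> NetworkSummary:
    """Read a per-network JSON written by :func:`write_summary_json`."""
    doc = json.loads(Path(path).read_text())
    scalars = {k: (np.nan if v is None else float(v))
               for k, v in doc["scalars"].items()}
    arrays = {k: np.asarray(v, dtype=float) for k, v in doc["arrays"].items()}
    return NetworkSummary(group=doc["group"], source=doc["source"],
                          scalars=scalars, arrays=arrays)


def write_summary_json(summary: NetworkSummary, path) -> None:
    """Full per-network result (scalars plus raw element distributions)."""
    doc = {
        "group": summary.group,
        "source": summary.source,
        "scalars": {k: (None if not np.isfinite(v) else float(v))
                    for k, v in summary.scalars.items()},
        "arrays": {k: np.asarray(v, dtype=float).tolist()
                   for k, v in summary.arrays.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1))
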