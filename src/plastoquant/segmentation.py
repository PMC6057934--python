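"""Network segmentation: local adaptive threshold plus mask cleanup.

A voxel is foreground iff its intensity exceeds the local mean inside an
anisotropy-aware window, scaled by ``(1 + offset_fraction)``.  The threshold is
purely relative, so segmentation is invariant to uniform intensity scaling.
Manual corrections are replayable add/remove voxel masks rather than an
interactive step, so every run is reproducible from its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stack_io import VoxelImage

#: 26-neighbourhood structuring element used for all 3D connectivity.
STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BinaryMask:
    """Segmented network voxels with the source image's spacing."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.voxels.shape

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def count(self) -> int:
        return int(self.voxels.sum())


def local_adaptive_threshold(image: VoxelImage, window_radius_um: float = 0.5,
                             offset_fraction: float = 0.10) -> BinaryMask:
    """Threshold each voxel against its local mean.

    The window is a box whose per-axis half-width is
    ``round(window_radius_um / spacing)`` voxels (so the physical window is
    approximately isotropic despite anisotropic sampling); boundaries are
    handled by reflective padding.  Foreground:
    ``intensity > local_mean * (1 + offset_fraction)``.
    """
    if not -1.0 <= offset_fraction <= 1.0:
        raise ValueError(f"offset_fraction must lie in [-1, 1], got {offset_fraction}")
    radii = [int(round(window_radius_um / s)) for s in image.spacing]
    if min(radii) < 1:
        raise ValueError(
            f"window radius {window_radius_um} um is below one voxel for spacing "
            f"{image.spacing}")
    size = [2 * r + 1 for r in radii]
    local_mean = ndimage.uniform_filter(
        image.intensities.astype(np.float64), size=size, mode="reflect")
    fg = image.intensities > local_mean * (1.0 + offset_fraction)
    return BinaryMask(fg, image.spacing, provenance={
        "step": "local_adaptive_threshold",
        "window_radius_um": window_radius_um,
        "offset_fraction": offset_fraction,
    })


def clean_mask(mask: BinaryMask, min_component_voxels: int) -> BinaryMask:
    """Drop small 26-connected components and fill single-voxel holes.

    Stands in for the interactive correction pass of the original workflow:
    specks below ``min_component_voxels`` are removed, then isolated
    single-voxel cavities (background voxels whose six face neighbours are all
    foreground) are filled.  Raises if nothing survives the cutoff.
    """
    if min_component_voxels < 1:
        raise ValueError("min_component_voxels must be >= 1")
    labels, n = ndimage.label(mask.voxels, structure=STRUCTURE_26)
    if n == 0:
        raise ValueError("empty mask: nothing to clean")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = sizes >= min_component_voxels
    removed = int(n - keep[1:].sum())
    out = keep[labels]
    if not out.any():
        raise ValueError(
            f"all {n} components fall below the {min_component_voxels}-voxel cutoff")
    # single-voxel holes: all six face neighbours foreground
    face = ndimage.generate_binary_structure(3, 1)
    face[1, 1, 1] = False
    n_face_fg = ndimage.convolve(out.astype(np.uint8), face.astype(np.uint8),
                                 mode="constant", cval=0)
    filled = int(((~out) & (n_face_fg == 6)).sum())
    out |= (~out) & (n_face_fg == 6)
    prov = dict(mask.provenance)
    prov.update({"step": "clean_mask", "min_component_voxels": min_component_voxels,
                 "removed_components": removed, "filled_holes": filled})
    return BinaryMask(out, mask.spacing, provenance=prov)


def apply_manual_corrections(mask: BinaryMask, add: np.ndarray,
                             remove: np.ndarray) -> BinaryMask:
    """Apply replayable edits: ``mask | add`` then ``\\ remove``.

    ``add`` and ``remove`` must match the mask's shape and be disjoint; the
    edit counts are logged in provenance.  Raises if the result is empty.
    """
    add = np.asarray(add, dtype=bool)
    remove = np.asarray(remove, dtype=bool)
    if add.shape != mask.shape or remove.shape != mask.shape:
        raise ValueError("edit masks must match the mask shape")
    if (add & remove).any():
        raise ValueError("add and remove edits overlap")
    out = (mask.voxels | add) & ~remove
    if not out.any():
        raise ValueError("manual corrections removed every foreground voxel")
    prov = dict(mask.provenance)
    prov.update({"step": "apply_manual_corrections",
                 "added_voxels": int((add & ~mask.voxels).sum()),
                 "removed_voxels": int((remove & mask.voxels).sum())})
    return BinaryMask(out, mask.spacing, provenance=prov)
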