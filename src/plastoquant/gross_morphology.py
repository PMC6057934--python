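"""Wrapped hull and the seven gross-morphology shape descriptors.

The wrapped hull is the union over z-slices of each slice's filled 2D convex
hull — a per-slice "shrink wrap" around the network that defines its outer
surface.  From the hull and the mask we compute enclosed volume V_EN, network
volume V_PN, volume density rho_PN = V_PN / V_EN, and, from the eigenvalues of
the covariance of the hull's surface voxel centres (the shape matrix), the
greatest / smallest diameters, stretch and oblateness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.morphology import convex_hull_image

from .segmentation import BinaryMask

# relative eigenvalue spread below which the hull counts as isotropic
_ISOTROPY_EPS = 1e-9


@dataclass
class WrappedHull:
    """Per-slice convex hulls of the network plus the derived solid mask.

    ``polygons`` maps z-slice index to an (k, 2) array of hull vertex
    coordinates in um (y, x order); degenerate slices (fewer than three
    non-collinear foreground voxels) carry no polygon and are represented in
    the mask by the foreground voxels themselves.  ``surface_points`` are the
    centres of hull boundary voxels in um (z, y, x).
    """

    polygons: dict[int, np.ndarray]
    mask: np.ndarray
    spacing: tuple[float, float, float]
    surface_points: np.ndarray = field(repr=False, default=None)


@dataclass
class ShapeDescriptors:
    V_EN: float
    V_PN: float
    rho_PN: float
    d_max: float
    d_min: float
    St: float
    Ob: float
    shape_matrix: np.ndarray
    eigenvalues: np.ndarray   # descending
    eigenvectors: np.ndarray  # columns, matching eigenvalue order
    degenerate: bool = False


def wrapped_hull(mask: BinaryMask) -> WrappedHull:
    """Compute the per-slice convex hull ("wrapped hull") of a network mask."""
    vox = mask.voxels
    if not vox.any():
        raise ValueError("cannot wrap an empty mask")
    dz, dy, dx = mask.spacing
    hull_mask = np.zeros_like(vox)
    polygons: dict[int, np.ndarray] = {}
    for z in range(vox.shape[0]):
        sl = vox[z]
        n_fg = int(sl.sum())
        if n_fg == 0:
            continue
        yy, xx = np.nonzero(sl)
        pts_um = np.column_stack(((yy + 0.5) * dy, (xx + 0.5) * dx))
        if n_fg >= 3 and np.linalg.matrix_rank(pts_um - pts_um[0]) == 2:
            # filled hull on the pixel grid; union keeps the input a subset
            # even when qhull's inclusion test drops a borderline pixel
            hull_mask[z] = convex_hull_image(sl, offset_coordinates=False) | sl
            hull2d = ConvexHull(pts_um)
            polygons[z] = pts_um[hull2d.vertices]
        else:
            # degenerate slice: point or collinear run; hull is the run itself
            hull_mask[z] = sl
    surface = _surface_voxel_centers(hull_mask, mask.spacing)
    return WrappedHull(polygons=polygons, mask=hull_mask, spacing=mask.spacing,
                       surface_points=surface)


def _surface_voxel_centers(hull_mask: np.ndarray,
                           spacing: tuple[float, float, float]) -> np.ndarray:
    face = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(hull_mask, structure=face, border_value=0)
    boundary = hull_mask & ~interior
    idx = np.argwhere(boundary)
    return (idx + 0.5) * np.asarray(spacing)


def slice_polygon_area(polygon: np.ndarray) -> float:
    """Area of a convex hull polygon (um^2), by the shoelace formula."""
    y, x = polygon[:, 0], polygon[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))


def shape_descriptors(mask: BinaryMask, hull: WrappedHull) -> ShapeDescriptors:
    """The seven shape descriptors from a mask and its wrapped hull.

    The shape matrix is the covariance of the hull's surface voxel centres;
    eigenvalues lambda_1 >= lambda_2 >= lambda_3 give stretch
    ``St = 1 - sqrt(lambda_3 / lambda_1)`` and oblateness
    ``Ob = 2 (sqrt(lambda_2) - sqrt(lambda_3)) / (sqrt(lambda_1) - sqrt(lambda_3)) - 1``
    (+1 plate-like, -1 rod-like, 0 for the isotropic case).  Diameters are the
    surface-point extents along the first and third eigenvectors.
    """
    voxvol = mask.voxel_volume
    v_en = float(hull.mask.sum()) * voxvol
    v_pn = float(mask.voxels.sum()) * voxvol
    if not (0 < v_pn <= v_en):
        raise ValueError("mask/hull volumes inconsistent (is the hull from this mask?)")
    pts = np.asarray(hull.surface_points, dtype=float)
    centered = pts - pts.mean(axis=0)
    degenerate = pts.shape[0] < 4 or np.linalg.matrix_rank(centered) < 3
    if degenerate:
        extent = pts.max(axis=0) - pts.min(axis=0) if len(pts) else np.zeros(3)
        return ShapeDescriptors(
            V_EN=v_en, V_PN=v_pn, rho_PN=v_pn / v_en,
            d_max=float(extent.max()), d_min=float(extent.min()),
            St=0.0, Ob=0.0, shape_matrix=np.cov(pts.T) if len(pts) > 1 else np.zeros((3, 3)),
            eigenvalues=np.zeros(3), eigenvectors=np.eye(3), degenerate=True)
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    proj_1 = centered @ evecs[:, 0]
    proj_3 = centered @ evecs[:, 2]
    d_max = float(proj_1.max() - proj_1.min())
    d_min = float(proj_3.max() - proj_3.min())
    s1, s2, s3 = np.sqrt(evals)
    st = 1.0 - s3 / s1
    ob = 0.0 if (s1 - s3) <= _ISOTROPY_EPS * s1 else 2.0 * (s2 - s3) / (s1 - s3) - 1.0
    return ShapeDescriptors(
        V_EN=v_en, V_PN=v_pn, rho_PN=v_pn / v_en, d_max=d_max, d_min=d_min,
        St=float(st), Ob=float(ob), shape_matrix=cov, eigenvalues=evals,
        eigenvectors=evecs, degenerate=False)
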