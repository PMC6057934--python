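"""The eighteen element descriptors of a spatial graph.

Node descriptors (thickness, density, nearest-neighbour / surface / centre
distances, compactness), segment descriptors (length, Menger curvature,
thickness, inhomogeneity, point spacing) and connection descriptors (mean
connections per node, open-node percentage, inter-segment angles at 3- and
4-way junctions), plus the join into a 25-descriptor NetworkSummary.

Compactness C_PN = (mean d_nc - mean d_ns) / mean d_nc is close to 1 when the
nodes hug the network surface far from its centre of gravity.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .gross_morphology import WrappedHull, shape_descriptors
from .segmentation import BinaryMask
from .spatial_graph import SpatialGraph
from .summary import NetworkSummary


def menger_curvature(p1, p2, p3) -> float:
    """Menger curvature of three points: 4 * triangle area / product of sides.

    Equals the reciprocal circumradius of the circle through the points; 0 for
    collinear points.  Raises for coincident points.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    a = np.linalg.norm(p2 - p1)
    b = np.linalg.norm(p3 - p2)
    c = np.linalg.norm(p3 - p1)
    if min(a, b, c) == 0.0:
        raise ValueError("Menger curvature is undefined for coincident points")
    area = 0.5 * np.linalg.norm(np.cross(p2 - p1, p3 - p1))
    return float(4.0 * area / (a * b * c))


def _menger_many(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    a = np.linalg.norm(p2 - p1, axis=1)
    b = np.linalg.norm(p3 - p2, axis=1)
    c = np.linalg.norm(p3 - p1, axis=1)
    area = 0.5 * np.linalg.norm(np.cross(p2 - p1, p3 - p1), axis=1)
    denom = a * b * c
    out = np.zeros(len(a))
    ok = denom > 0
    out[ok] = 4.0 * area[ok] / denom[ok]
    return out


def node_descriptors(graph: SpatialGraph, hull: WrappedHull,
                     mask: BinaryMask) -> dict:
    """Per-node distance/thickness table and the network-level means.

    The network centre of gravity is the mean physical position of the mask's
    foreground voxels.  d_nn is the Euclidean nearest-neighbour distance
    (undefined, hence NaN, for a single-node graph); d_ns the distance to the
    nearest wrapped-hull surface voxel centre; nodes lying exactly at the
    centre of gravity are excluded from the d_ns/d_nc ratio and from C_PN.
    """
    nodes = graph.census_nodes
    n = len(nodes)
    if n == 0:
        raise ValueError("graph has no nodes")
    pos = np.array([nd.position for nd in nodes])
    thick = np.array([nd.thickness_nm for nd in nodes])
    cog = (np.argwhere(mask.voxels) + 0.5) @ np.diag(mask.spacing)
    cog = cog.mean(axis=0)
    d_nc = np.linalg.norm(pos - cog, axis=1)
    surf_tree = cKDTree(hull.surface_points)
    d_ns, _ = surf_tree.query(pos)
    if n >= 2:
        node_tree = cKDTree(pos)
        dd, _ = node_tree.query(pos, k=2)
        d_nn = dd[:, 1]
    else:
        d_nn = np.full(n, np.nan)
    at_centre = d_nc <= 0.0
    ratio = np.where(at_centre, np.nan, d_ns / np.where(at_centre, 1.0, d_nc))
    mean_nc = float(d_nc[~at_centre].mean()) if (~at_centre).any() else np.nan
    mean_ns = float(d_ns[~at_centre].mean()) if (~at_centre).any() else np.nan
    c_pn = (mean_nc - mean_ns) / mean_nc if mean_nc and np.isfinite(mean_nc) else np.nan
    return {
        "N_n": n,
        "node_thickness_nm": thick,
        "d_nn_um": d_nn,
        "d_ns_um": d_ns,
        "d_nc_um": d_nc,
        "ratio_ns_nc": ratio,
        "excluded_at_centre": int(at_centre.sum()),
        "th_n": float(thick.mean()),
        "mean_d_nn": float(np.nanmean(d_nn)) if n >= 2 else np.nan,
        "mean_d_ns": mean_ns,
        "mean_d_nc": mean_nc,
        "mean_ratio": float(np.nanmean(ratio)),
        "C_PN": float(c_pn),
    }


def segment_descriptors(graph: SpatialGraph, curvature_stride_um: float = 0.3) -> dict:
    """Per-segment geometry table and the network-level means.

    Curvature is the mean Menger curvature over point triplets; triplets are
    taken at a physical stride (default 0.3 um) rather than at neighbouring
    resampled points, because the local circumradius of 50-nm-spaced points
    is dominated by sub-voxel position error.  Segments with fewer than three
    points have curvature 0.  Inhomogeneity is the count of interior points
    that triggered the orientation / thickness change criteria.
    """
    if not graph.segments:
        raise ValueError("graph has no segments")
    lengths, curvatures, thicknesses, inhom, dpp = [], [], [], [], []
    for seg in graph.segments:
        pts = seg.points
        lengths.append(seg.length_um)
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        dpp.append(float(steps.mean()) * 1e3 if len(steps) else np.nan)  # nm
        if len(pts) < 3:
            curvatures.append(0.0)
        else:
            mean_step = max(float(steps.mean()), 1e-9)
            k = max(1, int(round(curvature_stride_um / mean_step)))
            k = min(k, (len(pts) - 1) // 2)
            kap = _menger_many(pts[:-2 * k], pts[k:-k], pts[2 * k:])
            curvatures.append(float(kap.mean()))
        thicknesses.append(float(seg.thickness_nm.mean()))
        inhom.append(int(seg.change_flags.sum()))
    return {
        "N_s": len(graph.segments),
        "length_um": np.array(lengths),
        "curvature_per_um": np.array(curvatures),
        "thickness_nm": np.array(thicknesses),
        "inhomogeneity": np.array(inhom, dtype=float),
        "d_pp_nm": np.array(dpp),
        "L_s": float(np.mean(lengths)),
        "kappa_s": float(np.mean(curvatures)),
        "th_s": float(np.mean(thicknesses)),
        "I_s": float(np.mean(inhom)),
        "d_pp": float(np.nanmean(dpp)),
    }


def _tangent(seg, at_start: bool, offset_um: float) -> np.ndarray | None:
    """Unit chord from the segment end to the first point >= offset_um away."""
    pts = seg.points if at_start else seg.points[::-1]
    origin = pts[0]
    dist = np.linalg.norm(pts - origin, axis=1)
    far = np.nonzero(dist >= offset_um)[0]
    target = pts[far[0]] if len(far) else pts[-1]
    v = target - origin
    n = np.linalg.norm(v)
    return v / n if n > 0 else None


def connection_descriptors(graph: SpatialGraph, tangent_offset_um: float = 0.1) -> dict:
    """Connections per node, open-node percentage and junction angles.

    Angles are measured between all pairs of incident segment tangent
    directions at each 3- or 4-way junction (tangent = chord to the first
    polyline point at least ``tangent_offset_um`` from the node, damping voxel
    jitter), averaged per node and then over the network.  Cycle segments
    carry no junction and are excluded.
    """
    nodes = graph.census_nodes
    if not nodes:
        raise ValueError("graph has no nodes")
    junctions = [n for n in nodes if n.kind == "junction"]
    n_open = sum(1 for n in nodes if n.kind == "open")
    n_c = float(np.mean([n.degree for n in junctions])) if junctions else np.nan
    n_oe = 100.0 * n_open / len(nodes)
    incident: dict[int, list] = {n.id: [] for n in nodes}
    for seg in graph.segments:
        a, b = seg.nodes
        if a in incident:
            incident[a].append((seg, True))
        if b in incident:
            incident[b].append((seg, False))
    per_node_means = {3: [], 4: []}
    all_angles = {3: [], 4: []}
    for nd in junctions:
        if nd.degree not in (3, 4):
            continue
        tangents = [t for seg, at_start in incident[nd.id]
                    if (t := _tangent(seg, at_start, tangent_offset_um)) is not None]
        if len(tangents) < 2:
            continue
        angles = []
        for i in range(len(tangents)):
            for j in range(i + 1, len(tangents)):
                cosang = float(np.clip(np.dot(tangents[i], tangents[j]), -1.0, 1.0))
                angles.append(np.degrees(np.arccos(cosang)))
        per_node_means[nd.degree].append(float(np.mean(angles)))
        all_angles[nd.degree].extend(angles)
    theta3 = float(np.mean(per_node_means[3])) if per_node_means[3] else np.nan
    theta4 = float(np.mean(per_node_means[4])) if per_node_means[4] else np.nan
    return {
        "n_c": n_c,
        "n_oe": n_oe,
        "theta_c3": theta3,
        "theta_c4": theta4,
        "angles3_deg": np.array(all_angles[3]),
        "angles4_deg": np.array(all_angles[4]),
        "node_mean_angles3_deg": np.array(per_node_means[3]),
        "node_mean_angles4_deg": np.array(per_node_means[4]),
    }


def summarize_network(mask: BinaryMask, hull: WrappedHull, graph: SpatialGraph,
                      group: str = "", source: str = "",
                      curvature_stride_um: float = 0.3,
                      tangent_offset_um: float = 0.1) -> NetworkSummary:
    """Join shape + element descriptors into one 25-descriptor record."""
    shape = shape_descriptors(mask, hull)
    nd = node_descriptors(graph, hull, mask)
    sd = segment_descriptors(graph, curvature_stride_um=curvature_stride_um)
    cd = connection_descriptors(graph, tangent_offset_um=tangent_offset_um)
    scalars = {
        "V_EN": shape.V_EN, "V_PN": shape.V_PN, "rho_PN": shape.rho_PN,
        "d_max": shape.d_max, "d_min": shape.d_min, "St": shape.St, "Ob": shape.Ob,
        "N_n": nd["N_n"], "th_n": nd["th_n"],
        "rho_n": nd["N_n"] / shape.V_EN,
        "d_nn": nd["mean_d_nn"], "d_ns": nd["mean_d_ns"], "d_nc": nd["mean_d_nc"],
        "ratio_ns_nc": nd["mean_ratio"], "C_PN": nd["C_PN"],
        "N_s": sd["N_s"], "L_s": sd["L_s"], "kappa_s": sd["kappa_s"],
        "th_s": sd["th_s"], "I_s": sd["I_s"], "d_pp": sd["d_pp"],
        "n_c": cd["n_c"], "n_oe": cd["n_oe"],
        "theta_c3": cd["theta_c3"], "theta_c4": cd["theta_c4"],
    }
    arrays = {
        "node_thickness_nm": nd["node_thickness_nm"],
        "d_nn_um": nd["d_nn_um"], "d_ns_um": nd["d_ns_um"], "d_nc_um": nd["d_nc_um"],
        "ratio_ns_nc": nd["ratio_ns_nc"],
        "segment_length_um": sd["length_um"],
        "segment_curvature_per_um": sd["curvature_per_um"],
        "segment_thickness_nm": sd["thickness_nm"],
        "segment_inhomogeneity": sd["inhomogeneity"],
        "point_to_point_nm": sd["d_pp_nm"],
        "angles3_deg": cd["angles3_deg"], "angles4_deg": cd["angles4_deg"],
    }
    return NetworkSummary(group=group, source=source, scalars=scalars, arrays=arrays)
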