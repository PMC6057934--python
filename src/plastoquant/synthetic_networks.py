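"""Synthetic filament-network phantoms with exact ground truth.

Generates connected ground-truth networks that emulate the plastoskeleton of a
single chloroplast: junction nodes of degree mostly 3 (some 4) arranged on an
oblate ellipsoid shell (the networks observed in vivo hug the organelle
envelope), segments rendered as circular arcs (so Menger curvature has the
closed form 1/R), a minority of very thick "meganodes" (spheres of 480-520 nm
diameter), and a few open-ended filaments pointing out of the network hull.
Phantoms are voxelized onto an anisotropic grid, blurred with an anisotropic
Gaussian approximating the confocal PSF, and degraded with detector noise.

Everything is deterministic given the spec's seed; the noiseless render does
not consume random numbers at all.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .segmentation import BinaryMask
from .stack_io import VoxelImage
from .summary import NetworkSummary


class InfeasibleSpecError(ValueError):
    """The requested node/degree/endpoint combination cannot form a network."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for one phantom network.

    Distances in micrometres unless the name says nm.  ``degree_probs`` is the
    distribution of junction degrees over {3, 4}; ``curvature_level`` is the
    arc bow height as a fraction of the chord; ``baseline_fraction`` is the
    detector offset relative to the signal amplitude; Gaussian noise SD is
    ``amplitude / snr`` (``snr=None`` renders noiselessly).
    """

    domain_um: tuple[float, float, float] = (4.0, 6.0, 6.0)   # (z, y, x)
    spacing: tuple[float, float, float] = (0.24, 0.042, 0.042)
    n_junctions: int = 35
    degree_probs: dict = field(default_factory=lambda: {3: 0.85, 4: 0.15})
    n_open: int = 2
    segment_length_mean_um: float = 0.8
    segment_length_sd_um: float = 0.2
    radius_mean_nm: float = 60.0
    radius_sd_nm: float = 8.0
    meganode_fraction: float = 0.0
    meganode_diameter_nm: tuple[float, float] = (480.0, 520.0)
    curvature_level: float = 0.07
    min_separation_um: float = 0.7
    shell_margin_um: float = 0.8
    shell_jitter: float = 0.15
    blur_sigma_um: tuple[float, float, float] = (0.3, 0.07, 0.07)  # (z, y, x)
    snr: float | None = 10.0
    baseline_fraction: float = 2.0
    poisson_scale: float = 0.0
    amplitude: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.meganode_fraction <= 1.0:
            raise ValueError("meganode_fraction must lie in [0, 1]")
        lo, hi = self.meganode_diameter_nm
        if not (2 * self.radius_mean_nm < lo <= hi):
            raise ValueError("meganode diameters must exceed the filament diameter")
        if hi * 1e-3 >= min(self.domain_um):
            raise ValueError("meganode diameter must be far below the domain size")
        if any(s < 0 for s in self.blur_sigma_um):
            raise ValueError("blur sigmas must be >= 0")
        for name in ("segment_length_mean_um", "radius_mean_nm", "min_separation_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(sum(self.degree_probs.values()) - 1.0) > 1e-9 or \
                set(self.degree_probs) - {3, 4}:
            raise ValueError("degree_probs must be a distribution over {3, 4}")


@dataclass
class GTNode:
    id: int
    position: np.ndarray     # um (z, y, x)
    radius_nm: float
    kind: str                # 'junction' | 'endpoint' | 'meganode' | 'cycle'


@dataclass
class GTSegment:
    id: int
    points: np.ndarray       # (n, 3) um polyline, ends coincide with nodes
    radius_nm: np.ndarray    # per-point radius
    nodes: tuple[int, int]
    curvature_per_um: float  # exact Menger curvature of the arc (0 straight)
    length_um: float         # exact arc length


@dataclass
class GroundTruthGraph:
    nodes: list[GTNode]
    segments: list[GTSegment]

    def __post_init__(self):
        pos = {n.id: n.position for n in self.nodes}
        for seg in self.segments:
            a, b = seg.nodes
            if not (np.allclose(seg.points[0], pos[a], atol=1e-9)
                    and np.allclose(seg.points[-1], pos[b], atol=1e-9)):
                raise ValueError(f"segment {seg.id} ends do not coincide with its nodes")
        degree = {n.id: 0 for n in self.nodes}
        for seg in self.segments:
            degree[seg.nodes[0]] += 1
            degree[seg.nodes[1]] += 1
        for n in self.nodes:
            if n.kind in ("junction", "meganode") and degree[n.id] < 3:
                raise ValueError(f"junction node {n.id} has degree {degree[n.id]} < 3")
            if n.kind == "endpoint" and degree[n.id] != 1:
                raise ValueError(f"endpoint node {n.id} has degree {degree[n.id]} != 1")
        g = self.to_networkx()
        if g.number_of_nodes() and not nx.is_connected(g):
            raise ValueError("ground-truth graph must be connected")

    def degree(self, nid: int) -> int:
        return sum((s.nodes[0] == nid) + (s.nodes[1] == nid) for s in self.segments)

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n in self.nodes:
            g.add_node(n.id, kind=n.kind, radius_nm=n.radius_nm,
                       z=float(n.position[0]), y=float(n.position[1]),
                       x=float(n.position[2]))
        for s in self.segments:
            g.add_edge(*s.nodes, key=s.id, length_um=s.length_um,
                       curvature_per_um=s.curvature_per_um)
        return g

    def to_json(self, path) -> None:
        doc = {
            "nodes": [{"id": n.id, "position_um": n.position.tolist(),
                       "radius_nm": n.radius_nm, "kind": n.kind}
                      for n in self.nodes],
            "segments": [{"id": s.id, "nodes": list(s.nodes),
                          "points_um": s.points.tolist(),
                          "radius_nm": s.radius_nm.tolist(),
                          "curvature_per_um": s.curvature_per_um,
                          "length_um": s.length_um}
                         for s in self.segments],
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path) -> "GroundTruthGraph":
        doc = json.loads(Path(path).read_text())
        nodes = [GTNode(d["id"], np.array(d["position_um"]), d["radius_nm"], d["kind"])
                 for d in doc["nodes"]]
        segments = [GTSegment(d["id"], np.array(d["points_um"]),
                              np.array(d["radius_nm"]), tuple(d["nodes"]),
                              d["curvature_per_um"], d["length_um"])
                    for d in doc["segments"]]
        return cls(nodes, segments)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))


# --------------------------------------------------------------------------
# arc geometry helpers (chord + bow height parametrisation, exact curvature)

def arc_points(p0: np.ndarray, p1: np.ndarray, bow_dir: np.ndarray,
               bow_height: float, step_um: float = 0.02):
    """Circular-arc polyline from p0 to p1 bulging by ``bow_height``.

    Returns (points, curvature, arc_length); curvature is the exact Menger
    curvature 1/R with R = h/2 + c^2/(8h) (sagitta relation).  A zero bow
    gives the straight chord.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    chord = p1 - p0
    c = float(np.linalg.norm(chord))
    if c == 0:
        raise ValueError("degenerate segment: coincident endpoints")
    if bow_height <= 0:
        n = max(2, int(np.ceil(c / step_um)) + 1)
        t = np.linspace(0.0, 1.0, n)
        return p0 + t[:, None] * chord, 0.0, c
    u = chord / c
    w = np.asarray(bow_dir, dtype=float)
    w = w - np.dot(w, u) * u
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("bow direction parallel to the chord")
    w = w / nw
    h = float(bow_height)
    radius = h / 2.0 + c * c / (8.0 * h)
    mid = 0.5 * (p0 + p1)
    center = mid - (radius - h) * w
    alpha = np.arcsin(min(1.0, c / (2.0 * radius)))
    if h > c / 2.0:  # major arc
        alpha = np.pi - alpha
    arc_len = 2.0 * alpha * radius
    n = max(3, int(np.ceil(arc_len / step_um)) + 1)
    phi = np.linspace(-alpha, alpha, n)
    pts = center[None, :] + radius * (
        np.sin(phi)[:, None] * u[None, :] + np.cos(phi)[:, None] * w[None, :])
    pts[0], pts[-1] = p0, p1  # exact endpoints
    return pts, 1.0 / radius, arc_len


# --------------------------------------------------------------------------
# ground-truth sampling

def sample_ground_truth(spec: PhantomSpec) -> GroundTruthGraph:
    """Sample a connected network realising the spec exactly.

    Junction count and open-filament count are met exactly; junction degrees
    are drawn from ``degree_probs`` (one draw may be flipped 3<->4 to make the
    edge count integral, and degrees are raised where the requested endpoint
    count would otherwise exceed the free stubs).  Raises
    :class:`InfeasibleSpecError` rather than silently truncating.
    """
    rng = np.random.default_rng(spec.seed)
    center = np.asarray(spec.domain_um) / 2.0
    axes = center - spec.shell_margin_um
    if np.any(axes <= 0):
        raise InfeasibleSpecError("shell margin leaves no room inside the domain")

    if spec.n_junctions == 0:
        return _open_filament_only(spec, rng, center)

    positions = _sample_shell_positions(rng, spec.n_junctions, center, axes,
                                        spec.min_separation_um, spec.shell_jitter)
    degrees = _assign_degrees(rng, spec)
    edges, free_stubs = _wire_junctions(rng, positions, degrees, spec.n_open)

    nodes: list[GTNode] = []
    segments: list[GTSegment] = []
    seg_radii = {}
    for j in range(spec.n_junctions):
        nodes.append(GTNode(j, positions[j], 0.0, "junction"))

    def draw_radius():
        return float(np.clip(rng.normal(spec.radius_mean_nm, spec.radius_sd_nm),
                             20.0, 4 * spec.radius_mean_nm))

    for a, b in edges:
        r = draw_radius()
        pts, kappa, length = _junction_arc(rng, positions[a], positions[b],
                                           center, spec.curvature_level)
        sid = len(segments)
        segments.append(GTSegment(sid, pts, np.full(len(pts), r), (a, b),
                                  kappa, length))
        seg_radii[sid] = r

    # open filaments: outward from junctions that still have free stubs
    existing = list(positions)
    for j in free_stubs:
        r = draw_radius()
        pos_e = _place_endpoint(rng, positions[j], center, spec, existing)
        existing.append(pos_e)
        nid = len(nodes)
        nodes.append(GTNode(nid, pos_e, r, "endpoint"))
        pts, kappa, length = _junction_arc(rng, positions[j], pos_e, center,
                                           spec.curvature_level)
        sid = len(segments)
        segments.append(GTSegment(sid, pts, np.full(len(pts), r), (j, nid),
                                  kappa, length))

    # junction radii: thickest incident filament; meganodes override
    incident_r = {n.id: [] for n in nodes}
    for seg in segments:
        r = float(seg.radius_nm[0])
        incident_r[seg.nodes[0]].append(r)
        incident_r[seg.nodes[1]].append(r)
    for n in nodes:
        if n.kind == "junction":
            n.radius_nm = max(incident_r[n.id])
    n_mega = int(round(spec.meganode_fraction * spec.n_junctions))
    if n_mega > 0:
        chosen = rng.choice(spec.n_junctions, size=n_mega, replace=False)
        lo, hi = spec.meganode_diameter_nm
        for j in np.atleast_1d(chosen):
            nodes[int(j)].kind = "meganode"
            nodes[int(j)].radius_nm = float(rng.uniform(lo, hi)) / 2.0
    return GroundTruthGraph(nodes, segments)


def _open_filament_only(spec, rng, center) -> GroundTruthGraph:
    if spec.n_open != 2:
        raise InfeasibleSpecError(
            "a junction-free phantom is a single open filament (n_open must be 2)")
    length = max(0.2, float(rng.normal(spec.segment_length_mean_um,
                                       spec.segment_length_sd_um)))
    direction = _unit(rng.normal(size=3))
    p0 = center - direction * length / 2.0
    p1 = center + direction * length / 2.0
    r = float(np.clip(rng.normal(spec.radius_mean_nm, spec.radius_sd_nm), 20.0,
                      4 * spec.radius_mean_nm))
    bow = _perpendicular(rng, direction)
    pts, kappa, arclen = arc_points(p0, p1, bow, spec.curvature_level * length)
    nodes = [GTNode(0, p0, r, "endpoint"), GTNode(1, p1, r, "endpoint")]
    segments = [GTSegment(0, pts, np.full(len(pts), r), (0, 1), kappa, arclen)]
    return GroundTruthGraph(nodes, segments)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _perpendicular(rng, u):
    w = rng.normal(size=3)
    w -= np.dot(w, u) * u
    n = np.linalg.norm(w)
    return w / n if n > 1e-9 else _perpendicular(rng, u)


def _sample_shell_positions(rng, n, center, axes, min_sep, jitter=0.0):
    out = []
    for _ in range(400 * n):
        u = _unit(rng.normal(size=3))
        p = center + axes * u * (1.0 - jitter * rng.random())
        if all(np.linalg.norm(p - q) >= min_sep for q in out):
            out.append(p)
            if len(out) == n:
                return np.array(out)
    raise InfeasibleSpecError(
        f"cannot place {n} junctions {min_sep} um apart on the shell")


def _assign_degrees(rng, spec) -> np.ndarray:
    degs = sorted(spec.degree_probs)
    probs = [spec.degree_probs[d] for d in degs]
    d = rng.choice(degs, size=spec.n_junctions, p=probs).astype(int)
    J, E = spec.n_junctions, spec.n_open
    # cycles = (sum(d) - 2*(J-1) - E) / 2 must be a non-negative integer
    def n_cycles():
        return sum(d) - 2 * (J - 1) - E
    while n_cycles() < 0:
        threes = np.nonzero(d == 3)[0]
        if len(threes) == 0:
            raise InfeasibleSpecError(
                f"{E} open filaments exceed the free stubs of {J} junctions")
        d[rng.choice(threes)] = 4
    if n_cycles() % 2 == 1:
        threes = np.nonzero(d == 3)[0]
        fours = np.nonzero(d == 4)[0]
        if len(threes):
            d[rng.choice(threes)] = 4
        elif len(fours) and n_cycles() >= 2:
            d[rng.choice(fours)] = 3
        else:
            raise InfeasibleSpecError("degree/endpoint parity cannot be satisfied")
    return d


def _wire_junctions(rng, positions, degrees, n_open):
    """Spanning tree + extra nearest-pair edges; returns edges and the
    junction indices (with multiplicity) left with free stubs for endpoints."""
    J = len(positions)
    rem = degrees.copy().astype(int)
    edges = []
    order = rng.permutation(J)
    placed = [order[0]]
    for j in order[1:]:
        cands = [p for p in placed if rem[p] > 0]
        if not cands:
            raise InfeasibleSpecError("cannot build a connected junction tree")
        dists = [np.linalg.norm(positions[j] - positions[p]) for p in cands]
        pick = cands[int(np.argmin(dists))]
        edges.append((int(pick), int(j)))
        rem[pick] -= 1
        rem[j] -= 1
        placed.append(j)
    n_extra = (rem.sum() - n_open) // 2
    adjacency = {tuple(sorted(e)) for e in edges}
    for _ in range(int(n_extra)):
        free = np.nonzero(rem > 0)[0]
        best, best_d = None, np.inf
        for i_idx in range(len(free)):
            for j_idx in range(i_idx + 1, len(free)):
                a, b = int(free[i_idx]), int(free[j_idx])
                penalty = 100.0 if (a, b) in adjacency else 0.0
                dd = np.linalg.norm(positions[a] - positions[b]) + penalty
                if dd < best_d:
                    best, best_d = (a, b), dd
        if best is None:
            raise InfeasibleSpecError("no junction pair left for an extra edge")
        edges.append(best)
        adjacency.add(best)
        rem[best[0]] -= 1
        rem[best[1]] -= 1
    free_stubs = [int(j) for j in range(J) for _ in range(rem[j])]
    assert len(free_stubs) == n_open
    return edges, free_stubs


def _junction_arc(rng, p0, p1, center, curvature_level):
    chord = p1 - p0
    c = np.linalg.norm(chord)
    mid = 0.5 * (p0 + p1)
    radial = mid - center
    bow = np.cross(chord, radial)
    if np.linalg.norm(bow) < 1e-9:
        bow = _perpendicular(rng, chord / c)
    bow = _unit(bow) * (1.0 if rng.random() < 0.5 else -1.0)
    return arc_points(p0, p1, bow, curvature_level * c)


def _place_endpoint(rng, anchor, center, spec, existing):
    for _ in range(50):
        radial = _unit(anchor - center)
        direction = _unit(radial + 0.5 * rng.normal(size=3))
        length = float(np.clip(rng.normal(spec.segment_length_mean_um,
                                          spec.segment_length_sd_um),
                               0.7 * spec.shell_margin_um, 0.9 * spec.shell_margin_um))
        pos = anchor + direction * length
        pos = np.clip(pos, 0.15, np.asarray(spec.domain_um) - 0.15)
        if all(np.linalg.norm(pos - q) >= spec.min_separation_um / 2 for q in existing):
            return pos
    return pos  # last candidate; separation is best-effort for endpoints


# --------------------------------------------------------------------------
# rendering

def rasterize(graph: GroundTruthGraph, spec: PhantomSpec,
              warn: bool = True) -> BinaryMask:
    """Exact binary tube/sphere rasterization on the spec's voxel grid.

    A voxel is foreground iff its centre lies within the local radius of a
    segment polyline or inside a node sphere (meganodes).  Warns when the
    filament radius is below one voxel along every axis (sub-resolution).
    """
    spacing = np.asarray(spec.spacing)
    shape = tuple(int(round(d / s)) for d, s in zip(spec.domain_um, spacing))
    vol = np.zeros(shape, dtype=bool)
    min_r = min((float(s.radius_nm.min()) for s in graph.segments), default=np.inf)
    if warn and min_r * 1e-3 < min(spacing):
        warnings.warn("filament radius below one voxel in all axes; "
                      "structures may be sub-resolution", stacklevel=2)
    for seg in graph.segments:
        r_um = float(seg.radius_nm[0]) * 1e-3
        samples = _densify(seg.points, step=min(spacing) / 2.0)
        _stamp_tube(vol, samples, r_um, spacing)
    for node in graph.nodes:
        if node.kind == "meganode":
            _stamp_tube(vol, node.position[None, :], node.radius_nm * 1e-3, spacing)
    return BinaryMask(vol, tuple(spacing), provenance={"step": "rasterize",
                                                       "seed": spec.seed})


def _centerline_reference(img, graph: GroundTruthGraph, spec: PhantomSpec) -> float:
    spacing = np.asarray(spec.spacing)
    pts = np.vstack([_densify(s.points, step=min(spacing)) for s in graph.segments])
    idx = np.clip((pts / spacing).astype(int), 0, np.asarray(img.shape) - 1)
    vals = img[idx[:, 0], idx[:, 1], idx[:, 2]]
    ref = float(np.median(vals))
    return ref if ref > 0 else float(img.max())


def _densify(points, step):
    seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    n = max(2, int(np.ceil(s[-1] / step)) + 1)
    t = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(t, s, points[:, d]) for d in range(3)])


def _stamp_tube(vol, samples, r_um, spacing):
    lo = samples.min(axis=0) - r_um - spacing
    hi = samples.max(axis=0) + r_um + spacing
    i0 = np.maximum((lo / spacing - 0.5).astype(int), 0)
    i1 = np.minimum((hi / spacing + 0.5).astype(int) + 1, vol.shape)
    if np.any(i0 >= i1):
        return
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(i0, i1)], indexing="ij")
    idx = np.stack([g.ravel() for g in grids], axis=1)
    centers = (idx + 0.5) * spacing
    tree = cKDTree(samples)
    dist, _ = tree.query(centers, distance_upper_bound=r_um + 1e-12)
    inside = np.isfinite(dist)
    sel = idx[inside]
    vol[sel[:, 0], sel[:, 1], sel[:, 2]] = True


def render_phantom(graph: GroundTruthGraph, spec: PhantomSpec) -> VoxelImage:
    """Rasterize, blur with the anisotropic PSF, scale, add baseline + noise.

    The structure is rasterized on a z-supersampled grid (~15 nm axial step:
    the filament diameter is below the native slice spacing), blurred with
    the anisotropic Gaussian PSF at that fine resolution, and only then
    sampled at the native slice centres — mirroring how a confocal microscope
    convolves continuously before its discrete z sampling, and keeping the
    axial position of thin filaments encoded in the sampled profile.

    Intensities: blurred structure exposed so the median centerline value
    equals ``amplitude``, on a detector baseline of
    ``baseline_fraction * amplitude``; Gaussian noise SD is
    ``amplitude / snr`` (plus optional Poisson resampling when
    ``poisson_scale`` > 0).  The noiseless part is independent of the seed.
    """
    dz, dy, dx = spec.spacing
    f = int(np.clip(np.ceil(dz / 0.015), 1, 32))
    nz = int(round(spec.domain_um[0] / dz))
    fine_spec = replace(spec, spacing=(dz / f, dy, dx),
                        domain_um=(nz * dz, *spec.domain_um[1:]))
    fine = rasterize(graph, fine_spec, warn=False).voxels.astype(np.float64)
    sigma_fine = [spec.blur_sigma_um[0] / (dz / f),
                  spec.blur_sigma_um[1] / dy, spec.blur_sigma_um[2] / dx]
    if any(s > 0 for s in sigma_fine):
        fine = ndimage.gaussian_filter(fine, sigma=sigma_fine)
    # sample the continuous (fine) field at the native slice centres
    zc = np.clip(np.round((np.arange(nz) + 0.5) * f - 0.5).astype(int),
                 0, fine.shape[0] - 1)
    img = fine[zc]
    # expose for the filaments: unit signal = median blurred intensity along
    # the centerlines (junctions and meganodes may exceed it)
    ref = _centerline_reference(img, graph, spec)
    if ref > 0:
        img = img / ref * spec.amplitude
    img += spec.baseline_fraction * spec.amplitude
    rng = np.random.default_rng(spec.seed)
    if spec.poisson_scale > 0:
        img = rng.poisson(np.clip(img * spec.poisson_scale, 0, None)) / spec.poisson_scale
    if spec.snr is not None and np.isfinite(spec.snr) and spec.snr > 0:
        img = img + rng.normal(0.0, spec.amplitude / spec.snr, size=img.shape)
    return VoxelImage(np.clip(img, 0.0, None).astype(np.float32), spec.spacing)


# --------------------------------------------------------------------------
# analytic descriptors (the oracle against which the pipeline is tested)

def ground_truth_descriptors(graph: GroundTruthGraph, spec: PhantomSpec,
                             group: str = "truth", source: str = "") -> NetworkSummary:
    """Descriptors computed analytically from the graph, never from voxels.

    Segment lengths and curvatures come from the exact arc geometry; node
    thickness is twice the node radius; hull quantities use the 3D convex
    hull of the segment polylines (surface sampled uniformly by facet area
    for the shape matrix).  d_pp and I_s are artefacts of the pipeline's
    resampling and are reported as missing (NaN / 0).
    """
    census = [n for n in graph.nodes if n.kind in ("junction", "meganode", "endpoint")]
    pos = np.array([n.position for n in census])
    thick = np.array([2.0 * n.radius_nm for n in census])
    degree = {n.id: graph.degree(n.id) for n in census}

    all_pts = np.vstack([s.points for s in graph.segments])
    weights = np.concatenate([_arc_weights(s.points) for s in graph.segments])
    cog = (all_pts * weights[:, None]).sum(axis=0) / weights.sum()

    try:
        hull = ConvexHull(all_pts)
    except QhullError:
        # (near-)degenerate point cloud, e.g. one straight filament
        hull = ConvexHull(all_pts, qhull_options="QJ")
    d_nc = np.linalg.norm(pos - cog, axis=1)
    d_ns = _distance_to_hull(pos, hull)
    if len(pos) >= 2:
        tree = cKDTree(pos)
        dd, _ = tree.query(pos, k=2)
        d_nn = dd[:, 1]
    else:
        d_nn = np.full(len(pos), np.nan)
    ok = d_nc > 0
    ratio = np.where(ok, d_ns / np.where(ok, d_nc, 1.0), np.nan)
    mean_nc, mean_ns = float(d_nc[ok].mean()), float(d_ns[ok].mean())
    c_pn = (mean_nc - mean_ns) / mean_nc

    lengths = np.array([s.length_um for s in graph.segments])
    curvatures = np.array([s.curvature_per_um for s in graph.segments])
    seg_thick = np.array([2.0 * float(s.radius_nm.mean()) for s in graph.segments])

    junctions = [n for n in census if n.kind in ("junction", "meganode")]
    n_open = sum(1 for n in census if n.kind == "endpoint")
    n_c = float(np.mean([degree[n.id] for n in junctions])) if junctions else np.nan
    theta = _gt_angles(graph, junctions, degree)

    v_pn = float(np.sum(np.pi * (np.array([s.radius_nm[0] * 1e-3
                                           for s in graph.segments]) ** 2) * lengths))
    v_pn += sum(4.0 / 3.0 * np.pi * (n.radius_nm * 1e-3) ** 3
                for n in graph.nodes if n.kind == "meganode")
    v_en = float(hull.volume)
    surf = _sample_hull_surface(hull, n_points=4000, seed=spec.seed)
    cov = np.cov(surf.T)
    evals = np.sort(np.clip(np.linalg.eigvalsh(cov), 0, None))[::-1]
    evecs = np.linalg.eigh(cov)[1][:, np.argsort(np.linalg.eigvalsh(cov))[::-1]]
    cen = surf - surf.mean(axis=0)
    d_max = float(np.ptp(cen @ evecs[:, 0]))
    d_min = float(np.ptp(cen @ evecs[:, 2]))
    s1, s2, s3 = np.sqrt(evals)
    st = 1.0 - s3 / s1
    ob = 0.0 if (s1 - s3) <= 1e-9 * s1 else 2.0 * (s2 - s3) / (s1 - s3) - 1.0

    scalars = {
        "V_EN": v_en, "V_PN": v_pn, "rho_PN": v_pn / v_en,
        "d_max": d_max, "d_min": d_min, "St": float(st), "Ob": float(ob),
        "N_n": len(census), "th_n": float(thick.mean()),
        "rho_n": len(census) / v_en,
        "d_nn": float(np.nanmean(d_nn)), "d_ns": mean_ns, "d_nc": mean_nc,
        "ratio_ns_nc": float(np.nanmean(ratio)), "C_PN": float(c_pn),
        "N_s": len(graph.segments), "L_s": float(lengths.mean()),
        "kappa_s": float(curvatures.mean()), "th_s": float(seg_thick.mean()),
        "I_s": 0.0, "d_pp": np.nan,
        "n_c": n_c, "n_oe": 100.0 * n_open / len(census),
        "theta_c3": theta[3], "theta_c4": theta[4],
    }
    arrays = {
        "node_thickness_nm": thick, "d_nn_um": d_nn, "d_ns_um": d_ns,
        "d_nc_um": d_nc, "ratio_ns_nc": ratio,
        "segment_length_um": lengths, "segment_curvature_per_um": curvatures,
        "segment_thickness_nm": seg_thick,
        "segment_inhomogeneity": np.zeros(len(lengths)),
        "point_to_point_nm": np.full(len(lengths), np.nan),
        "angles3_deg": theta["all3"], "angles4_deg": theta["all4"],
    }
    return NetworkSummary(group=group, source=source, scalars=scalars, arrays=arrays)


def _arc_weights(points):
    seglen = np.linalg.norm(np.diff(points, axis=0), axis=1)
    w = np.zeros(len(points))
    w[:-1] += seglen / 2.0
    w[1:] += seglen / 2.0
    return w


def _distance_to_hull(points, hull: ConvexHull) -> np.ndarray:
    # for points inside a convex hull the distance to the surface is the
    # smallest plane distance over facets; hull vertices get exactly 0
    eq = hull.equations  # outward normals: n.x + d <= 0 inside
    d = -(points @ eq[:, :3].T + eq[:, 3])
    return np.clip(d.min(axis=1), 0.0, None)


def _sample_hull_surface(hull: ConvexHull, n_points: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    pts = hull.points
    tris = pts[hull.simplices]
    areas = 0.5 * np.linalg.norm(
        np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1)
    if areas.sum() <= 0:  # (near-)degenerate hull, e.g. one straight filament
        return pts[hull.vertices]
    probs = areas / areas.sum()
    pick = rng.choice(len(tris), size=n_points, p=probs)
    r1 = np.sqrt(rng.random(n_points))
    r2 = rng.random(n_points)
    a, b, c = tris[pick, 0], tris[pick, 1], tris[pick, 2]
    return (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (r1 * r2)[:, None] * c


def _gt_angles(graph, junctions, degree):
    out = {3: [], 4: [], "all3": [], "all4": []}
    incident = {n.id: [] for n in junctions}
    for seg in graph.segments:
        for nid, at_start in ((seg.nodes[0], True), (seg.nodes[1], False)):
            if nid in incident:
                pts = seg.points if at_start else seg.points[::-1]
                if len(pts) >= 2:
                    incident[nid].append(_unit(pts[min(5, len(pts) - 1)] - pts[0]))
    for n in junctions:
        deg = degree[n.id]
        if deg not in (3, 4) or len(incident[n.id]) < 2:
            continue
        tangents = incident[n.id]
        angles = [np.degrees(np.arccos(np.clip(np.dot(tangents[i], tangents[j]),
                                               -1.0, 1.0)))
                  for i in range(len(tangents)) for j in range(i + 1, len(tangents))]
        out[deg].append(float(np.mean(angles)))
        out[f"all{deg}"].extend(angles)
    return {3: float(np.mean(out[3])) if out[3] else np.nan,
            4: float(np.mean(out[4])) if out[4] else np.nan,
            "all3": np.array(out["all3"]), "all4": np.array(out["all4"])}


# --------------------------------------------------------------------------
# simple deterministic fixtures (noiseless recovery tests)

def y_graph(arm_length_um: float = 1.5, radius_nm: float = 100.0,
            center=(2.0, 3.0, 3.0)) -> GroundTruthGraph:
    """Planar 'Y': one 3-way junction with arms 120 degrees apart."""
    c = np.asarray(center, dtype=float)
    nodes = [GTNode(0, c, radius_nm, "junction")]
    segments = []
    for k, ang in enumerate((90.0, 210.0, 330.0)):
        d = np.array([0.0, np.sin(np.radians(ang)), np.cos(np.radians(ang))])
        tip = c + d * arm_length_um
        nodes.append(GTNode(k + 1, tip, radius_nm, "endpoint"))
        pts, kappa, length = arc_points(c, tip, np.array([1.0, 0, 0]), 0.0)
        segments.append(GTSegment(k, pts, np.full(len(pts), radius_nm),
                                  (0, k + 1), kappa, length))
    return GroundTruthGraph(nodes, segments)


def plus_graph(arm_length_um: float = 1.5, radius_nm: float = 100.0,
               center=(2.0, 3.0, 3.0)) -> GroundTruthGraph:
    """Planar '+': one 4-way junction with orthogonal in-plane arms."""
    c = np.asarray(center, dtype=float)
    nodes = [GTNode(0, c, radius_nm, "junction")]
    segments = []
    dirs = [np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0]),
            np.array([0.0, 1.0, 0.0]), np.array([0.0, -1.0, 0.0])]
    for k, d in enumerate(dirs):
        tip = c + d * arm_length_um
        nodes.append(GTNode(k + 1, tip, radius_nm, "endpoint"))
        pts, kappa, length = arc_points(c, tip, np.array([1.0, 0, 0]), 0.0)
        segments.append(GTSegment(k, pts, np.full(len(pts), radius_nm),
                                  (0, k + 1), kappa, length))
    return GroundTruthGraph(nodes, segments)


def tube_graph(length_um: float = 4.0, radius_nm: float = 150.0,
               center=(2.0, 3.0, 3.0), axis=(0.0, 0.0, 1.0)) -> GroundTruthGraph:
    """A single straight open filament along ``axis``."""
    c = np.asarray(center, dtype=float)
    d = _unit(np.asarray(axis, dtype=float))
    p0, p1 = c - d * length_um / 2, c + d * length_um / 2
    nodes = [GTNode(0, p0, radius_nm, "endpoint"), GTNode(1, p1, radius_nm, "endpoint")]
    pts, kappa, length = arc_points(p0, p1, np.array([1.0, 0, 0]), 0.0)
    return GroundTruthGraph(nodes, [GTSegment(0, pts, np.full(len(pts), radius_nm),
                                              (0, 1), kappa, length)])


def torus_graph(major_radius_um: float = 1.5, tube_radius_nm: float = 120.0,
                center=(2.0, 3.0, 3.0)) -> GroundTruthGraph:
    """A closed circular loop (in-plane torus centerline)."""
    c = np.asarray(center, dtype=float)
    phi = np.linspace(0.0, 2.0 * np.pi, 400)
    pts = c[None, :] + major_radius_um * np.column_stack(
        [np.zeros_like(phi), np.sin(phi), np.cos(phi)])
    pts[-1] = pts[0]
    node = GTNode(0, pts[0], tube_radius_nm, "cycle")
    seg = GTSegment(0, pts, np.full(len(pts), tube_radius_nm), (0, 0),
                    1.0 / major_radius_um, 2.0 * np.pi * major_radius_um)
    return GroundTruthGraph([node], [seg])
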