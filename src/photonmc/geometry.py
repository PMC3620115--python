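"""Closed triangular surface meshes, nested tissue regions and ray queries.

Tissue anatomy is modelled as a tree of closed, outward-oriented triangle
meshes: every region's boundary mesh lies strictly inside its parent's, the
outermost boundary is unique, and the complement of everything is the
ambient medium (free space, refractive index ``ambient_n``).

Ray-mesh intersection uses a Moller-Trumbore barycentric test with
inclusive edges.  A per-region axis-aligned bounding-box cull runs ahead of
the flat vectorized triangle scan; a brute-force all-triangle scan is kept
(and tested) as the independent oracle.  Ties between coincident triangles
are broken by the smallest triangle id so replays are deterministic.

Epsilon policy: after any boundary event the photon origin is nudged
``EPS_NUDGE`` (1e-7 mm) along its new direction, and intersections closer
than ``EPS_NUDGE`` are discarded, which prevents self-hits on the surface
just left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import trimesh

from .optics import OpticalProperties

#: Post-event nudge distance / minimum accepted hit distance (mm).
EPS_NUDGE = 1e-7

#: Probe direction for point-in-region parity tests; an "irrational" slope
#: so axis-aligned mesh edges are never hit exactly.
_PROBE_DIR = np.array([1.0, 2.0, 3.0]) / np.sqrt(14.0)

#: Cube face labels in storage order: 2*axis + (normal points to +axis).
FACE_LABELS = ("-x", "+x", "-y", "+y", "-z", "+z")


class SurfaceMesh:
    """A closed, outward-oriented triangular surface mesh (units: mm)."""

    def __init__(self, vertices, faces, validate: bool = True):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array of vertex indices")
        v = self.vertices
        f = self.faces
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise ValueError("face indices out of range")
        e1 = v[f[:, 1]] - v[f[:, 0]]
        e2 = v[f[:, 2]] - v[f[:, 0]]
        n = np.cross(e1, e2)
        norms = np.linalg.norm(n, axis=1)
        if validate and np.any(norms <= 0):
            raise ValueError("mesh contains degenerate (zero-area) triangles")
        with np.errstate(invalid="ignore"):
            self.face_normals = n / norms[:, None]
        self.face_areas = 0.5 * norms
        self.face_centers = v[f].mean(axis=1)
        if validate:
            self._validate_closed()

    def _validate_closed(self) -> None:
        tm = self.as_trimesh()
        if not tm.is_watertight:
            raise ValueError("mesh is not closed (open or non-manifold edges)")
        if not tm.is_winding_consistent:
            raise ValueError("mesh winding is inconsistent")
        if self.signed_volume() <= 0:
            raise ValueError("mesh normals must point outward (positive signed volume)")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def signed_volume(self) -> float:
        """Enclosed volume by the divergence theorem (positive = outward)."""
        v = self.vertices[self.faces]
        return float(np.einsum("ij,ij->", v[:, 0], np.cross(v[:, 1], v[:, 2]))) / 6.0

    @property
    def aabb(self):
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    @property
    def n_triangles(self) -> int:
        return len(self.faces)

    def contains(self, points) -> np.ndarray:
        """Point-in-mesh test by crossing parity along the probe direction."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        counts = _crossing_counts(points, self.vertices[self.faces])
        return counts % 2 == 1

    def save(self, path: str) -> None:
        """Write the mesh to STL / PLY / OFF (by file extension)."""
        self.as_trimesh().export(path)

    @classmethod
    def load(cls, path: str) -> "SurfaceMesh":
        """Read a mesh from STL / PLY / OFF, re-orienting outward if needed."""
        tm = trimesh.load_mesh(path, process=True)
        mesh = cls(np.asarray(tm.vertices), np.asarray(tm.faces), validate=False)
        if mesh.signed_volume() < 0:
            mesh = cls(np.asarray(tm.vertices), np.asarray(tm.faces)[:, ::-1])
        else:
            mesh = cls(np.asarray(tm.vertices), np.asarray(tm.faces))
        return mesh


# ---------------------------------------------------------------------------
# Phantom generators
# ---------------------------------------------------------------------------

def make_cube_phantom(side: float, subdivisions_per_edge: int = 1) -> SurfaceMesh:
    """Axis-aligned cube phantom centered at the origin.

    Each face is a ``subdivisions x subdivisions`` grid of quads split into
    two triangles, giving exactly ``12 * subdivisions**2`` outward-oriented
    triangles.
    """
    if side <= 0:
        raise ValueError("cube side must be positive")
    k = int(subdivisions_per_edge)
    if k < 1:
        raise ValueError("subdivisions_per_edge must be >= 1")
    h = side / 2.0
    verts: list[tuple[float, float, float]] = []
    vindex: dict[tuple[int, int, int], int] = {}
    faces: list[tuple[int, int, int]] = []

    def vid(i: int, j: int, l: int) -> int:
        key = (i, j, l)
        if key not in vindex:
            vindex[key] = len(verts)
            verts.append((-h + i * side / k, -h + j * side / k, -h + l * side / k))
        return vindex[key]

    # (axis, sign): grid over the two remaining axes, wound outward.
    for axis in range(3):
        a1, a2 = [a for a in range(3) if a != axis]
        for sign in (0, 1):
            fixed = 0 if sign == 0 else k
            for i in range(k):
                for j in range(k):
                    idx = [0, 0, 0]
                    idx[axis] = fixed

                    def v(ii, jj):
                        q = idx.copy()
                        q[a1] = ii
                        q[a2] = jj
                        return vid(*q)

                    c00, c10 = v(i, j), v(i + 1, j)
                    c01, c11 = v(i, j + 1), v(i + 1, j + 1)
                    if (sign == 1) ^ (axis == 1):
                        faces.append((c00, c10, c11))
                        faces.append((c00, c11, c01))
                    else:
                        faces.append((c00, c11, c10))
                        faces.append((c00, c01, c11))
    return SurfaceMesh(np.array(verts), np.array(faces))


def make_ellipsoid_mesh(
    semi_axes: Sequence[float],
    center: Sequence[float] = (0.0, 0.0, 0.0),
    refinement: int = 3,
) -> SurfaceMesh:
    """Icosphere-based ellipsoid; volume -> (4/3) pi abc as refinement grows."""
    semi = np.asarray(semi_axes, dtype=float)
    if semi.shape != (3,) or np.any(semi <= 0):
        raise ValueError("semi_axes must be three positive lengths")
    ico = trimesh.creation.icosphere(subdivisions=int(refinement), radius=1.0)
    verts = np.asarray(ico.vertices) * semi + np.asarray(center, dtype=float)
    return SurfaceMesh(verts, np.asarray(ico.faces))


def make_sphere_mesh(
    radius: float, center: Sequence[float] = (0.0, 0.0, 0.0), refinement: int = 3
) -> SurfaceMesh:
    """Sphere phantom (equal-axis ellipsoid)."""
    return make_ellipsoid_mesh((radius, radius, radius), center, refinement)


# ---------------------------------------------------------------------------
# Regions and scenes
# ---------------------------------------------------------------------------

PropsLike = Union[OpticalProperties, Mapping[str, OpticalProperties]]


@dataclass
class Region:
    """One tissue region: a closed boundary mesh plus optical properties.

    ``props`` is either a single :class:`OpticalProperties` (single-band
    run) or a mapping from band name (e.g. ``"excitation"``/``"emission"``)
    to properties.  ``parent`` names the enclosing region, ``None`` meaning
    the region sits directly in the ambient medium.
    """

    id: str
    mesh: SurfaceMesh
    props: PropsLike
    parent: Optional[str] = None

    def props_for(self, band: str) -> OpticalProperties:
        if isinstance(self.props, OpticalProperties):
            return self.props
        try:
            return self.props[band]
        except KeyError:
            raise KeyError(f"region {self.id!r} has no optical properties for band {band!r}")


@dataclass
class RayHit:
    """Nearest ray-mesh intersection; always a region transition."""

    distance: float
    triangle_id: int
    region_from: Optional[str]
    region_to: Optional[str]
    hit_point: np.ndarray
    surface_normal: np.ndarray


@dataclass
class CompiledScene:
    """Flat array view of a scene, consumed by the transport kernel."""

    v0: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    normals: np.ndarray
    areas: np.ndarray
    centers: np.ndarray
    inside: np.ndarray        # (M,) region index owning each triangle
    outside: np.ndarray       # (M,) parent region index, -1 = ambient
    reg_bb_min: np.ndarray    # (R, 3)
    reg_bb_max: np.ndarray
    reg_tri_start: np.ndarray
    reg_tri_end: np.ndarray
    mu_a: np.ndarray          # (R, B)
    mu_s: np.ndarray
    g: np.ndarray
    n: np.ndarray
    ambient_n: float
    depth: np.ndarray
    region_ids: list
    band_names: tuple
    outer_is_box: bool
    box_min: np.ndarray
    box_max: np.ndarray

    @property
    def n_triangles(self) -> int:
        return len(self.v0)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def region_index(self, region_id: Optional[str]) -> int:
        if region_id is None:
            return -1
        return self.region_ids.index(region_id)


class Scene:
    """Nested closed mesh regions plus the ambient medium.

    Validates at build time (not per query) that every mesh is closed,
    oriented and non-degenerate, that parent links form a tree with a
    unique outermost region, and that children lie strictly inside their
    parents (all child vertices pass the parent's point-in-mesh test and
    sibling meshes do not interpenetrate, checked on vertices).
    """

    def __init__(self, regions: Sequence[Region], ambient_n: float = 1.0):
        self.ambient_n = float(ambient_n)
        self.regions = {r.id: r for r in regions}
        if len(self.regions) != len(regions):
            raise ValueError("duplicate region ids")
        roots = [r for r in regions if r.parent is None]
        if len(roots) != 1:
            raise ValueError("scene must have exactly one outermost region")
        self.root = roots[0]
        for r in regions:
            if r.parent is not None and r.parent not in self.regions:
                raise ValueError(f"region {r.id!r} references unknown parent {r.parent!r}")
        # depth by walking parent chains; also detects cycles
        self._depth: dict[str, int] = {}
        for r in regions:
            d, cur, seen = 0, r, set()
            while cur.parent is not None:
                if cur.id in seen:
                    raise ValueError("region parent links contain a cycle")
                seen.add(cur.id)
                cur = self.regions[cur.parent]
                d += 1
            self._depth[r.id] = d
        self._validate_containment()
        self._compiled: dict[tuple, CompiledScene] = {}

    def _validate_containment(self) -> None:
        for r in self.regions.values():
            if r.parent is None:
                continue
            parent = self.regions[r.parent]
            if not parent.mesh.contains(r.mesh.vertices).all():
                raise ValueError(f"region {r.id!r} is not contained in parent {r.parent!r}")
        # siblings must not interpenetrate (vertex-level check)
        regs = list(self.regions.values())
        for i, a in enumerate(regs):
            for b in regs[i + 1 :]:
                if a.parent != b.parent:
                    continue
                amin, amax = a.mesh.aabb
                bmin, bmax = b.mesh.aabb
                if np.any(amax < bmin) or np.any(bmax < amin):
                    continue
                if a.mesh.contains(b.mesh.vertices).any() or b.mesh.contains(
                    a.mesh.vertices
                ).any():
                    raise ValueError(f"sibling regions {a.id!r} and {b.id!r} intersect")

    def compile(self, bands: Sequence[str] = ("single",)) -> CompiledScene:
        key = tuple(bands)
        if key in self._compiled:
            return self._compiled[key]
        region_ids = list(self.regions.keys())
        index = {rid: i for i, rid in enumerate(region_ids)}
        R, B = len(region_ids), len(bands)
        chunks_v0, chunks_v1, chunks_v2, chunks_n = [], [], [], []
        chunks_area, chunks_center = [], []
        inside, outside = [], []
        start = np.zeros(R, dtype=np.int64)
        end = np.zeros(R, dtype=np.int64)
        bb_min = np.zeros((R, 3))
        bb_max = np.zeros((R, 3))
        mu_a = np.zeros((R, B))
        mu_s = np.zeros((R, B))
        g = np.zeros((R, B))
        n = np.zeros((R, B))
        depth = np.zeros(R, dtype=np.int32)
        offset = 0
        for i, rid in enumerate(region_ids):
            reg = self.regions[rid]
            mesh = reg.mesh
            tri = mesh.vertices[mesh.faces]
            m = len(tri)
            chunks_v0.append(tri[:, 0])
            chunks_v1.append(tri[:, 1])
            chunks_v2.append(tri[:, 2])
            chunks_n.append(mesh.face_normals)
            chunks_area.append(mesh.face_areas)
            chunks_center.append(mesh.face_centers)
            inside.append(np.full(m, i, dtype=np.int32))
            parent_idx = -1 if reg.parent is None else index[reg.parent]
            outside.append(np.full(m, parent_idx, dtype=np.int32))
            start[i], end[i] = offset, offset + m
            offset += m
            lo, hi = mesh.aabb
            bb_min[i], bb_max[i] = lo - 1e-9, hi + 1e-9
            depth[i] = self._depth[rid]
            for bi, band in enumerate(bands):
                p = reg.props_for(band)
                mu_a[i, bi], mu_s[i, bi], g[i, bi], n[i, bi] = p.mu_a, p.mu_s, p.g, p.n

        outer = self.root.mesh
        lo, hi = outer.aabb
        on_box = (
            np.isclose(outer.vertices, lo[None, :], atol=1e-9)
            | np.isclose(outer.vertices, hi[None, :], atol=1e-9)
        ).any(axis=1)
        outer_is_box = bool(
            on_box.all() and abs(outer.signed_volume() - np.prod(hi - lo)) < 1e-6 * np.prod(hi - lo)
        )
        compiled = CompiledScene(
            v0=np.ascontiguousarray(np.concatenate(chunks_v0)),
            v1=np.ascontiguousarray(np.concatenate(chunks_v1)),
            v2=np.ascontiguousarray(np.concatenate(chunks_v2)),
            normals=np.ascontiguousarray(np.concatenate(chunks_n)),
            areas=np.concatenate(chunks_area),
            centers=np.concatenate(chunks_center),
            inside=np.concatenate(inside),
            outside=np.concatenate(outside),
            reg_bb_min=bb_min,
            reg_bb_max=bb_max,
            reg_tri_start=start,
            reg_tri_end=end,
            mu_a=mu_a,
            mu_s=mu_s,
            g=g,
            n=n,
            ambient_n=self.ambient_n,
            depth=depth,
            region_ids=region_ids,
            band_names=key,
            outer_is_box=outer_is_box,
            box_min=lo.copy(),
            box_max=hi.copy(),
        )
        self._compiled[key] = compiled
        return compiled


# ---------------------------------------------------------------------------
# Ray queries
# ---------------------------------------------------------------------------

def _moller_trumbore(origin, direction, tri):
    """Vectorized inclusive-edge ray-triangle test.

    Returns (t, hit_mask) over an (m, 3, 3) triangle array.
    """
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    p = np.cross(direction[None, :], e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) > 1e-14
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / det
        tvec = origin[None, :] - v0
        u = np.einsum("ij,ij->i", tvec, p) * inv
        q = np.cross(tvec, e1)
        v = np.einsum("j,ij->i", direction, q) * inv
        t = np.einsum("ij,ij->i", e2, q) * inv
        hit = ok & (u >= 0.0) & (v >= 0.0) & (u + v <= 1.0) & (t > EPS_NUDGE)
    return t, hit


def _crossing_counts(points, tri) -> np.ndarray:
    counts = np.zeros(len(points), dtype=np.int64)
    for k, p in enumerate(points):
        t, hit = _moller_trumbore(p, _PROBE_DIR, tri)
        counts[k] = int(hit.sum())
    return counts


def brute_force_intersection(origin, direction, compiled: CompiledScene, max_dist=np.inf):
    """All-triangle oracle scan, no culling.  Returns (tri_id, distance) or None."""
    tri = np.stack([compiled.v0, compiled.v1, compiled.v2], axis=1)
    t, hit = _moller_trumbore(np.asarray(origin, float), np.asarray(direction, float), tri)
    hit &= t <= max_dist
    if not hit.any():
        return None
    t = np.where(hit, t, np.inf)
    best = int(np.argmin(t))  # argmin keeps the smallest id on exact ties
    return best, float(t[best])


def first_intersection(origin, direction, scene, max_dist=np.inf) -> Optional[RayHit]:
    """Nearest triangle hit across all region meshes within ``max_dist``.

    ``scene`` may be a :class:`Scene` or an already-compiled scene.  The
    transition (region_from, region_to) is deduced from the sign of
    direction . normal of the hit triangle: moving along the outward
    normal leaves the triangle's region, moving against it enters.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("direction must be a non-zero vector")
    direction = direction / norm
    compiled = scene.compile() if isinstance(scene, Scene) else scene

    best_id, best_t = -1, np.inf
    cap = min(max_dist, np.inf)
    for r in range(compiled.n_regions):
        if not _ray_hits_aabb(
            origin, direction, compiled.reg_bb_min[r], compiled.reg_bb_max[r], min(cap, best_t)
        ):
            continue
        s, e = compiled.reg_tri_start[r], compiled.reg_tri_end[r]
        tri = np.stack([compiled.v0[s:e], compiled.v1[s:e], compiled.v2[s:e]], axis=1)
        t, hit = _moller_trumbore(origin, direction, tri)
        hit &= t <= cap
        if not hit.any():
            continue
        t = np.where(hit, t, np.inf)
        local = int(np.argmin(t))
        if t[local] < best_t:
            best_t = float(t[local])
            best_id = int(s + local)
    if best_id < 0:
        return None
    nrm = compiled.normals[best_id]
    inside = int(compiled.inside[best_id])
    outside = int(compiled.outside[best_id])
    leaving = float(np.dot(direction, nrm)) > 0.0
    r_from, r_to = (inside, outside) if leaving else (outside, inside)
    ids = compiled.region_ids
    return RayHit(
        distance=best_t,
        triangle_id=best_id,
        region_from=None if r_from < 0 else ids[r_from],
        region_to=None if r_to < 0 else ids[r_to],
        hit_point=origin + best_t * direction,
        surface_normal=nrm.copy(),
    )


def _ray_hits_aabb(origin, direction, lo, hi, tmax) -> bool:
    t0, t1 = 0.0, tmax
    for a in range(3):
        d = direction[a]
        if abs(d) < 1e-300:
            if origin[a] < lo[a] or origin[a] > hi[a]:
                return False
            continue
        inv = 1.0 / d
        ta = (lo[a] - origin[a]) * inv
        tb = (hi[a] - origin[a]) * inv
        if ta > tb:
            ta, tb = tb, ta
        t0 = max(t0, ta)
        t1 = min(t1, tb)
        if t0 > t1:
            return False
    return True


def locate_region(point, scene) -> Optional[str]:
    """Innermost region containing ``point`` (None = ambient).

    Uses crossing parity of a probe ray against each region mesh; among
    regions with odd parity the deepest one in the containment tree wins.
    """
    compiled = scene.compile() if isinstance(scene, Scene) else scene
    point = np.asarray(point, dtype=float)
    best, best_depth = None, -1
    for r in range(compiled.n_regions):
        s, e = compiled.reg_tri_start[r], compiled.reg_tri_end[r]
        tri = np.stack([compiled.v0[s:e], compiled.v1[s:e], compiled.v2[s:e]], axis=1)
        _, hit = _moller_trumbore(point, _PROBE_DIR, tri)
        if int(hit.sum()) % 2 == 1 and compiled.depth[r] > best_depth:
            best, best_depth = compiled.region_ids[r], int(compiled.depth[r])
    return best


def face_grid_index(hit_point, face, grid, box_min, box_max):
    """Bin a point on a named box face into a (rows, cols) recording grid.

    The face chart spans the two axes of the face ordered by axis index
    (lower axis -> rows), with the origin at the minimal corner; bins are
    ``floor(local / delta)`` clamped to the last bin at the maximal edge.
    ``face`` is a label from :data:`FACE_LABELS` or the integer index.
    """
    p = np.asarray(hit_point, dtype=float)
    lo = np.asarray(box_min, dtype=float)
    hi = np.asarray(box_max, dtype=float)
    if isinstance(face, str):
        face = FACE_LABELS.index(face)
    axis, positive = divmod(face, 2)[0], face % 2
    plane = hi[axis] if positive else lo[axis]
    if abs(p[axis] - plane) > 1e-6:
        raise ValueError(f"point does not lie on face {FACE_LABELS[face]}")
    a1, a2 = [a for a in range(3) if a != axis]
    rows, cols = grid
    d1 = (hi[a1] - lo[a1]) / rows
    d2 = (hi[a2] - lo[a2]) / cols
    row = min(int((p[a1] - lo[a1]) / d1), rows - 1)
    col = min(int((p[a2] - lo[a2]) / d2), cols - 1)
    if row < 0 or col < 0:
        raise ValueError("point lies outside the face extent")
    return row, col
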