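"""Free-space tissue-to-CCD imaging: lens position mapping + Lambert energy mapping.

The tissue surface is treated as a collection of Lambertian emitters (the
exit-record cells of a transport run, each with outgoing flux density
J = exited weight / cell area).  A thin-lens camera maps each surface
element to a detector pixel by central projection through the lens center,
and the energy carried there follows Lambert's cosine law

    dE = J cos(theta_s) cos(theta_d) xi(r, r_d) dS / (pi |r - r_d|^2)

where xi is a 0/1 visibility factor against the scene meshes.  The energy
is evaluated at the virtual detector plane — the real detector plane
mirrored through the lens center, at distance v in front of it — and
assigned to the conjugate pixel by pure coordinate scaling (the flux
density at the mirrored point equals that at the pixel).  This keeps the
receiver facing the incoming light and |r - r_d| equal to the physical
propagation distance.  No aperture integration: ideal pinhole with
thin-lens conjugates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import EPS_NUDGE, CompiledScene, Scene, _moller_trumbore

#: Contributions with |r - r_d| below this are skipped (near-singular).
MIN_DISTANCE_MM = 1e-6


def _orthonormal_basis(axis: np.ndarray):
    """Two unit vectors spanning the plane perpendicular to ``axis``."""
    a = axis / np.linalg.norm(axis)
    helper = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(helper, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    return a, e1, e2


@dataclass
class CameraModel:
    """Thin-lens CCD camera.

    ``axis`` is the unit optical axis pointing from the lens center toward
    the scene.  The detector plane sits at distance ``v`` behind the lens,
    ``(rows, cols)`` pixels at ``pitch_mm`` pitch, row/col axes along the
    in-plane basis vectors.  Construction enforces the thin-lens relation
    1/u + 1/v = 1/f to 1e-9.
    """

    lens_center: np.ndarray
    axis: np.ndarray
    u: float
    v: float
    f: float
    rows: int = 120
    cols: int = 120
    pitch_mm: float = 0.1
    view_angle_deg: float = 0.0
    e1: np.ndarray = field(init=False, repr=False)
    e2: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.lens_center = np.asarray(self.lens_center, dtype=float)
        if abs(1.0 / self.u + 1.0 / self.v - 1.0 / self.f) > 1e-9:
            raise ValueError("thin-lens relation 1/u + 1/v = 1/f violated")
        self.axis, self.e1, self.e2 = _orthonormal_basis(np.asarray(self.axis, float))

    @classmethod
    def looking_at(
        cls,
        lens_center,
        target=(0.0, 0.0, 0.0),
        f: float = 50.0,
        u: Optional[float] = None,
        rows: int = 120,
        cols: int = 120,
        pitch_mm: float = 0.1,
        view_angle_deg: float = 0.0,
    ) -> "CameraModel":
        """Camera at ``lens_center`` aimed at ``target``; v from the lens law.

        ``u`` defaults to the lens-target distance (scene in focus).
        """
        lens_center = np.asarray(lens_center, float)
        axis = np.asarray(target, float) - lens_center
        dist = np.linalg.norm(axis)
        if dist == 0:
            raise ValueError("camera cannot be placed at its target")
        if u is None:
            u = dist
        if u <= f:
            raise ValueError("object distance must exceed the focal length")
        v = 1.0 / (1.0 / f - 1.0 / u)
        return cls(lens_center, axis / dist, u, v, f, rows, cols, pitch_mm, view_angle_deg)

    @property
    def magnification(self) -> float:
        return self.v / self.u

    def detector_extent_mm(self):
        return self.rows * self.pitch_mm, self.cols * self.pitch_mm


@dataclass
class SurfaceFluxMap:
    """Per-element outgoing flux density on the tissue surface.

    ``flux`` is weight per mm^2; ``centers``, ``normals`` (outward unit)
    and ``areas`` describe the elements (face-grid cells or triangles).
    """

    centers: np.ndarray
    normals: np.ndarray
    areas: np.ndarray
    flux: np.ndarray

    def total_weight(self) -> float:
        return float(np.sum(self.flux * self.areas))


@dataclass
class DetectorImage:
    """Pixel grid of received flux density (weight per mm^2)."""

    pixels: np.ndarray
    pitch_mm: float
    camera: CameraModel

    def total(self) -> float:
        return float(self.pixels.sum())

    def total_power(self) -> float:
        return float(self.pixels.sum() * self.pitch_mm**2)


def surface_flux_map(result, band: int = 0, source: str = "triangles") -> SurfaceFluxMap:
    """Build a flux map from a transport run's exit recorders.

    ``source`` selects the per-triangle record or the per-face grid cells
    of an axis-aligned box phantom.  Sum(J dS) equals the recorded exited
    weight of the chosen band.
    """
    compiled = result.compiled_scene
    if source == "triangles":
        rec = result.triangle_record
        if rec is None:
            raise ValueError("run has no triangle record")
        w = rec.data[band].sum(axis=-1)
        nz = w > 0
        areas = compiled.areas[nz]
        return SurfaceFluxMap(
            centers=compiled.centers[nz],
            normals=compiled.normals[nz],
            areas=areas,
            flux=w[nz] / areas,
        )
    if source == "face_grid":
        rec = result.face_record
        if rec is None:
            raise ValueError("run has no face-grid record")
        lo, hi = rec.box_min, rec.box_max
        n_bands, _, rows, cols, _ = rec.data.shape
        centers, normals, areas, flux = [], [], [], []
        for face in range(6):
            grid = rec.data[band, face].sum(axis=-1)
            nz_r, nz_c = np.nonzero(grid)
            if len(nz_r) == 0:
                continue
            axis = face // 2
            positive = face % 2 == 1
            a1, a2 = [a for a in range(3) if a != axis]
            d1 = (hi[a1] - lo[a1]) / rows
            d2 = (hi[a2] - lo[a2]) / cols
            pts = np.zeros((len(nz_r), 3))
            pts[:, axis] = hi[axis] if positive else lo[axis]
            pts[:, a1] = lo[a1] + (nz_r + 0.5) * d1
            pts[:, a2] = lo[a2] + (nz_c + 0.5) * d2
            nrm = np.zeros((len(nz_r), 3))
            nrm[:, axis] = 1.0 if positive else -1.0
            centers.append(pts)
            normals.append(nrm)
            areas.append(np.full(len(nz_r), d1 * d2))
            flux.append(grid[nz_r, nz_c] / (d1 * d2))
        if not centers:
            z = np.zeros((0, 3))
            return SurfaceFluxMap(z, z, np.zeros(0), np.zeros(0))
        return SurfaceFluxMap(
            np.concatenate(centers),
            np.concatenate(normals),
            np.concatenate(areas),
            np.concatenate(flux),
        )
    raise ValueError("source must be 'triangles' or 'face_grid'")


def lens_image_point(surface_point, camera: CameraModel):
    """Map a surface point to fractional (row, col) detector coordinates.

    Central projection through the lens center onto the detector plane at
    distance v behind the lens; the lateral magnification is v/depth
    (v/u for in-focus points) with image inversion.  Returns None when the
    projected point misses the detector extent; raises for points on the
    lens plane.
    """
    p = np.asarray(surface_point, dtype=float)
    rel = p - camera.lens_center
    depth = float(np.dot(rel, camera.axis))
    if abs(depth) < 1e-12:
        raise ValueError("surface point lies on the lens plane")
    if depth < 0:
        return None  # behind the camera
    scale = -camera.v / depth
    x = scale * float(np.dot(rel, camera.e1))
    y = scale * float(np.dot(rel, camera.e2))
    row = y / camera.pitch_mm + (camera.rows - 1) / 2.0
    col = x / camera.pitch_mm + (camera.cols - 1) / 2.0
    if not (-0.5 <= row <= camera.rows - 0.5 and -0.5 <= col <= camera.cols - 0.5):
        return None
    return row, col


def visibility(r, r_d, scene) -> int:
    """1 iff the open segment r -> r_d hits no scene triangle, else 0.

    Hits within the epsilon guard of ``r`` (the emitting surface itself)
    are ignored.
    """
    compiled = scene.compile() if isinstance(scene, Scene) else scene
    r = np.asarray(r, float)
    r_d = np.asarray(r_d, float)
    seg = r_d - r
    dist = np.linalg.norm(seg)
    if dist == 0:
        raise ValueError("visibility requires distinct endpoints")
    d = seg / dist
    tri = np.stack([compiled.v0, compiled.v1, compiled.v2], axis=1)
    t, hit = _moller_trumbore(r, d, tri)
    blocked = hit & (t < dist - EPS_NUDGE)
    return 0 if blocked.any() else 1


def lambertian_contribution(
    flux_density: float,
    area_mm2: float,
    r,
    surface_normal,
    r_d,
    detector_normal,
    scene=None,
) -> float:
    """Lambert-cosine flux-density increment at a receiving point.

    dE = J cos(theta_s) cos(theta_d) xi dS / (pi d^2) with the cosines
    clamped at zero (back-facing emitters/receivers contribute nothing).
    Near-singular geometry (d < 1 um) is skipped.
    """
    r = np.asarray(r, float)
    r_d = np.asarray(r_d, float)
    seg = r_d - r
    dist = float(np.linalg.norm(seg))
    if dist < MIN_DISTANCE_MM:
        return 0.0
    d_hat = seg / dist
    cos_s = max(0.0, float(np.dot(surface_normal, d_hat)))
    cos_d = max(0.0, float(-np.dot(detector_normal, d_hat)))
    if cos_s == 0.0 or cos_d == 0.0:
        return 0.0
    xi = visibility(r, r_d, scene) if scene is not None else 1
    return flux_density * cos_s * cos_d * xi * area_mm2 / (np.pi * dist * dist)


def render_detector(
    flux: SurfaceFluxMap, camera: CameraModel, scene=None
) -> DetectorImage:
    """Render the surface flux map into a detector image.

    Each element is imaged through the lens center to its nearest pixel;
    the flux density assigned there is the Lambert-cosine contribution at
    the element's conjugate point on the virtual detector plane (distance
    v in front of the lens), with 0/1 mesh visibility when a scene is
    given.  Pixels are never negative; out-of-frame elements are dropped.
    """
    img = np.zeros((camera.rows, camera.cols))
    n_el = len(flux.flux)
    if n_el == 0:
        return DetectorImage(img, camera.pitch_mm, camera)
    compiled = None
    tri = None
    if scene is not None:
        compiled = scene.compile() if isinstance(scene, Scene) else scene
        tri = np.stack([compiled.v0, compiled.v1, compiled.v2], axis=1)

    L = camera.lens_center
    rel = flux.centers - L
    depth = rel @ camera.axis
    ok = depth > 1e-9
    # detector-plane projection (behind the lens, inverted)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale_det = -camera.v / depth
        x = scale_det * (rel @ camera.e1)
        y = scale_det * (rel @ camera.e2)
        rows_f = y / camera.pitch_mm + (camera.rows - 1) / 2.0
        cols_f = x / camera.pitch_mm + (camera.cols - 1) / 2.0
        rows_i = np.round(rows_f).astype(np.int64)
        cols_i = np.round(cols_f).astype(np.int64)
    ok &= (rows_i >= 0) & (rows_i < camera.rows) & (cols_i >= 0) & (cols_i < camera.cols)

    # conjugate receiving points on the virtual (mirrored) detector plane
    with np.errstate(divide="ignore", invalid="ignore"):
        scale_virt = (camera.v / depth)[:, None]
    p_virt = L + scale_virt * rel
    seg = p_virt - flux.centers
    dist = np.linalg.norm(seg, axis=1)
    ok &= dist > MIN_DISTANCE_MM
    with np.errstate(divide="ignore", invalid="ignore"):
        d_hat = seg / dist[:, None]
    cos_s = np.einsum("ij,ij->i", flux.normals, d_hat)
    # receiver normal faces the scene (n_d = optical axis, lens -> scene)
    cos_d = -(d_hat @ camera.axis)
    ok &= (cos_s > 0.0) & (cos_d > 0.0)

    idx = np.nonzero(ok)[0]
    for i in idx:
        if tri is not None:
            t, hit = _moller_trumbore(flux.centers[i], d_hat[i], tri)
            if (hit & (t < dist[i] - EPS_NUDGE)).any():
                continue
        de = (
            flux.flux[i]
            * cos_s[i]
            * cos_d[i]
            * flux.areas[i]
            / (np.pi * dist[i] * dist[i])
        )
        img[rows_i[i], cols_i[i]] += de
    return DetectorImage(img, camera.pitch_mm, camera)


def place_cameras(
    n_views: int,
    radius: float,
    axis=(0.0, 0.0, 1.0),
    f: float = 50.0,
    rows: int = 120,
    cols: int = 120,
    pitch_mm: float = 0.1,
    scene=None,
    target=(0.0, 0.0, 0.0),
) -> list:
    """Cameras equally spaced in angle about ``axis``, aimed at ``target``.

    View k sits at angle 360 k / n_views degrees in the plane perpendicular
    to ``axis`` at distance ``radius`` from the target.  When a scene is
    given, ``radius`` must exceed its bounding-sphere radius.
    """
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if scene is not None:
        compiled = scene.compile() if isinstance(scene, Scene) else scene
        allv = np.vstack([compiled.v0, compiled.v1, compiled.v2])
        bound = float(np.linalg.norm(allv - np.asarray(target, float), axis=1).max())
        if radius <= bound:
            raise ValueError(
                f"camera radius {radius} lies inside the scene bounding sphere ({bound:.3f})"
            )
    a, e1, e2 = _orthonormal_basis(np.asarray(axis, float))
    cams = []
    target = np.asarray(target, float)
    for k in range(n_views):
        ang = 2.0 * np.pi * k / n_views
        pos = target + radius * (np.cos(ang) * e1 + np.sin(ang) * e2)
        cams.append(
            CameraModel.looking_at(
                pos, target, f=f, rows=rows, cols=cols, pitch_mm=pitch_mm,
                view_angle_deg=np.degrees(ang),
            )
        )
    return cams
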