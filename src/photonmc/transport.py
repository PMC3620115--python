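"""Monte Carlo photon-packet transport: sources, recorders and the run loop.

The engine follows the classic weighted-packet scheme: packets are launched
with weight ``total_power / n_photons``, hop exponentially-distributed free
paths, deposit the fraction mu_a / (mu_a + mu_s) of their weight at every
interaction site, scatter by the Henyey-Greenstein phase function, undergo
all-or-nothing Fresnel reflection/refraction at mesh boundaries, and die by
Russian roulette or by crossing the outermost boundary, where the residual
weight lands on the exit recorders.  Time-domain runs tag every event with
the optical-path elapsed time and bin it into uniform gates.

A run is fully deterministic given its seed: every packet owns a splitmix64
stream keyed by (seed, packet index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernel
from .geometry import CompiledScene, EPS_NUDGE, Scene, locate_region
from .optics import OpticalProperties, fresnel_reflectance

STATUS_NAMES = {
    _kernel.STATUS_EXIT: "exited",
    _kernel.STATUS_ROULETTE: "roulette_killed",
    _kernel.STATUS_ABSORBED: "absorbed",
    _kernel.STATUS_CAP: "step_cap",
    _kernel.STATUS_LOST: "lost",
}


@dataclass
class PhotonPacket:
    """State of one photon packet between events."""

    position: np.ndarray
    direction: np.ndarray
    weight: float
    time: float = 0.0
    region: Optional[str] = None
    band: str = "single"

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(self.direction)
        if nrm == 0:
            raise ValueError("direction must be non-zero")
        self.direction = self.direction / nrm


@dataclass
class SourceSpec:
    """Light source description.

    ``kind`` is ``"internal"`` (packets start uniformly inside ``volume``
    with isotropic directions — a bioluminescent inclusion) or ``"beam"``
    (packets enter at ``entry`` travelling along ``direction``; the
    normal-incidence specular fraction is removed at entry).  ``volume`` is
    ``("sphere", center, radius)`` or ``("box", lo, hi)``.
    """

    kind: str = "internal"
    volume: Optional[tuple] = None
    entry: Optional[Sequence[float]] = None
    direction: Optional[Sequence[float]] = None
    total_power: float = 1.0
    band: str = "single"

    def __post_init__(self) -> None:
        if self.kind not in ("internal", "beam"):
            raise ValueError("source kind must be 'internal' or 'beam'")
        if self.kind == "internal":
            if self.volume is None:
                raise ValueError("internal source requires a volume")
            shape = self.volume[0]
            if shape not in ("sphere", "box"):
                raise ValueError("source volume shape must be 'sphere' or 'box'")
            if shape == "sphere" and self.volume[2] <= 0:
                raise ValueError("source sphere radius must be positive")
        else:
            if self.entry is None or self.direction is None:
                raise ValueError("beam source requires entry point and direction")
            d = np.asarray(self.direction, dtype=float)
            if np.linalg.norm(d) == 0:
                raise ValueError("beam direction must be non-zero")


@dataclass
class FluorophoreSpec:
    """Fluorophore: emission packets are spawned inside ``region`` with
    probability ``quantum_efficiency`` per excitation interaction."""

    region: str
    quantum_efficiency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.quantum_efficiency <= 1.0:
            raise ValueError("quantum efficiency must lie in [0, 1]")


@dataclass
class TimeGates:
    """Uniform time gates [start, stop) with width dt (all picoseconds)."""

    start: float = 0.0
    stop: float = 100.0
    dt: float = 10.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.stop <= self.start:
            raise ValueError("gates require stop > start and dt > 0")
        n = (self.stop - self.start) / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("gate width must divide the gate span evenly")

    @property
    def n_gates(self) -> int:
        return int(round((self.stop - self.start) / self.dt))

    @property
    def edges(self) -> np.ndarray:
        return self.start + self.dt * np.arange(self.n_gates + 1)

    @property
    def centers(self) -> np.ndarray:
        return self.start + self.dt * (np.arange(self.n_gates) + 0.5)


@dataclass
class RunControls:
    """Run controls: photon budget, seed, roulette and recording mode.

    ``roulette_threshold`` is a fraction of the initial packet weight
    (0 disables roulette); ``roulette_m`` is the survival multiplier.
    """

    n_photons: int = 100_000
    seed: int = 1
    roulette_threshold: float = 1e-4
    roulette_m: float = 10.0
    mode: str = "CW"
    gates: Optional[TimeGates] = None
    max_steps: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_photons < 0:
            raise ValueError("n_photons must be non-negative")
        if self.roulette_threshold < 0:
            raise ValueError("roulette threshold must be >= 0")
        if self.roulette_m <= 1.0:
            raise ValueError("roulette constant m must exceed 1")
        if self.mode not in ("CW", "TD"):
            raise ValueError("mode must be 'CW' or 'TD'")
        if self.mode == "TD" and self.gates is None:
            self.gates = TimeGates()


@dataclass
class RecorderSpec:
    """Which recorders to allocate for a run."""

    face_grid: Optional[tuple] = None        # (rows, cols); outer box only
    absorption_voxel_mm: Optional[float] = None
    absorption_bounds: Optional[tuple] = None  # ((lo), (hi)); default scene AABB
    triangle: bool = True


class TriangleRecord:
    """Per-triangle exited weight, with band and time axes."""

    def __init__(self, n_triangles: int, n_bands: int, n_time: int):
        self.data = np.zeros((n_bands, n_triangles, n_time))

    def total(self, band: Optional[int] = None) -> float:
        return float(self.data.sum() if band is None else self.data[band].sum())


class FaceGridRecord:
    """Per-face (rows x cols) exited-weight grids on an axis-aligned box.

    Faces are ordered ``(-x, +x, -y, +y, -z, +z)``; each face chart spans
    the two in-plane axes ordered by axis index (lower axis -> rows).
    """

    def __init__(self, rows, cols, box_min, box_max, n_bands, n_time):
        self.data = np.zeros((n_bands, 6, rows, cols, n_time))
        self.box_min = np.asarray(box_min, dtype=float)
        self.box_max = np.asarray(box_max, dtype=float)

    def face_map(self, face: int, band: int = 0) -> np.ndarray:
        """Time-integrated transmittance map of one face."""
        return self.data[band, face].sum(axis=-1)

    def face_totals(self, band: int = 0) -> np.ndarray:
        return self.data[band].sum(axis=(1, 2, 3))

    def total(self, band: Optional[int] = None) -> float:
        return float(self.data.sum() if band is None else self.data[band].sum())


class AbsorptionGrid:
    """Axis-aligned voxel grid of deposited weight (+ overflow bucket)."""

    def __init__(self, origin, voxel_mm, shape, n_bands=1, n_time=1):
        self.origin = np.asarray(origin, dtype=float)
        self.voxel_mm = float(voxel_mm)
        self.data = np.zeros((n_bands, *shape, n_time))
        self.overflow = np.zeros((n_bands, n_time))

    @classmethod
    def covering(cls, lo, hi, voxel_mm, n_bands=1, n_time=1) -> "AbsorptionGrid":
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        shape = tuple(int(np.ceil((hi[a] - lo[a]) / voxel_mm)) for a in range(3))
        return cls(lo, voxel_mm, shape, n_bands, n_time)

    def add(self, position, dw: float, band: int = 0, gate: int = 0) -> None:
        idx = np.floor((np.asarray(position, float) - self.origin) / self.voxel_mm).astype(int)
        if np.all(idx >= 0) and np.all(idx < self.data.shape[1:4]):
            self.data[(band, *idx, gate)] += dw
        else:
            self.overflow[band, gate] += dw

    def total(self, band: Optional[int] = None) -> float:
        if band is None:
            return float(self.data.sum() + self.overflow.sum())
        return float(self.data[band].sum() + self.overflow[band].sum())


@dataclass
class SimulationResult:
    """All recorders plus the run log of one simulation."""

    totals: dict
    status_counts: dict
    triangle_record: Optional[TriangleRecord]
    face_record: Optional[FaceGridRecord]
    absorption: Optional[AbsorptionGrid]
    compiled_scene: CompiledScene
    seed: int
    n_photons: int
    initial_weight: float
    band_names: tuple
    gates: Optional[TimeGates]
    photon_status: np.ndarray = field(repr=False, default=None)
    photon_exit_weight: np.ndarray = field(repr=False, default=None)
    photon_exit_time: np.ndarray = field(repr=False, default=None)
    photon_exit_triangle: np.ndarray = field(repr=False, default=None)
    photon_band: np.ndarray = field(repr=False, default=None)

    @property
    def conservation_residual(self) -> float:
        """(in - out) / in for the weight ledger; ~0 when roulette is off."""
        t = self.totals
        inflow = t["launched"] + t["roulette_injected"]
        outflow = (
            t["specular"]
            + t["deposited"]
            + t["exited"]
            + t["roulette_killed"]
            + t["step_cap"]
            + t["lost"]
        )
        return (inflow - outflow) / inflow if inflow else 0.0


def launch_photon(source: SourceSpec, rng: np.random.Generator, *, n_photons: int,
                  scene: Optional[Scene] = None) -> PhotonPacket:
    """Sample one initial packet from a source specification.

    Initial weight is total_power / n_photons.  Internal sources place the
    packet uniformly in the source volume (rejection sampling) with an
    isotropic direction (cos(theta) uniform on [-1, 1]); beams start at the
    entry point along the beam direction.
    """
    if n_photons <= 0:
        raise ValueError("n_photons must be positive to launch a packet")
    w0 = source.total_power / n_photons
    if source.kind == "internal":
        shape = source.volume[0]
        if shape == "sphere":
            center = np.asarray(source.volume[1], float)
            radius = float(source.volume[2])
            while True:
                p = center + radius * (2.0 * rng.random(3) - 1.0)
                if np.sum((p - center) ** 2) <= radius * radius:
                    break
        else:
            lo = np.asarray(source.volume[1], float)
            hi = np.asarray(source.volume[2], float)
            if np.any(hi <= lo):
                raise ValueError("empty source box")
            p = lo + (hi - lo) * rng.random(3)
        ct = 2.0 * rng.random() - 1.0
        phi = 2.0 * np.pi * rng.random()
        st = np.sqrt(1.0 - ct * ct)
        d = np.array([st * np.cos(phi), st * np.sin(phi), ct])
    else:
        p = np.asarray(source.entry, float)
        d = np.asarray(source.direction, float)
        d = d / np.linalg.norm(d)
    region = locate_region(p, scene) if scene is not None else None
    return PhotonPacket(position=p, direction=d, weight=w0, time=0.0,
                        region=region, band=source.band)


def boundary_event(photon: PhotonPacket, hit, scene, xi: float) -> PhotonPacket:
    """Resolve one boundary interaction: all-or-nothing reflect/transmit.

    With probability R(theta_i) the packet reflects specularly and stays in
    its region; otherwise it refracts by Snell's law and takes the far-side
    region.  Transmission through the outermost boundary terminates the
    packet (weight left intact for the caller's exit recorder).
    """
    compiled = scene.compile() if isinstance(scene, Scene) else scene
    nrm = np.asarray(hit.surface_normal, float)
    u = photon.direction
    dot = float(np.dot(u, nrm))
    band = photon.band if photon.band in compiled.band_names else compiled.band_names[0]
    bi = compiled.band_names.index(band)

    def _n(region_id):
        if region_id is None:
            return compiled.ambient_n
        return compiled.n[compiled.region_index(region_id), bi]

    n_i = _n(hit.region_from)
    n_t = _n(hit.region_to)
    theta_i = float(np.arccos(np.clip(abs(dot), -1.0, 1.0)))
    refl = fresnel_reflectance(n_i, n_t, theta_i)
    pos = np.asarray(hit.hit_point, float)
    if xi <= refl:
        new_dir = u - 2.0 * dot * nrm
        new_dir /= np.linalg.norm(new_dir)
        return PhotonPacket(pos + EPS_NUDGE * new_dir, new_dir, photon.weight,
                            photon.time, photon.region, photon.band)
    if n_i != n_t:
        g = -nrm if dot > 0 else nrm
        eta = n_i / n_t
        ci = abs(dot)
        cost = np.sqrt(max(0.0, 1.0 - eta * eta * (1.0 - ci * ci)))
        new_dir = eta * u + (eta * ci - cost) * g
        new_dir /= np.linalg.norm(new_dir)
    else:
        new_dir = u.copy()
    return PhotonPacket(pos + EPS_NUDGE * new_dir, new_dir, photon.weight,
                        photon.time, hit.region_to, photon.band)


def deposit(photon: PhotonPacket, props: OpticalProperties,
            grid: Optional[AbsorptionGrid] = None, gate: int = 0, band: int = 0) -> float:
    """Deposit dw = w * mu_a / (mu_a + mu_s) at the packet position.

    Mutates the packet weight and (optionally) the absorption grid;
    returns the deposited weight.
    """
    if props.mu_t <= 0:
        return 0.0
    dw = photon.weight * props.mu_a / props.mu_t
    photon.weight -= dw
    if grid is not None and dw > 0.0:
        grid.add(photon.position, dw, band=band, gate=gate)
    return dw


def td_to_fd(td_histogram, gate_centers_ps, f_mhz: float):
    """Frequency-domain datum from a time-gated record by discrete Fourier sum.

    Returns (amplitude, phase) of sum_k h_k exp(-i 2 pi f t_k) over gate
    centers; f = 0 reproduces the CW total with zero phase.  Phase is in
    radians; the empty-histogram phase is NaN (flagged undefined).
    """
    h = np.asarray(td_histogram, dtype=float)
    t = np.asarray(gate_centers_ps, dtype=float)
    if h.shape != t.shape:
        raise ValueError("histogram and gate centers must have matching shapes")
    if h.size == 0 or not np.any(h):
        return 0.0, float("nan")
    omega_t = 2.0 * np.pi * f_mhz * 1e6 * t * 1e-12
    z = np.sum(h * np.exp(-1j * omega_t))
    return float(np.abs(z)), float(np.angle(z))


def _band_names(source: SourceSpec, fluorophore: Optional[FluorophoreSpec]) -> tuple:
    if fluorophore is not None:
        return ("excitation", "emission")
    return (source.band,)


def run_simulation(
    scene: Scene,
    source: SourceSpec,
    controls: RunControls,
    fluorophore: Optional[FluorophoreSpec] = None,
    recorders: Optional[RecorderSpec] = None,
) -> SimulationResult:
    """Seeded, reproducible transport run over ``controls.n_photons`` packets."""
    recorders = recorders or RecorderSpec()
    bands = _band_names(source, fluorophore)
    compiled = scene.compile(bands)
    if fluorophore is not None and source.band != "excitation":
        raise ValueError("fluorescence runs require an excitation-band source")
    n = int(controls.n_photons)
    w0 = source.total_power / n if n > 0 else 0.0

    td = controls.mode == "TD"
    gates = controls.gates if td else None
    n_gates = gates.n_gates if td else 1
    n_time = n_gates + 1 if td else 1  # trailing overflow gate in TD

    n_bands = len(bands)
    tri_rec = TriangleRecord(compiled.n_triangles, n_bands, n_time) if recorders.triangle else None
    tri_data = (
        tri_rec.data
        if tri_rec is not None
        else np.zeros((n_bands, compiled.n_triangles, n_time))
    )

    face_rec = None
    if recorders.face_grid is not None:
        if not compiled.outer_is_box:
            raise ValueError("face-grid recording requires an axis-aligned box outer mesh")
        rows, cols = recorders.face_grid
        face_rec = FaceGridRecord(rows, cols, compiled.box_min, compiled.box_max,
                                  n_bands, n_time)
    face_data = face_rec.data if face_rec is not None else np.zeros((n_bands, 6, 1, 1, 1))
    face_rows = face_rec.data.shape[2] if face_rec is not None else 1
    face_cols = face_rec.data.shape[3] if face_rec is not None else 1

    vox = None
    if recorders.absorption_voxel_mm is not None:
        if recorders.absorption_bounds is not None:
            lo, hi = (np.asarray(b, float) for b in recorders.absorption_bounds)
        else:
            lo, hi = compiled.box_min, compiled.box_max
        vox = AbsorptionGrid.covering(lo, hi, recorders.absorption_voxel_mm, n_bands, n_time)
    vox_data = vox.data if vox is not None else np.zeros((n_bands, 1, 1, 1, 1))
    vox_overflow = vox.overflow if vox is not None else np.zeros((n_bands, 1))
    vox_origin = vox.origin if vox is not None else np.zeros(3)
    vox_size = vox.voxel_mm if vox is not None else 1.0

    # source arrays for the kernel
    if source.kind == "internal":
        src_kind = 0
        shape = source.volume[0]
        if shape == "sphere":
            src_shape = 0
            src_center = np.asarray(source.volume[1], float)
            src_radius = float(source.volume[2])
            src_bmin = np.zeros(3)
            src_bmax = np.zeros(3)
        else:
            src_shape = 1
            src_center = np.zeros(3)
            src_radius = 0.0
            src_bmin = np.asarray(source.volume[1], float)
            src_bmax = np.asarray(source.volume[2], float)
        src_entry = np.zeros(3)
        src_dir = np.array([0.0, 0.0, 1.0])
    else:
        src_kind = 1
        src_shape = 0
        src_center = np.zeros(3)
        src_radius = 0.0
        src_bmin = np.zeros(3)
        src_bmax = np.zeros(3)
        src_entry = np.asarray(source.entry, float)
        src_dir = np.asarray(source.direction, float)
        src_dir = src_dir / np.linalg.norm(src_dir)

    fluo_region = -1
    fluo_eta = 0.0
    if fluorophore is not None:
        fluo_region = compiled.region_index(fluorophore.region)
        fluo_eta = fluorophore.quantum_efficiency

    totals = np.zeros(_kernel.N_TOTALS)
    status_out = np.zeros(n, dtype=np.int8)
    exit_w = np.zeros(n)
    exit_t = np.zeros(n)
    exit_tri = np.zeros(n, dtype=np.int64)
    band_out = np.zeros(n, dtype=np.int8)
    seeds = _kernel.derive_photon_seeds(controls.seed, n)

    if n > 0:
        _kernel.run_photons(
            seeds, w0, 0,
            src_kind, src_shape, src_center, src_radius, src_bmin, src_bmax,
            src_entry, src_dir,
            compiled.v0, compiled.v1, compiled.v2, compiled.normals,
            compiled.inside, compiled.outside,
            compiled.reg_bb_min, compiled.reg_bb_max,
            compiled.reg_tri_start, compiled.reg_tri_end, compiled.depth,
            compiled.mu_a, compiled.mu_s, compiled.g, compiled.n, compiled.ambient_n,
            fluo_region, fluo_eta,
            controls.roulette_threshold * w0, controls.roulette_m, controls.max_steps,
            gates.start if td else 0.0, gates.dt if td else 1.0, n_gates, td,
            tri_data, face_data, face_rec is not None,
            compiled.box_min, compiled.box_max, face_rows, face_cols,
            vox_data, vox is not None, vox_origin, vox_size, vox_overflow,
            totals,
            status_out, exit_w, exit_t, exit_tri, band_out,
        )

    if totals[_kernel.T_CAP] > 0:
        warnings.warn(
            f"{int((status_out == _kernel.STATUS_CAP).sum())} photon(s) hit the "
            f"step-count cap; their weight is in totals['step_cap']",
            RuntimeWarning,
            stacklevel=2,
        )

    totals_dict = {
        "launched": totals[_kernel.T_LAUNCHED],
        "specular": totals[_kernel.T_SPECULAR],
        "deposited": totals[_kernel.T_DEPOSITED],
        "exited": totals[_kernel.T_EXITED],
        "roulette_killed": totals[_kernel.T_ROULETTE_KILLED],
        "roulette_injected": totals[_kernel.T_ROULETTE_INJECTED],
        "step_cap": totals[_kernel.T_CAP],
        "converted": totals[_kernel.T_CONVERTED],
        "lost": totals[_kernel.T_LOST],
    }
    status_counts = {
        name: int((status_out == code).sum()) for code, name in STATUS_NAMES.items()
    }
    return SimulationResult(
        totals=totals_dict,
        status_counts=status_counts,
        triangle_record=tri_rec,
        face_record=face_rec,
        absorption=vox,
        compiled_scene=compiled,
        seed=controls.seed,
        n_photons=n,
        initial_weight=w0,
        band_names=bands,
        gates=gates,
        photon_status=status_out,
        photon_exit_weight=exit_w,
        photon_exit_time=exit_t,
        photon_exit_triangle=exit_tri,
        photon_band=band_out,
    )


def propagate(
    photon: PhotonPacket,
    scene: Scene,
    fluorophore: Optional[FluorophoreSpec] = None,
    controls: Optional[RunControls] = None,
    seed: int = 0,
) -> dict:
    """Trace one already-launched packet through the compiled kernel.

    Returns a dict with the terminal ``status`` name, the weight ledger
    ``totals`` and, for exits, the exit weight/time/triangle.
    """
    controls = controls or RunControls(n_photons=1)
    bands = ("excitation", "emission") if fluorophore is not None else (photon.band,)
    compiled = scene.compile(bands)
    td = controls.mode == "TD"
    gates = controls.gates if td else None
    n_gates = gates.n_gates if td else 1
    n_time = n_gates + 1 if td else 1
    n_bands = len(bands)
    tri_data = np.zeros((n_bands, compiled.n_triangles, n_time))
    face_data = np.zeros((n_bands, 6, 1, 1, 1))
    vox_data = np.zeros((n_bands, 1, 1, 1, 1))
    vox_overflow = np.zeros((n_bands, 1))
    totals = np.zeros(_kernel.N_TOTALS)
    region = photon.region
    if region is None:
        region = locate_region(photon.position, scene)
    reg_idx = compiled.region_index(region) if region is not None else -1
    band_idx = bands.index(photon.band) if photon.band in bands else 0
    fluo_region = compiled.region_index(fluorophore.region) if fluorophore else -1
    fluo_eta = fluorophore.quantum_efficiency if fluorophore else 0.0
    totals[_kernel.T_LAUNCHED] = photon.weight
    state = _kernel.derive_photon_seeds(seed, 1)[0]
    state, status, wex, tex, triex, band_f = _kernel._trace_one(
        state,
        photon.position[0], photon.position[1], photon.position[2],
        photon.direction[0], photon.direction[1], photon.direction[2],
        photon.weight, photon.time, reg_idx, band_idx,
        compiled.v0, compiled.v1, compiled.v2, compiled.normals,
        compiled.inside, compiled.outside,
        compiled.reg_bb_min, compiled.reg_bb_max,
        compiled.reg_tri_start, compiled.reg_tri_end, compiled.depth,
        compiled.mu_a, compiled.mu_s, compiled.g, compiled.n, compiled.ambient_n,
        fluo_region, fluo_eta,
        controls.roulette_threshold * photon.weight, controls.roulette_m,
        controls.max_steps,
        gates.start if td else 0.0, gates.dt if td else 1.0, n_gates, td,
        tri_data, face_data, False,
        compiled.box_min, compiled.box_max, 1, 1,
        vox_data, False, np.zeros(3), 1.0, vox_overflow,
        totals,
    )
    return {
        "status": STATUS_NAMES[int(status)],
        "exit_weight": float(wex),
        "exit_time": float(tex),
        "exit_triangle": int(triex),
        "band": bands[int(band_f)],
        "totals": {
            "launched": totals[_kernel.T_LAUNCHED],
            "deposited": totals[_kernel.T_DEPOSITED],
            "exited": totals[_kernel.T_EXITED],
            "roulette_killed": totals[_kernel.T_ROULETTE_KILLED],
            "roulette_injected": totals[_kernel.T_ROULETTE_INJECTED],
        },
        "triangle_record": tri_data,
    }
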