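"""Simulation configuration: JSON schema, validation, legacy parameter files.

A run is described by one JSON document (scene + source + optional
fluorophore + controls + recorders + cameras).  Validation is strict —
unknown keys are rejected and *all* problems are reported at once — and
round-trips are lossless: ``parse_config(write_config(c)) == c``.

A legacy-style flat key/value parameter file is also accepted (see
:func:`parse_legacy_params` for the grammar).
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Dict, List, Literal, Optional, Tuple, Union

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    model_validator,
)

from .geometry import (
    Region,
    Scene,
    SurfaceMesh,
    make_cube_phantom,
    make_ellipsoid_mesh,
    make_sphere_mesh,
)
from .optics import OpticalProperties
from .transport import (
    FluorophoreSpec,
    RecorderSpec,
    RunControls,
    SourceSpec,
    TimeGates,
)


class ConfigError(ValueError):
    """Raised with the full list of validation problems."""

    def __init__(self, problems: List[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


Vec3 = Tuple[float, float, float]


class OpticalBlock(_Model):
    """Per-region optical properties (mm^-1 coefficients)."""

    mu_a: float = Field(ge=0)
    mu_s: float = Field(ge=0)
    g: float = Field(gt=-1, lt=1)
    n: float = Field(ge=1)

    def to_props(self) -> OpticalProperties:
        return OpticalProperties(self.mu_a, self.mu_s, self.g, self.n)


class CubeMesh(_Model):
    kind: Literal["cube"] = "cube"
    side: float = Field(gt=0)
    subdivisions: int = Field(default=1, ge=1)


class EllipsoidMesh(_Model):
    kind: Literal["ellipsoid"] = "ellipsoid"
    semi_axes: Vec3
    center: Vec3 = (0.0, 0.0, 0.0)
    refinement: int = Field(default=2, ge=0)


class SphereMesh(_Model):
    kind: Literal["sphere"] = "sphere"
    radius: float = Field(gt=0)
    center: Vec3 = (0.0, 0.0, 0.0)
    refinement: int = Field(default=2, ge=0)


class FileMesh(_Model):
    kind: Literal["file"] = "file"
    path: str


MeshSpec = Union[CubeMesh, EllipsoidMesh, SphereMesh, FileMesh]


class RegionConfig(_Model):
    id: str
    mesh: MeshSpec = Field(discriminator="kind")
    parent: Optional[str] = None
    optical: Union[OpticalBlock, Dict[str, OpticalBlock]]


class SceneConfig(_Model):
    ambient_n: float = Field(default=1.0, ge=1)
    regions: List[RegionConfig] = Field(min_length=1)


class SphereVolume(_Model):
    shape: Literal["sphere"] = "sphere"
    center: Vec3
    radius: float = Field(gt=0)


class BoxVolume(_Model):
    shape: Literal["box"] = "box"
    lo: Vec3
    hi: Vec3


class SourceConfig(_Model):
    kind: Literal["internal", "beam"]
    volume: Optional[Union[SphereVolume, BoxVolume]] = None
    entry: Optional[Vec3] = None
    direction: Optional[Vec3] = None
    total_power: float = Field(default=1.0, gt=0)
    band: Literal["single", "excitation"] = "single"

    @model_validator(mode="after")
    def _check_kind(self) -> "SourceConfig":
        if self.kind == "internal" and self.volume is None:
            raise ValueError("internal source requires a volume")
        if self.kind == "beam" and (self.entry is None or self.direction is None):
            raise ValueError("beam source requires entry and direction")
        return self


class FluorophoreConfig(_Model):
    region: str
    quantum_efficiency: float = Field(ge=0, le=1)


class GatesConfig(_Model):
    start_ps: float = 0.0
    stop_ps: float = Field(gt=0)
    dt_ps: float = Field(gt=0)


class ControlsConfig(_Model):
    n_photons: int = Field(ge=0)
    seed: int = 1
    roulette_threshold: float = Field(default=1e-4, ge=0)
    roulette_m: float = Field(default=10.0, gt=1)
    mode: Literal["CW", "TD"] = "CW"
    gates: Optional[GatesConfig] = None
    max_steps: int = Field(default=1_000_000, ge=1)

    @model_validator(mode="after")
    def _check_gates(self) -> "ControlsConfig":
        if self.mode == "TD" and self.gates is None:
            raise ValueError("TD mode requires time gates")
        return self


class FaceGridConfig(_Model):
    rows: int = Field(default=300, ge=1)
    cols: int = Field(default=300, ge=1)


class AbsorptionConfig(_Model):
    voxel_mm: float = Field(gt=0)
    bounds_lo: Optional[Vec3] = None
    bounds_hi: Optional[Vec3] = None


class RecordersConfig(_Model):
    face_grid: Optional[FaceGridConfig] = None
    absorption: Optional[AbsorptionConfig] = None
    triangle: bool = True


class CameraConfig(_Model):
    n_views: int = Field(default=4, ge=1)
    radius: float = Field(gt=0)
    axis: Vec3 = (0.0, 0.0, 1.0)
    f: float = Field(default=50.0, gt=0)
    rows: int = Field(default=120, ge=1)
    cols: int = Field(default=120, ge=1)
    pitch_mm: float = Field(default=0.1, gt=0)


class SimulationConfig(_Model):
    """Complete description of one simulation run."""

    scene: SceneConfig
    source: SourceConfig
    fluorophore: Optional[FluorophoreConfig] = None
    controls: ControlsConfig
    recorders: RecordersConfig = RecordersConfig()
    cameras: Optional[CameraConfig] = None
    output_dir: Optional[str] = None

    @model_validator(mode="after")
    def _cross_checks(self) -> "SimulationConfig":
        ids = [r.id for r in self.scene.regions]
        problems = []
        if len(set(ids)) != len(ids):
            problems.append("duplicate region ids")
        for r in self.scene.regions:
            if r.parent is not None and r.parent not in ids:
                problems.append(f"region {r.id!r} has unknown parent {r.parent!r}")
        if self.fluorophore is not None:
            if self.fluorophore.region not in ids:
                problems.append(
                    f"fluorophore region {self.fluorophore.region!r} is not a scene region"
                )
            if self.source.band != "excitation":
                problems.append("fluorescence runs require source band 'excitation'")
            for r in self.scene.regions:
                if not isinstance(r.optical, dict) or not {
                    "excitation",
                    "emission",
                } <= set(r.optical):
                    problems.append(
                        f"region {r.id!r} needs 'excitation' and 'emission' optical bands"
                    )
        if problems:
            raise ValueError("; ".join(problems))
        return self


def parse_config(path_or_text: str) -> SimulationConfig:
    """Parse and fully validate a JSON config (file path or JSON text).

    All validation problems are collected into one :class:`ConfigError`
    rather than stopping at the first.
    """
    text = path_or_text
    if os.path.exists(path_or_text):
        with open(path_or_text) as fh:
            text = fh.read()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError([f"not valid JSON: {exc}"]) from exc
    return validate_config(data)


def validate_config(data: dict) -> SimulationConfig:
    try:
        return SimulationConfig.model_validate(data)
    except ValidationError as exc:
        problems = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigError(problems) from exc


def write_config(config: SimulationConfig, path: Optional[str] = None) -> str:
    """Serialize to canonical JSON; returns the text (and writes if path given)."""
    text = json.dumps(config.model_dump(mode="json"), indent=2, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def config_hash(config: SimulationConfig) -> str:
    """sha256 of the canonical JSON serialization (stamped on outputs)."""
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Config -> runtime objects
# ---------------------------------------------------------------------------

def _build_mesh(spec: MeshSpec) -> SurfaceMesh:
    if isinstance(spec, CubeMesh):
        return make_cube_phantom(spec.side, spec.subdivisions)
    if isinstance(spec, EllipsoidMesh):
        return make_ellipsoid_mesh(spec.semi_axes, spec.center, spec.refinement)
    if isinstance(spec, SphereMesh):
        return make_sphere_mesh(spec.radius, spec.center, spec.refinement)
    return SurfaceMesh.load(spec.path)


def build_scene(config: SimulationConfig) -> Scene:
    regions = []
    for rc in config.scene.regions:
        if isinstance(rc.optical, dict):
            props = {band: block.to_props() for band, block in rc.optical.items()}
        else:
            props = rc.optical.to_props()
        regions.append(Region(rc.id, _build_mesh(rc.mesh), props, rc.parent))
    return Scene(regions, ambient_n=config.scene.ambient_n)


def build_source(config: SimulationConfig) -> SourceSpec:
    sc = config.source
    if sc.kind == "internal":
        vol = (
            ("sphere", sc.volume.center, sc.volume.radius)
            if isinstance(sc.volume, SphereVolume)
            else ("box", sc.volume.lo, sc.volume.hi)
        )
        return SourceSpec(kind="internal", volume=vol, total_power=sc.total_power,
                          band=sc.band)
    return SourceSpec(kind="beam", entry=sc.entry, direction=sc.direction,
                      total_power=sc.total_power, band=sc.band)


def build_controls(config: SimulationConfig, seed: Optional[int] = None,
                   n_photons: Optional[int] = None) -> RunControls:
    cc = config.controls
    gates = None
    if cc.gates is not None:
        gates = TimeGates(cc.gates.start_ps, cc.gates.stop_ps, cc.gates.dt_ps)
    return RunControls(
        n_photons=n_photons if n_photons is not None else cc.n_photons,
        seed=seed if seed is not None else cc.seed,
        roulette_threshold=cc.roulette_threshold,
        roulette_m=cc.roulette_m,
        mode=cc.mode,
        gates=gates,
        max_steps=cc.max_steps,
    )


def build_recorders(config: SimulationConfig) -> RecorderSpec:
    rc = config.recorders
    face = (rc.face_grid.rows, rc.face_grid.cols) if rc.face_grid else None
    vox = rc.absorption.voxel_mm if rc.absorption else None
    bounds = None
    if rc.absorption and rc.absorption.bounds_lo is not None:
        bounds = (rc.absorption.bounds_lo, rc.absorption.bounds_hi)
    return RecorderSpec(face_grid=face, absorption_voxel_mm=vox,
                        absorption_bounds=bounds, triangle=rc.triangle)


def build_fluorophore(config: SimulationConfig) -> Optional[FluorophoreSpec]:
    if config.fluorophore is None:
        return None
    return FluorophoreSpec(config.fluorophore.region,
                           config.fluorophore.quantum_efficiency)


def build_cameras(config: SimulationConfig):
    from .imaging import place_cameras

    cc = config.cameras
    if cc is None:
        return []
    return place_cameras(cc.n_views, cc.radius, cc.axis, f=cc.f, rows=cc.rows,
                         cols=cc.cols, pitch_mm=cc.pitch_mm)


def run_config(config: SimulationConfig, seed: Optional[int] = None,
               n_photons: Optional[int] = None):
    """Assemble and execute a configured run; returns a SimulationResult."""
    from .transport import run_simulation

    return run_simulation(
        build_scene(config),
        build_source(config),
        build_controls(config, seed=seed, n_photons=n_photons),
        fluorophore=build_fluorophore(config),
        recorders=build_recorders(config),
    )


# ---------------------------------------------------------------------------
# Legacy flat parameter files
# ---------------------------------------------------------------------------

def parse_legacy_params(text: str) -> SimulationConfig:
    """Parse a flat key/value parameter file into a validated config.

    Grammar (one assignment per line)::

        # comment (also ';' comments); blank lines ignored
        dotted.key.path = value

    Values are JSON literals (numbers, strings, ``[..]`` arrays).  Dotted
    paths address the JSON config document; integer components index into
    lists (e.g. ``scene.regions.0.id = "cube"``).  Example::

        scene.ambient_n = 1.0
        scene.regions.0.id = "phantom"
        scene.regions.0.mesh.kind = "cube"
        scene.regions.0.mesh.side = 10
        scene.regions.0.optical.mu_a = 0.0002
        scene.regions.0.optical.mu_s = 11.7
        scene.regions.0.optical.g = 0.95
        scene.regions.0.optical.n = 1.37
        source.kind = "internal"
        source.volume.shape = "sphere"
        source.volume.center = [0, 0, 2]
        source.volume.radius = 0.5
        controls.n_photons = 100000
    """
    root: dict = {}
    problems: List[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].split(";", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            problems.append(f"line {lineno}: expected 'key = value'")
            continue
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        try:
            parsed = json.loads(value)
        except json.JSONDecodeError:
            parsed = value  # bare string
        node = root
        parts = key.split(".")
        try:
            for i, part in enumerate(parts):
                last = i == len(parts) - 1
                nxt = parts[i + 1] if not last else None
                if isinstance(node, list):
                    idx = int(part)
                    while len(node) <= idx:
                        node.append({})
                    if last:
                        node[idx] = parsed
                    else:
                        if not isinstance(node[idx], (dict, list)):
                            node[idx] = [] if nxt.isdigit() else {}
                        node = node[idx]
                else:
                    if last:
                        node[part] = parsed
                    else:
                        if part not in node or not isinstance(node[part], (dict, list)):
                            node[part] = [] if nxt.isdigit() else {}
                        node = node[part]
        except (ValueError, TypeError):
            problems.append(f"line {lineno}: bad key path {key!r}")
    if problems:
        raise ConfigError(problems)
    return validate_config(root)
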