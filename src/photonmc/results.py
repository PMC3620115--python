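"""Result serialization: HDF5 recorders, CSV maps, PNG previews, run logs.

A run directory contains::

    result.h5       all recorders + metadata (seed, config hash, totals)
    config.json     the exact configuration used (when available)
    <map>.csv       2D transmittance / detector maps as plain CSV
    <map>.png       16-bit linear previews with a .json scaling sidecar
    runlog.jsonl    one JSON line per run with seed, hash and totals

HDF5 objects are written with ``track_times=False`` so identical runs
produce byte-identical files.
"""

from __future__ import annotations

import json
import os
import time
from typing import Optional

import h5py
import numpy as np
from PIL import Image

from .transport import SimulationResult


def _create(group, name, data):
    group.create_dataset(name, data=np.asarray(data), track_times=False)


def save_result(result: SimulationResult, outdir: str,
                config_text: Optional[str] = None,
                config_hash: Optional[str] = None,
                write_maps: bool = True) -> str:
    """Write a run directory; returns the path to result.h5."""
    os.makedirs(outdir, exist_ok=True)
    h5path = os.path.join(outdir, "result.h5")
    with h5py.File(h5path, "w", track_order=False) as fh:
        fh.attrs["seed"] = result.seed
        fh.attrs["n_photons"] = result.n_photons
        fh.attrs["initial_weight"] = result.initial_weight
        fh.attrs["bands"] = ",".join(result.band_names)
        if config_hash:
            fh.attrs["config_hash"] = config_hash
        tot = fh.create_group("totals")
        for key, val in result.totals.items():
            tot.attrs[key] = val
        st = fh.create_group("status_counts")
        for key, val in result.status_counts.items():
            st.attrs[key] = val
        if result.gates is not None:
            _create(fh, "gate_edges_ps", result.gates.edges)
        if result.triangle_record is not None:
            _create(fh, "triangle_exit_weight", result.triangle_record.data)
        if result.face_record is not None:
            g = fh.create_group("face_grid")
            _create(g, "exit_weight", result.face_record.data)
            _create(g, "box_min", result.face_record.box_min)
            _create(g, "box_max", result.face_record.box_max)
        if result.absorption is not None:
            g = fh.create_group("absorption")
            _create(g, "deposited_weight", result.absorption.data)
            _create(g, "overflow", result.absorption.overflow)
            _create(g, "origin", result.absorption.origin)
            g.attrs["voxel_mm"] = result.absorption.voxel_mm
        log = fh.create_group("photons")
        _create(log, "status", result.photon_status)
        _create(log, "exit_weight", result.photon_exit_weight)
        _create(log, "exit_time_ps", result.photon_exit_time)
        _create(log, "exit_triangle", result.photon_exit_triangle)
        _create(log, "band", result.photon_band)
    if config_text is not None:
        with open(os.path.join(outdir, "config.json"), "w") as fh:
            fh.write(config_text if config_text.endswith("\n") else config_text + "\n")
    if write_maps and result.face_record is not None:
        from .geometry import FACE_LABELS

        for bi, band in enumerate(result.band_names):
            for face in range(6):
                grid = result.face_record.face_map(face, band=bi)
                if not grid.any():
                    continue
                stem = f"transmittance_{band}_face{FACE_LABELS[face].replace('-', 'm').replace('+', 'p')}"
                save_map_csv(grid, os.path.join(outdir, stem + ".csv"), config_hash)
                save_map_png(grid, os.path.join(outdir, stem + ".png"))
    append_runlog(
        os.path.join(outdir, "runlog.jsonl"),
        {
            "seed": result.seed,
            "n_photons": result.n_photons,
            "config_hash": config_hash,
            "bands": list(result.band_names),
            "totals": {k: float(v) for k, v in result.totals.items()},
            "status_counts": result.status_counts,
        },
    )
    return h5path


def save_map_csv(grid: np.ndarray, path: str, config_hash: Optional[str] = None) -> None:
    header = f"config_hash={config_hash}" if config_hash else ""
    np.savetxt(path, grid, delimiter=",", header=header)


def load_map_csv(path: str) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))


def save_map_png(grid: np.ndarray, path: str) -> None:
    """16-bit linear preview; the scaling lands in a JSON sidecar."""
    peak = float(grid.max())
    scale = 65535.0 / peak if peak > 0 else 0.0
    img = np.clip(grid * scale, 0, 65535).astype(np.uint16)
    Image.fromarray(img).save(path)
    with open(path + ".json", "w") as fh:
        json.dump({"scale": scale, "min": float(grid.min()), "max": peak}, fh)


def append_runlog(path: str, record: dict) -> None:
    record = dict(record)
    record.setdefault("timestamp", time.strftime("%Y-%m-%dT%H:%M:%S"))
    with open(path, "a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")


def load_triangle_record(h5path: str) -> np.ndarray:
    with h5py.File(h5path, "r") as fh:
        return fh["triangle_exit_weight"][...]
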