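"""Packaged example configurations.

Three ready-to-run study setups:

``blt_cube``
    Bioluminescence (CW): a homogeneous 10 mm cube phantom
    (mu_a = 0.0002 mm^-1, mu_s = 11.7 mm^-1, g = 0.95, n = 1.37) with an
    internal isotropic source centred 3 mm below the +z face, 300x300
    per-face transmittance grids, and four CCD cameras at 90 degree
    intervals around the phantom.

``dot_mouse``
    Diffuse optical tomography (CW): a simplified multi-organ phantom —
    nested ellipsoidal "organs" inside an ellipsoidal body carrying the
    heterogeneous tissue properties of a small-animal study at 670 nm,
    with an optional solid-tumor inclusion on the back, an external
    perpendicular beam, and a 0.5 mm absorption voxel grid.  The phantom
    geometry is synthetic: it stands in for a digital-mouse atlas while
    preserving the computational content (nested heterogeneous regions,
    external illumination, with/without-tumor contrast).

``fmt_td``
    Fluorescence molecular tomography (time domain): the same synthetic
    multi-organ phantom with two-wavelength optical properties
    (excitation 620 nm / emission 690 nm), a fluorophore of quantum
    efficiency 0.6 in the kidney, an external excitation beam, and time
    gates from 0 to 100 ps at 10 ps.
"""

from __future__ import annotations

from typing import Dict

from .config import SimulationConfig, validate_config

EXAMPLE_NAMES = ("blt_cube", "dot_mouse", "fmt_td")

# (mu_a mm^-1, mu_s mm^-1, g, n) per tissue at 670 nm, used by dot_mouse.
DOT_TISSUES: Dict[str, tuple] = {
    "surface": (0.004, 20.13, 0.94, 1.37),
    "lung": (0.196, 36.23, 0.94, 1.37),
    "kidney": (0.066, 16.09, 0.86, 1.37),
    "heart": (0.059, 6.42, 0.85, 1.37),
    "stomach": (0.011, 17.96, 0.92, 1.37),
    "liver": (0.035, 6.78, 0.9, 1.37),
    "tumor": (0.55, 29.5, 0.9, 1.37),
}

# Two-band properties (excitation 620 nm, emission 690 nm) for fmt_td.
FMT_TISSUES: Dict[str, tuple] = {
    "surface": ((0.0088, 20.97, 0.94, 1.37), (0.003, 19.82, 0.94, 1.37)),
    "heart": ((0.138, 7.18, 0.85, 1.37), (0.04367, 6.16, 0.85, 1.37)),
    "stomach": ((0.026, 19.36, 0.92, 1.37), (0.0086, 17.46, 0.92, 1.37)),
    "lung": ((0.46, 37.75, 0.94, 1.37), (0.145, 35.67, 0.94, 1.37)),
    "liver": ((0.829, 7.35, 0.9, 1.37), (0.261, 6.57, 0.9, 1.37)),
    "kidney": ((0.155, 18.09, 0.86, 1.37), (0.05, 15.39, 0.86, 1.37)),
}

# Synthetic organ layout: ellipsoid (semi_axes, center) inside the body.
_ORGAN_SHAPES = {
    "heart": ((2.5, 2.0, 2.0), (9.0, 0.0, 1.0)),
    "lung": ((3.0, 2.5, 2.0), (3.0, 0.0, 2.0)),
    "stomach": ((3.0, 2.5, 2.0), (-3.0, 0.0, -1.0)),
    "liver": ((3.5, 3.0, 2.0), (-10.0, 0.0, 0.0)),
    "kidney": ((2.0, 1.5, 1.5), (3.0, -1.0, -3.0)),
}
_BODY_SEMI_AXES = (20.0, 10.0, 8.0)
_TUMOR_SHAPE = ((2.0, 1.5, 1.5), (0.0, 3.0, 5.0))


def _optical(entry: tuple) -> dict:
    mu_a, mu_s, g, n = entry
    return {"mu_a": mu_a, "mu_s": mu_s, "g": g, "n": n}


def _blt_cube() -> dict:
    return {
        "scene": {
            "ambient_n": 1.0,
            "regions": [
                {
                    "id": "phantom",
                    "mesh": {"kind": "cube", "side": 10.0, "subdivisions": 1},
                    "optical": {"mu_a": 0.0002, "mu_s": 11.7, "g": 0.95, "n": 1.37},
                }
            ],
        },
        # isotropic source centred at (0, 0, 2): 3 mm below the +z face
        "source": {
            "kind": "internal",
            "volume": {"shape": "sphere", "center": (0.0, 0.0, 2.0), "radius": 0.5},
            "total_power": 1.0,
        },
        "controls": {"n_photons": 10_000_000, "seed": 1},
        "recorders": {"face_grid": {"rows": 300, "cols": 300}},
        "cameras": {
            "n_views": 4,
            "radius": 150.0,
            "axis": (0.0, 0.0, 1.0),
            "f": 50.0,
            "rows": 120,
            "cols": 120,
            "pitch_mm": 0.1,
        },
    }


def _mouse_regions(band_tables, tumor: bool) -> list:
    regions = [
        {
            "id": "body",
            "mesh": {
                "kind": "ellipsoid",
                "semi_axes": _BODY_SEMI_AXES,
                "refinement": 2,
            },
            "optical": band_tables("surface"),
        }
    ]
    for organ, (semi, center) in _ORGAN_SHAPES.items():
        regions.append(
            {
                "id": organ,
                "mesh": {
                    "kind": "ellipsoid",
                    "semi_axes": semi,
                    "center": center,
                    "refinement": 1,
                },
                "parent": "body",
                "optical": band_tables(organ),
            }
        )
    if tumor:
        semi, center = _TUMOR_SHAPE
        regions.append(
            {
                "id": "tumor",
                "mesh": {
                    "kind": "ellipsoid",
                    "semi_axes": semi,
                    "center": center,
                    "refinement": 1,
                },
                "parent": "body",
                "optical": band_tables("tumor"),
            }
        )
    return regions


def _dot_mouse(tumor: bool = True) -> dict:
    return {
        "scene": {
            "ambient_n": 1.0,
            "regions": _mouse_regions(lambda t: _optical(DOT_TISSUES[t]), tumor),
        },
        # external beam illuminating the back (+z) perpendicularly,
        # entering above the tumor site
        "source": {
            "kind": "beam",
            "entry": (0.0, 3.0, 7.63),
            "direction": (0.0, 0.0, -1.0),
            "total_power": 1.0,
        },
        "controls": {"n_photons": 10_000_000, "seed": 1},
        "recorders": {
            "absorption": {
                "voxel_mm": 0.5,
                "bounds_lo": (-20.0, -10.0, -8.0),
                "bounds_hi": (20.0, 10.0, 8.0),
            }
        },
    }


def _fmt_td() -> dict:
    def bands(tissue: str) -> dict:
        exc, emi = FMT_TISSUES[tissue]
        return {"excitation": _optical(exc), "emission": _optical(emi)}

    return {
        "scene": {
            "ambient_n": 1.0,
            "regions": _mouse_regions(bands, tumor=False),
        },
        # excitation beam entering the back above the kidney
        "source": {
            "kind": "beam",
            "entry": (3.0, -1.0, 7.86),
            "direction": (0.0, 0.0, -1.0),
            "total_power": 1.0,
            "band": "excitation",
        },
        "fluorophore": {"region": "kidney", "quantum_efficiency": 0.6},
        "controls": {
            "n_photons": 10_000_000,
            "seed": 1,
            "mode": "TD",
            "gates": {"start_ps": 0.0, "stop_ps": 100.0, "dt_ps": 10.0},
        },
        "recorders": {
            "absorption": {
                "voxel_mm": 0.5,
                "bounds_lo": (-20.0, -10.0, -8.0),
                "bounds_hi": (20.0, 10.0, 8.0),
            }
        },
    }


def builtin_example(name: str, **options) -> SimulationConfig:
    """Return a packaged, validated example configuration.

    ``dot_mouse`` accepts ``tumor=False`` for the normal-tissue control
    used in absorption-contrast comparisons.
    """
    if name == "blt_cube":
        data = _blt_cube()
    elif name == "dot_mouse":
        data = _dot_mouse(tumor=options.pop("tumor", True))
    elif name == "fmt_td":
        data = _fmt_td()
    else:
        raise ValueError(
            f"unknown example {name!r}; available: {', '.join(EXAMPLE_NAMES)}"
        )
    if options:
        raise TypeError(f"unknown options for {name!r}: {sorted(options)}")
    return validate_config(data)
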