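"""Profile extraction, normalization and NRMSE comparison of 2D maps.

These are the quantitative-comparison utilities used on transmittance
maps and detector images: sample a line profile by bilinear
interpolation, peak-normalize it, and score two profiles with the
normalized root-mean-square error

    NRMSE(x, y) = ||x - y||_2 / ||y||_2

which is zero iff the profiles are identical and invariant under a
common positive rescaling of both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates


@dataclass
class LineProfile:
    """Ordered sample positions (mm along the line) and values."""

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have matching shapes")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")


def extract_line_profile(image, start, end, n_samples: int, pitch_mm: float = 1.0) -> LineProfile:
    """Bilinear samples at ``n_samples`` evenly spaced points on a segment.

    ``start``/``end`` are (row, col) pixel coordinates (fractional allowed)
    inside the image; positions are millimetres along the segment given the
    pixel ``pitch_mm``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    for p in (start, end):
        if not (0 <= p[0] <= image.shape[0] - 1 and 0 <= p[1] <= image.shape[1] - 1):
            raise ValueError("profile endpoints must lie inside the image")
    if n_samples < 2:
        raise ValueError("need at least two samples")
    frac = np.linspace(0.0, 1.0, n_samples)
    coords = start[:, None] + (end - start)[:, None] * frac[None, :]
    values = map_coordinates(image, coords, order=1, mode="nearest")
    length = np.linalg.norm(end - start) * pitch_mm
    return LineProfile(frac * length, values)


def normalize_profile(profile: LineProfile) -> LineProfile:
    """Divide by the maximum so the peak equals 1 (errors on all-zero input)."""
    peak = profile.values.max(initial=-np.inf)
    if peak <= 0:
        raise ValueError("cannot normalize a profile with no positive values")
    return LineProfile(profile.positions.copy(), profile.values / peak)


def nrmse(x, y) -> float:
    """||x - y||_2 / ||y||_2 over equal-length value arrays (y = reference)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("nrmse requires equal-length inputs")
    if x.size == 0:
        raise ValueError("nrmse requires at least one sample")
    ref = np.sqrt(np.sum(y * y))
    if ref == 0:
        raise ValueError("reference norm is zero")
    return float(np.sqrt(np.sum((x - y) ** 2)) / ref)
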