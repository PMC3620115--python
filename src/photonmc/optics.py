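"""Single-interaction optical physics of the photon-packet random walk.

Every function here is a pure, vectorizable primitive of the Monte Carlo
transport loop: exponential free-path sampling, Henyey-Greenstein deflection,
Fresnel/Snell boundary optics, Russian-roulette termination, fluorescence
conversion and optical-path timekeeping.  The compiled transport kernel
(:mod:`photonmc._kernel`) re-implements the same formulas in scalar numba
code; a unit test pins the two routes against each other.

All lengths are millimetres, times picoseconds, coefficients mm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Speed of light in vacuum, mm per picosecond.
C_MM_PER_PS = 0.299792458


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one tissue region at one wavelength.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient (mm^-1, >= 0).
    mu_s : float
        Scattering coefficient (mm^-1, >= 0).
    g : float
        Henyey-Greenstein anisotropy factor, the mean cosine of the
        single-scattering deflection angle; must lie in (-1, 1).
    n : float
        Refractive index (>= 1).
    """

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"anisotropy g must lie in (-1, 1), got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s (mm^-1)."""
        return self.mu_a + self.mu_s


def _as_open_unit(xi, name: str = "xi"):
    xi = np.asarray(xi, dtype=float)
    if np.any(xi <= 0.0) or np.any(xi >= 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1)")
    return xi


def sample_step(props: OpticalProperties, xi):
    """Sample a free path length s = -ln(xi) / (mu_a + mu_s).

    ``xi`` may be a scalar or array of uniforms in the open interval (0, 1).
    Raises ``ValueError`` when the medium has mu_a + mu_s == 0 (no
    interaction length is defined) or when ``xi`` leaves (0, 1).
    """
    if props.mu_t <= 0.0:
        raise ValueError("step sampling requires mu_a + mu_s > 0")
    xi = _as_open_unit(xi)
    return -np.log(xi) / props.mu_t


def sample_hg_cos(g: float, xi):
    """Inverse-CDF sample of the Henyey-Greenstein deflection cosine.

    For g == 0 the phase function is isotropic and cos(theta) = 2 xi - 1;
    otherwise

        cos(theta) = (1 + g^2 - ((1 - g^2) / (1 + g - 2 g xi))^2) / (2 g)

    The result is clamped to [-1, 1] against rounding.
    """
    if not -1.0 < g < 1.0:
        raise ValueError(f"anisotropy g must lie in (-1, 1), got {g}")
    xi = np.asarray(xi, dtype=float)
    if abs(g) < 1e-12:
        return 2.0 * xi - 1.0
    frac = (1.0 - g * g) / (1.0 + g - 2.0 * g * xi)
    cos_t = (1.0 + g * g - frac * frac) / (2.0 * g)
    return np.clip(cos_t, -1.0, 1.0)


def scatter_direction(direction, cos_theta, phi):
    """Rotate a unit direction by deflection cos(theta) and azimuth phi.

    Uses the standard local-frame update about the current direction; when
    the current direction is within 1e-5 of +/-z the degenerate-frame
    formula applies.  The output is renormalized to unit length.
    """
    u = np.asarray(direction, dtype=float)
    ct = float(cos_theta)
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cp, sp = np.cos(phi), np.sin(phi)
    ux, uy, uz = u
    if abs(uz) > 0.99999:
        out = np.array([st * cp, st * sp, np.sign(uz) * ct])
    else:
        den = np.sqrt(1.0 - uz * uz)
        out = np.array(
            [
                st * (ux * uz * cp - uy * sp) / den + ux * ct,
                st * (uy * uz * cp + ux * sp) / den + uy * ct,
                -st * cp * den + uz * ct,
            ]
        )
    return out / np.linalg.norm(out)


def critical_angle(n_i: float, n_t: float):
    """Critical angle asin(n_t / n_i) in radians, or None.

    Total internal reflection only exists going from the denser medium to
    the rarer one (n_i > n_t); for n_i < n_t there is no critical angle and
    ``None`` is returned.  Matched indices give the grazing limit pi/2.
    """
    if n_i < 1.0 or n_t < 1.0:
        raise ValueError("refractive indices must be >= 1")
    if n_i < n_t:
        return None
    return float(np.arcsin(n_t / n_i))


def fresnel_reflectance(n_i: float, n_t: float, theta_i):
    """Unpolarized Fresnel reflectance R(theta_i) in [0, 1].

    Snell's law gives the transmission angle; the reflectance is

        R = 1/2 [ sin^2(ai - at)/sin^2(ai + at) + tan^2(ai - at)/tan^2(ai + at) ]

    with R = 1 beyond the critical angle and the closed form
    ((n_i - n_t)/(n_i + n_t))^2 at normal incidence.  ``theta_i`` may be a
    scalar or array in [0, pi/2].
    """
    theta_i = np.asarray(theta_i, dtype=float)
    if np.any(theta_i < 0) or np.any(theta_i > np.pi / 2 + 1e-12):
        raise ValueError("theta_i must lie in [0, pi/2]")
    if n_i == n_t:
        return np.zeros_like(theta_i) if theta_i.ndim else 0.0
    sin_i = np.sin(theta_i)
    sin_t = n_i / n_t * sin_i
    tir = sin_t >= 1.0
    sin_t = np.clip(sin_t, 0.0, 1.0 - 1e-16)
    theta_t = np.arcsin(sin_t)
    # Angle-difference form; the tan term vanishes at Brewster incidence
    # where tan(ai + at) diverges.
    with np.errstate(divide="ignore", invalid="ignore"):
        s_ratio = np.sin(theta_i - theta_t) ** 2 / np.sin(theta_i + theta_t) ** 2
        t_ratio = (np.tan(theta_i - theta_t) / np.tan(theta_i + theta_t)) ** 2
    t_ratio = np.where(np.isfinite(t_ratio), t_ratio, 0.0)
    r = 0.5 * (s_ratio + t_ratio)
    normal = sin_i < 1e-9
    r0 = ((n_i - n_t) / (n_i + n_t)) ** 2
    r = np.where(normal, r0, r)
    r = np.where(tir, 1.0, r)
    r = np.clip(r, 0.0, 1.0)
    return float(r) if r.ndim == 0 else r


def specular_reflectance(n_i: float, n_t: float) -> float:
    """Normal-incidence Fresnel reflectance ((n_i - n_t)/(n_i + n_t))^2."""
    return ((n_i - n_t) / (n_i + n_t)) ** 2


def roulette(weight: float, m: float, xi: float) -> float:
    """Russian-roulette termination: survive with probability 1/m at m*w.

    The scheme is unbiased: E[output] = (1/m) * m * w = w.
    """
    if m <= 1.0:
        raise ValueError("roulette constant m must exceed 1")
    if weight < 0.0:
        raise ValueError("weight must be non-negative")
    return m * weight if xi <= 1.0 / m else 0.0


def fluorescence_convert(eta: float, xi):
    """Bernoulli fluorescence conversion: True iff xi < eta.

    ``eta`` is the quantum efficiency of the fluorophore, the probability
    that an excitation interaction launches an emission packet.  Accepts a
    scalar or array of uniforms.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("quantum efficiency must lie in [0, 1]")
    xi = np.asarray(xi, dtype=float)
    out = xi < eta
    return bool(out) if out.ndim == 0 else out


def advance_time(time_ps: float, step_mm: float, n: float) -> float:
    """Advance elapsed time by the optical path step * n / c (picoseconds)."""
    if step_mm < 0:
        raise ValueError("step must be non-negative")
    return time_ps + step_mm * n / C_MM_PER_PS
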