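"""Synthetic AFM data with known ground truth.

Every downstream stage (roughness, indentation, dehydration) is exercised
on data from this module, so each generator records the quantity the
analysis is supposed to recover:

* height maps — an isotropic correlated Gaussian field rescaled to an
  exact target Ra, with optional smooth elliptical lacunae (depressions)
  and a tilt plane;
* force curves — forward Hertz-sphere inversion of a prescribed modulus
  profile E(h), with a flat pre-contact baseline, the true contact index,
  and optional Gaussian deflection noise;
* dehydration series — the power-law drying model with multiplicative
  Gaussian noise.

All generators take an explicit integer seed and are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .dehydration import DehydrationSeries
from .indentation import ForceCurve, HertzParams, hertz_deflection
from .roughness import HeightMap

__all__ = [
    "LacunaSpec",
    "SurfaceSpec",
    "CurveSpec",
    "LacunaOutsideGridError",
    "generate_height_map",
    "generate_force_curve",
    "generate_dehydration_series",
    "linear_modulus_profile",
    "piecewise_modulus_profile",
]

EProfile = Union[float, Callable[[np.ndarray], np.ndarray]]


class LacunaOutsideGridError(ValueError):
    """A lacuna footprint extends beyond the height-map grid."""


@dataclass(frozen=True)
class LacunaSpec:
    """A smooth elliptical depression: centre and semi-axes in nm, depth in nm.

    The footprint is the ellipse of the given semi-axes; the profile is a
    raised-cosine bowl reaching the full depth at the centre and zero at
    the ellipse boundary (continuously differentiable, so levelling and
    peak detection stay well-posed).
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    depth: float

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("lacuna depth must be positive")
        if min(self.semi_axes) <= 0:
            raise ValueError("lacuna semi-axes must be positive")


@dataclass(frozen=True)
class SurfaceSpec:
    """Recipe for a synthetic cartilage-like surface.

    ``target_Ra`` (nm) is hit exactly (to float precision) for the base
    texture: the correlated field is rescaled so the grand mean of per-row
    profile Ra equals it.  Lacunae are subtracted and the tilt plane added
    afterwards, mimicking features the analysis must handle.
    ``correlation_length`` is the 1/e half-width of the field's Gaussian
    autocorrelation, at least twice the pixel size.
    """

    nx: int
    ny: int
    pixel_size: float
    target_Ra: float
    correlation_length: float
    tilt: tuple[float, float] = (0.0, 0.0)
    lacunae: tuple[LacunaSpec, ...] = ()
    seed: int = 0
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise ValueError("grid must be at least 8x8")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.target_Ra <= 0:
            raise ValueError("target_Ra must be positive")
        if self.correlation_length < 2.0 * self.pixel_size:
            raise ValueError("correlation_length must be >= 2 * pixel_size")
        object.__setattr__(self, "lacunae", tuple(self.lacunae))


def generate_height_map(spec: SurfaceSpec) -> HeightMap:
    """Correlated random surface with exact row-profile Ra, lacunae and tilt.

    White noise is smoothed with a Gaussian kernel of sigma =
    correlation_length / (sqrt(2) * pixel_size) pixels, giving the field a
    Gaussian autocorrelation of 1/e half-width ``correlation_length``; the
    smoothed field is rescaled so the grand mean of per-row Ra equals
    ``target_Ra``.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.ny, spec.nx))
    sigma_px = spec.correlation_length / (np.sqrt(2.0) * spec.pixel_size)
    z = gaussian_filter(z, sigma_px, mode="reflect")
    z -= z.mean()
    # mean over rows of mean|row - row mean|; linear in the field amplitude
    ra = np.mean(np.abs(z - z.mean(axis=1, keepdims=True)))
    if ra == 0:
        raise ValueError("degenerate random field (zero roughness)")
    z *= spec.target_Ra / ra

    ps = spec.pixel_size
    x = np.arange(spec.nx) * ps
    y = np.arange(spec.ny) * ps
    X, Y = np.meshgrid(x, y)
    for lac in spec.lacunae:
        cx, cy = lac.center
        a, b = lac.semi_axes
        if cx - a < 0 or cx + a > x[-1] or cy - b < 0 or cy + b > y[-1]:
            raise LacunaOutsideGridError(
                f"lacuna at ({cx}, {cy}) nm with semi-axes ({a}, {b}) nm "
                "extends outside the grid"
            )
        r = np.sqrt(((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2)
        inside = r < 1.0
        z[inside] -= lac.depth * np.cos(0.5 * np.pi * r[inside]) ** 2

    sx, sy = spec.tilt
    if sx or sy:
        cols, rows = np.meshgrid(np.arange(spec.nx), np.arange(spec.ny))
        z = z + sx * cols + sy * rows
    return HeightMap(z, ps, spec.label)


def linear_modulus_profile(E_at_0: float, E_at_hmax: float, h_max: float):
    """E(h) declining (or rising) linearly between the surface and h_max."""

    def profile(h):
        return E_at_0 + (E_at_hmax - E_at_0) * np.asarray(h, dtype=float) / h_max

    return profile


def piecewise_modulus_profile(anchors: Sequence[tuple[float, float]]):
    """Piecewise-linear E(h) through (h_nm, E_MPa) anchor points."""
    pts = sorted(anchors)
    hs = np.array([p[0] for p in pts], dtype=float)
    Es = np.array([p[1] for p in pts], dtype=float)

    def profile(h):
        return np.interp(np.asarray(h, dtype=float), hs, Es)

    return profile


@dataclass(frozen=True)
class CurveSpec:
    """Recipe for a synthetic Hertzian force curve.

    ``E_profile`` is either a constant modulus (MPa) or a callable mapping
    depth h (nm) to E (MPa); it must be positive over [0, h_max].
    ``n_contact`` samples cover depths 0..h_max uniformly; ``n_baseline``
    zero-deflection samples are prepended.  Gaussian noise of sd
    ``noise_sd`` (nm) is added to Zdefl only — Zpos is treated as exactly
    commanded.
    """

    E_profile: EProfile
    k: float = 0.08
    R: float = 30.0
    V: float = 0.5
    h_max: float = 300.0
    n_contact: int = 100
    n_baseline: int = 30
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h_max <= 0:
            raise ValueError("h_max must be positive")
        if not 0.0 <= self.V < 1.0:
            raise ValueError("Poisson ratio must lie in [0, 1)")
        if self.k <= 0 or self.R <= 0:
            raise ValueError("k and R must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_contact < 4 or self.n_baseline < 4:
            raise ValueError("need at least 4 contact and 4 baseline samples")

    @property
    def params(self) -> HertzParams:
        return HertzParams(V=self.V, k=self.k, R=self.R)

    def modulus_at(self, h) -> np.ndarray:
        if callable(self.E_profile):
            return np.asarray(self.E_profile(h), dtype=float)
        return np.full_like(np.asarray(h, dtype=float), float(self.E_profile))


def generate_force_curve(spec: CurveSpec) -> ForceCurve:
    """Forward-model a force curve from a prescribed E(h).

    Depths h lie on a uniform grid over [0, h_max]; Zdefl follows the
    Hertz-sphere relation for E(h), Zpos = h + Zdefl.  The returned curve
    carries the true contact index (the h = 0 sample, immediately after
    the baseline).
    """
    params = spec.params
    h = np.linspace(0.0, spec.h_max, spec.n_contact)
    E = spec.modulus_at(h)
    if np.any(E <= 0):
        raise ValueError("E_profile must be positive over [0, h_max]")
    zdefl_contact = hertz_deflection(E, h, params)
    zpos_contact = h + zdefl_contact

    dz = zpos_contact[1] - zpos_contact[0]
    zpos_base = -dz * np.arange(spec.n_baseline, 0, -1)
    zpos = np.concatenate([zpos_base, zpos_contact])
    zdefl = np.concatenate([np.zeros(spec.n_baseline), zdefl_contact])
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        zdefl = zdefl + rng.normal(0.0, spec.noise_sd, size=zdefl.size)
    return ForceCurve(
        zpos=zpos,
        zdefl=zdefl,
        params=params,
        z0=0.0,
        true_contact_index=spec.n_baseline,
    )


def generate_dehydration_series(
    m0: float,
    b: float,
    times,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DehydrationSeries:
    """Drying series m_i = m0 (1+t_i)^b (1 + eps_i), eps ~ N(0, noise_sd).

    ``noise_sd`` is relative (multiplicative); the series is deterministic
    for a fixed seed.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if m0 <= 0:
        raise ValueError("m0 must be positive")
    if b >= 0:
        raise ValueError("drying exponent b must be negative")
    m = m0 * np.power(1.0 + t, b)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        m = m * (1.0 + rng.normal(0.0, noise_sd, size=t.size))
    return DehydrationSeries(t=t, m=m)
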