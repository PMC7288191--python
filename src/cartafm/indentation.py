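"""Depth-resolved Young's modulus from AFM force curves (Hertz sphere model).

A force curve records cantilever deflection ``Zdefl`` against vertical
stage position ``Zpos`` (both nm).  After contact, the tip penetrates the
sample to depth

    h = Zpos - Zdefl,

and for a spherical tip of radius R on an elastic half-space the pointwise
Young's modulus is

    E(h) = 3 (1 - V^2) k Zdefl / (4 sqrt(R) h^{3/2}),

with cantilever stiffness k (N/m) and Poisson ratio V.  All lengths are
carried in nm at the interface and converted to SI internally, so E comes
out in Pa and is returned in MPa.

The analysis covers the approach (loading) segment only.  Contact is found
by a baseline-noise threshold; E is evaluated pointwise for h at or above a
lower cutoff ``h_min`` (default 10 nm) that guards the h^{-3/2} divergence
near the contact point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "HertzParams",
    "ForceCurve",
    "ModulusProfile",
    "ModulusSummary",
    "ContactNotFoundError",
    "DEFAULT_H_MIN",
    "hertz_deflection",
    "detect_contact_point",
    "compute_indentation_depth",
    "compute_E_point",
    "compute_E_profile",
    "average_profiles",
    "extract_modulus_summary",
]

_NM = 1e-9  # nm -> m
_MPA = 1e6  # Pa -> MPa divisor

#: Default lower depth cutoff (nm) below which E is not evaluated.
DEFAULT_H_MIN = 10.0


class ContactNotFoundError(ValueError):
    """No sample of the curve satisfies the contact criterion."""


@dataclass(frozen=True)
class HertzParams:
    """Probe constants: Poisson ratio V, cantilever stiffness k (N/m), tip radius R (nm).

    Defaults are the cartilage/CSC38 values V = 0.5, k = 0.08 N/m, R = 30 nm.
    """

    V: float = 0.5
    k: float = 0.08
    R: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.V < 1.0:
            raise ValueError("Poisson ratio must lie in [0, 1)")
        if self.k <= 0 or self.R <= 0:
            raise ValueError("stiffness and tip radius must be positive")


@dataclass(frozen=True, eq=False)
class ForceCurve:
    """Approach segment of a force curve: paired (Zpos, Zdefl) in nm.

    ``z0`` is the baseline deflection reference; ``true_contact_index`` is
    ground truth carried by the synthetic generator (None for real data).
    """

    zpos: np.ndarray
    zdefl: np.ndarray
    params: HertzParams = field(default_factory=HertzParams)
    z0: float = 0.0
    true_contact_index: Optional[int] = None

    def __post_init__(self) -> None:
        zp = np.asarray(self.zpos, dtype=float)
        zd = np.asarray(self.zdefl, dtype=float)
        if zp.ndim != 1 or zp.shape != zd.shape or zp.size < 8:
            raise ValueError("zpos and zdefl must be equal-length 1-D arrays (n >= 8)")
        if np.any(np.diff(zp) <= 0):
            raise ValueError("zpos must be strictly increasing")
        object.__setattr__(self, "zpos", zp)
        object.__setattr__(self, "zdefl", zd)

    def __len__(self) -> int:
        return self.zpos.size


@dataclass(frozen=True, eq=False)
class ModulusProfile:
    """Depth-resolved modulus: depths h (nm, increasing) and E (MPa)."""

    h: np.ndarray
    E: np.ndarray
    h_min: float = DEFAULT_H_MIN

    def __post_init__(self) -> None:
        h = np.asarray(self.h, dtype=float)
        E = np.asarray(self.E, dtype=float)
        if h.ndim != 1 or h.shape != E.shape or h.size == 0:
            raise ValueError("h and E must be non-empty 1-D arrays of equal length")
        if np.any(np.diff(h) <= 0):
            raise ValueError("depths must be strictly increasing")
        if h[0] < self.h_min or self.h_min <= 0:
            raise ValueError("depths must satisfy h >= h_min > 0")
        object.__setattr__(self, "h", h)
        object.__setattr__(self, "E", E)

    def __len__(self) -> int:
        return self.h.size


@dataclass(frozen=True)
class ModulusSummary:
    """Surface and maximum modulus of one averaged profile."""

    E_surface: float
    E_max: float
    h_at_max: float


def hertz_deflection(E_mpa, h_nm, params: HertzParams):
    """Cantilever deflection (nm) produced by modulus E (MPa) at depth h (nm).

    Forward Hertz-sphere relation, the inverse of :func:`compute_E_point`;
    used by the synthetic force-curve generator.
    """
    E_pa = np.asarray(E_mpa, dtype=float) * _MPA
    h_m = np.asarray(h_nm, dtype=float) * _NM
    zdefl_m = 4.0 * E_pa * np.sqrt(params.R * _NM) * h_m ** 1.5 / (
        3.0 * (1.0 - params.V ** 2) * params.k
    )
    return zdefl_m / _NM


def compute_E_point(
    zdefl_nm: float, h_nm: float, params: HertzParams, h_min: float = DEFAULT_H_MIN
) -> float:
    """Pointwise Young's modulus (MPa) from one (Zdefl, h) pair.

    E = 3 (1-V^2) k Zdefl / (4 sqrt(R) h^{3/2}) evaluated in SI internally.
    ``h`` below ``h_min`` is rejected (the expression diverges as h -> 0),
    as is negative deflection.
    """
    if h_nm < h_min:
        raise ValueError(f"depth {h_nm} nm is below the cutoff h_min={h_min} nm")
    if zdefl_nm < 0:
        raise ValueError("deflection must be non-negative")
    E_pa = (
        3.0 * (1.0 - params.V ** 2) * params.k * (zdefl_nm * _NM)
        / (4.0 * np.sqrt(params.R * _NM) * (h_nm * _NM) ** 1.5)
    )
    return float(E_pa / _MPA)


def detect_contact_point(
    curve: ForceCurve,
    noise_mult: float = 3.0,
    baseline_fraction: float = 0.2,
    persistence: int = 3,
) -> int:
    """Index of the first sample whose deflection rises clearly above baseline.

    Baseline mean and sd are estimated from the first ``baseline_fraction``
    of samples; contact is the first index where Zdefl exceeds
    mean + noise_mult * sd and stays above for ``persistence`` consecutive
    samples.  Raises :class:`ContactNotFoundError` when no index qualifies
    (e.g. an all-baseline curve).
    """
    zd = curve.zdefl
    nb = max(3, int(round(baseline_fraction * zd.size)))
    mu = float(zd[:nb].mean())
    sd = float(zd[:nb].std(ddof=1))
    # noiseless baselines have sd == 0; require a strict rise above the mean
    scale = max(float(np.max(np.abs(zd))), 1.0)
    threshold = mu + max(noise_mult * sd, 1e-12 * scale)
    above = zd > threshold
    if persistence > 1:
        windows = np.lib.stride_tricks.sliding_window_view(above, persistence)
        sustained = windows.all(axis=1)
    else:
        sustained = above
    idx = np.flatnonzero(sustained)
    if idx.size == 0:
        raise ContactNotFoundError("no contact detected: deflection never leaves baseline")
    return int(idx[0])


def compute_indentation_depth(curve: ForceCurve, contact: int) -> np.ndarray:
    """Indentation depths h = Zpos - Zdefl (nm) for samples from ``contact`` on.

    Both channels are re-referenced to the contact sample.  Any
    substantially negative depth signals a mis-placed contact point and
    raises; sub-nm numerical negatives are clipped to zero.
    """
    if not 0 <= contact < len(curve):
        raise ValueError("contact index out of range")
    zp = curve.zpos[contact:] - curve.zpos[contact]
    zd = curve.zdefl[contact:] - curve.zdefl[contact]
    h = zp - zd
    if np.any(h < -1e-6):
        raise ValueError("negative indentation depth: bad contact point")
    return np.clip(h, 0.0, None)


def compute_E_profile(
    curve: ForceCurve,
    h_min: float = DEFAULT_H_MIN,
    noise_mult: float = 3.0,
    baseline_fraction: float = 0.2,
) -> ModulusProfile:
    """Depth-resolved E(h) for the post-contact part of a force curve.

    The threshold crossing found by :func:`detect_contact_point` overshoots
    the mechanical touch point by construction (deflection must already
    exceed the noise band there), so the sample immediately before the
    crossing is used as the contact reference for re-zeroing Zpos.  Zdefl
    is re-zeroed to the baseline mean, which is less noisy than any single
    sample.  E is evaluated pointwise wherever h >= h_min.
    """
    i_cross = detect_contact_point(
        curve, noise_mult=noise_mult, baseline_fraction=baseline_fraction
    )
    ref = max(i_cross - 1, 0)
    nb = max(3, int(round(baseline_fraction * len(curve))))
    baseline = float(curve.zdefl[:nb].mean())

    zp = curve.zpos[ref:] - curve.zpos[ref]
    zd = curve.zdefl[ref:] - baseline
    h = zp - zd
    # near-contact samples carry deflection noise into h; only depths clearly
    # below zero (beyond the noise band) indicate a mis-detected contact
    noise_sd = float(curve.zdefl[:nb].std(ddof=1))
    if np.any(h < -(1e-6 + 6.0 * noise_sd)):
        raise ValueError("negative indentation depth: bad contact point")
    h = np.clip(h, 0.0, None)

    mask = h >= h_min
    if not np.any(mask):
        raise ValueError(f"no post-contact samples with h >= {h_min} nm")
    h_sel = h[mask]
    zd_sel = np.clip(zd[mask], 0.0, None)
    E = np.array(
        [compute_E_point(z, d, curve.params, h_min=h_min) for z, d in zip(zd_sel, h_sel)]
    )
    return ModulusProfile(h=h_sel, E=E, h_min=h_min)


def average_profiles(
    profiles: Sequence[ModulusProfile], n_grid: Optional[int] = None
) -> ModulusProfile:
    """Pointwise mean of modulus profiles over their common depth range.

    Profiles are linearly resampled onto a shared grid spanning the overlap
    of their depth ranges (``n_grid`` points, default the longest input).
    Raises when the overlap is empty.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    lo = max(p.h[0] for p in profiles)
    hi = min(p.h[-1] for p in profiles)
    if not lo < hi:
        raise ValueError("profiles have no overlapping depth range")
    if n_grid is None:
        n_grid = max(len(p) for p in profiles)
    grid = np.linspace(lo, hi, n_grid)
    E = np.mean([np.interp(grid, p.h, p.E) for p in profiles], axis=0)
    return ModulusProfile(h=grid, E=E, h_min=max(p.h_min for p in profiles))


def extract_modulus_summary(profile: ModulusProfile) -> ModulusSummary:
    """Surface modulus (at the shallowest depth) and the profile maximum."""
    i_max = int(np.argmax(profile.E))
    return ModulusSummary(
        E_surface=float(profile.E[0]),
        E_max=float(profile.E[i_max]),
        h_at_max=float(profile.h[i_max]),
    )
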