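"""Surface-roughness metrology for AFM height maps of cartilage.

Implements the profile parameters used to stage osteoarthritic wear:

* ``Ra`` — arithmetic mean of absolute height deviations from the profile
  mean line;
* ``Rp`` — maximum peak height above the mean line;
* ``S``  — mean spacing between consecutive local peaks along the profile;
* ``Sa`` — areal analogue of Ra over the whole 2-D map.

Maps are plane-levelled before any parameter is computed; profiles are
taken row-wise, following the AFM fast-scan raster convention.  Wear stages
are assigned from Ra measured at the 9x9 um^2 scan area by an equal-width
tripartition of the worn range [24.6, 61.2] nm, with Ra above 61.2 nm
classed healthy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "HeightMap",
    "Profile",
    "RoughnessResult",
    "RoughnessSummary",
    "LacunaRegion",
    "WearStage",
    "UndefinedPeakSpacingError",
    "WEAR_RA_MIN",
    "WEAR_RA_MAX",
    "wear_stage_bounds",
    "level_height_map",
    "extract_profiles",
    "compute_Ra",
    "compute_Rp",
    "compute_S",
    "compute_Sa",
    "map_roughness",
    "detect_lacunae",
    "summarize_roughness",
    "percent_change",
    "stage_wear",
]

ROUGHNESS_PARAMETERS = ("Ra", "Rp", "S")

#: Worn-cartilage Ra range (nm) that is tripartitioned into wear stages.
WEAR_RA_MIN = 24.6
WEAR_RA_MAX = 61.2


class UndefinedPeakSpacingError(ValueError):
    """Raised when a profile has fewer than two local peaks, so S is undefined."""


@dataclass(frozen=True, eq=False)
class HeightMap:
    """A rectangular grid of surface heights.

    Parameters
    ----------
    heights : 2-D array
        Heights in nm, shape (ny, nx); all values must be finite.
    pixel_size : float
        Lateral sampling step in nm/pixel (square pixels).
    label : str
        Scan-area tag, e.g. ``"9x9"`` for a 9x9 um^2 scan; free-form.
    """

    heights: np.ndarray
    pixel_size: float
    label: str = "custom"

    def __post_init__(self) -> None:
        z = np.asarray(self.heights, dtype=float)
        if z.ndim != 2 or min(z.shape) < 2:
            raise ValueError("heights must be a 2-D grid of at least 2x2")
        if not np.all(np.isfinite(z)):
            raise ValueError("heights must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "heights", z)

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def scan_area_um2(self) -> float:
        ny, nx = self.heights.shape
        return (nx * self.pixel_size * 1e-3) * (ny * self.pixel_size * 1e-3)


@dataclass(frozen=True, eq=False)
class Profile:
    """A 1-D height profile with uniform lateral spacing (both in nm)."""

    y: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 1 or y.size < 3:
            raise ValueError("profile needs at least 3 samples")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "y", y)


@dataclass(frozen=True)
class RoughnessResult:
    """Roughness parameters of one measurement point (nm)."""

    Ra: float
    Rp: float
    S: float
    n_peaks: int = 0


@dataclass(frozen=True)
class LacunaRegion:
    """A detected depression: centroid (nm), area (nm^2), max depth (nm)."""

    id: int
    x_nm: float
    y_nm: float
    area_nm2: float
    depth_nm: float


@dataclass(frozen=True)
class RoughnessSummary:
    """Per-area descriptive statistics of roughness parameters.

    ``table`` has one row per (Ar, parameter) with columns
    mean, sd, min, max, n; ``n_total`` counts all measurement records
    (points x specimens x scan areas).
    """

    table: pd.DataFrame
    n_total: int


@dataclass(frozen=True)
class WearStage:
    """Wear-stage label with the Ra interval (nm) that produced it."""

    label: str
    Ra_bounds: tuple[float, float]


def level_height_map(hmap: HeightMap) -> HeightMap:
    """Remove the least-squares plane (tilt + offset) from a height map.

    The output has zero mean; refitting a plane to it yields coefficients
    at numerical-noise level.  A constant map levels to all zeros.
    """
    z = hmap.heights
    ny, nx = z.shape
    x, y = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    design = np.column_stack([np.ones(z.size), x.ravel(), y.ravel()])
    coef, *_ = np.linalg.lstsq(design, z.ravel(), rcond=None)
    plane = (design @ coef).reshape(z.shape)
    return HeightMap(z - plane, hmap.pixel_size, hmap.label)


def extract_profiles(hmap: HeightMap) -> list[Profile]:
    """One profile per grid row, in row order, spacing = pixel size."""
    return [Profile(row, hmap.pixel_size) for row in hmap.heights]


def compute_Ra(profile: Profile) -> float:
    """Arithmetic mean of |y - mean(y)| along the profile."""
    y = profile.y
    return float(np.mean(np.abs(y - y.mean())))


def compute_Rp(profile: Profile) -> float:
    """Maximum peak height above the profile mean line."""
    y = profile.y
    return float(y.max() - y.mean())


def _peak_indices(y: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus collapse to their first sample."""
    # run-length encode so equal-height plateaus count once
    change = np.flatnonzero(np.diff(y) != 0)
    starts = np.concatenate([[0], change + 1])
    vals = y[starts]
    if vals.size < 3:
        return np.empty(0, dtype=int)
    inner = np.arange(1, vals.size - 1)
    is_peak = (vals[inner] > vals[inner - 1]) & (vals[inner] > vals[inner + 1])
    return starts[inner[is_peak]]


def compute_S(profile: Profile) -> float:
    """Mean spacing (nm) between consecutive local peaks of the profile.

    A local peak is a sample strictly greater than both neighbours; runs of
    equal height are collapsed to their first sample.  Raises
    :class:`UndefinedPeakSpacingError` when fewer than two peaks exist.
    """
    peaks = _peak_indices(profile.y)
    if peaks.size < 2:
        raise UndefinedPeakSpacingError(
            f"profile has {peaks.size} local peak(s); S needs at least 2"
        )
    return float(np.mean(np.diff(peaks)) * profile.spacing)


def count_peaks(profile: Profile) -> int:
    return int(_peak_indices(profile.y).size)


def compute_Sa(hmap: HeightMap) -> float:
    """Areal mean absolute deviation of heights from the grid mean (nm)."""
    z = hmap.heights
    return float(np.mean(np.abs(z - z.mean())))


def map_roughness(hmap: HeightMap, level: bool = True) -> RoughnessResult:
    """Roughness parameters of a map, aggregated over its row profiles.

    Ra and Rp are means of the per-row values; S is the mean over rows that
    contain at least two local peaks (NaN when no row does).  This is the
    per-measurement-point statistic used by the study pipeline.
    """
    if level:
        hmap = level_height_map(hmap)
    profiles = extract_profiles(hmap)
    ra = np.mean([compute_Ra(p) for p in profiles])
    rp = np.mean([compute_Rp(p) for p in profiles])
    spacings, n_peaks = [], 0
    for p in profiles:
        peaks = _peak_indices(p.y)
        n_peaks += peaks.size
        if peaks.size >= 2:
            spacings.append(np.mean(np.diff(peaks)) * p.spacing)
    s = float(np.mean(spacings)) if spacings else float("nan")
    return RoughnessResult(Ra=float(ra), Rp=float(rp), S=s, n_peaks=n_peaks)


def detect_lacunae(hmap: HeightMap, depth_threshold: float) -> list[LacunaRegion]:
    """Find connected depressions deeper than ``depth_threshold`` (nm).

    Depth is measured relative to the median height of the (levelled) map,
    which is robust to the depressions themselves.  Each connected region
    below ``median - depth_threshold`` is reported with its centroid (nm),
    area (nm^2) and maximum depth (nm).  Returns an empty list when nothing
    exceeds the threshold; the count is non-increasing in the threshold.
    """
    if depth_threshold <= 0:
        raise ValueError("depth_threshold must be positive")
    z = hmap.heights
    ref = float(np.median(z))
    mask = z < ref - depth_threshold
    labels, n = ndimage.label(mask)
    regions: list[LacunaRegion] = []
    if n == 0:
        return regions
    ps = hmap.pixel_size
    centroids = ndimage.center_of_mass(mask, labels, range(1, n + 1))
    minima = ndimage.minimum(z, labels, range(1, n + 1))
    areas = ndimage.sum_labels(mask, labels, range(1, n + 1))
    for i, ((cy, cx), zmin, npx) in enumerate(zip(centroids, minima, areas), start=1):
        regions.append(
            LacunaRegion(
                id=i,
                x_nm=float(cx * ps),
                y_nm=float(cy * ps),
                area_nm2=float(npx * ps * ps),
                depth_nm=float(ref - zmin),
            )
        )
    return regions


def summarize_roughness(
    grouped: Mapping[str, Iterable[RoughnessResult]]
) -> RoughnessSummary:
    """Descriptive statistics of Ra/Rp/S per scan area.

    ``grouped`` maps a scan-area label to the measurement results collected
    at that area.  The summary reports mean, sd (n-1 denominator; 0 for a
    single value), min and max per parameter, ignoring NaN values of S, and
    the total record count over all areas.
    """
    rows = []
    n_total = 0
    for ar, results in grouped.items():
        results = list(results)
        if not results:
            raise ValueError(f"empty result group for scan area {ar!r}")
        n_total += len(results)
        for param in ROUGHNESS_PARAMETERS:
            vals = np.array([getattr(r, param) for r in results], dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                mean = sd = lo = hi = float("nan")
            else:
                mean = float(vals.mean())
                sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
                lo, hi = float(vals.min()), float(vals.max())
            rows.append(
                {"Ar": ar, "parameter": param, "mean": mean, "sd": sd,
                 "min": lo, "max": hi, "n": len(results)}
            )
    table = pd.DataFrame(rows, columns=["Ar", "parameter", "mean", "sd", "min", "max", "n"])
    return RoughnessSummary(table=table, n_total=n_total)


def percent_change(healthy_mean: float, worn_extreme: float, rounded: bool = True):
    """Percent decrease of a roughness parameter relative to the healthy mean.

    100 * (healthy_mean - worn_extreme) / healthy_mean, rounded to the
    nearest integer for reporting by default.
    """
    if healthy_mean <= 0:
        raise ValueError("healthy mean must be positive")
    pct = 100.0 * (healthy_mean - worn_extreme) / healthy_mean
    return int(round(pct)) if rounded else pct


def wear_stage_bounds() -> tuple[float, float, float, float]:
    """Stage edges (nm) from the equal-width tripartition of the worn Ra range."""
    width = (WEAR_RA_MAX - WEAR_RA_MIN) / 3.0
    return (
        WEAR_RA_MIN,
        WEAR_RA_MIN + width,
        WEAR_RA_MIN + 2.0 * width,
        WEAR_RA_MAX,
    )


def stage_wear(Ra: float) -> WearStage:
    """Assign a wear stage from Ra (nm) measured at the 9x9 um^2 area.

    healthy above 61.2 nm; then three equal-width worn stages
    (small / medium / heavy) tiling [24.6, 61.2] nm; ``out_of_range``
    below 24.6 nm.  Boundary values fall to the more-worn stage.
    """
    if Ra < 0:
        raise ValueError("Ra must be non-negative")
    b0, b1, b2, b3 = wear_stage_bounds()
    if Ra > b3:
        return WearStage("healthy", (b3, float("inf")))
    if Ra > b2:
        return WearStage("small", (b2, b3))
    if Ra > b1:
        return WearStage("medium", (b1, b2))
    if Ra >= b0:
        return WearStage("heavy", (b0, b1))
    return WearStage("out_of_range", (0.0, b0))
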