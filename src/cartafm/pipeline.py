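"""End-to-end synthetic study orchestration.

Mirrors the measurement protocol of the cartilage study: a cohort of
healthy and worn specimens is imaged at three scan areas (3x3, 9x9,
18x18 um^2); roughness parameters are measured at five sub-window points
per specimen per area; per-area summaries, healthy-vs-worn percent
changes and wear-stage assignments are tabulated.  Separately, force
curves are collected in triplicate per wear stage and cartilage layer
(surface layer 1, cross-section layers 2 and 3), averaged, and reduced to
surface / maximum modulus.

Everything is seeded and deterministic: reruns with the same config and
seed produce byte-identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import io as cio
from .indentation import (
    HertzParams,
    average_profiles,
    compute_E_profile,
    extract_modulus_summary,
)
from .roughness import (
    RoughnessResult,
    RoughnessSummary,
    map_roughness,
    percent_change,
    stage_wear,
    summarize_roughness,
)
from .synthetic import CurveSpec, SurfaceSpec, generate_force_curve, generate_height_map
from .synthetic import piecewise_modulus_profile

logger = logging.getLogger(__name__)

__all__ = [
    "ScanArea",
    "CohortGroup",
    "StageModulusModel",
    "StudyConfig",
    "StudyReport",
    "DEFAULT_AREAS",
    "DEFAULT_MODULUS_MODELS",
    "default_config",
    "run_roughness_study",
    "run_indentation_study",
    "write_report",
]


@dataclass(frozen=True)
class ScanArea:
    """One AFM scan scale: label, side length (um) and grid resolution."""

    label: str
    size_um: float
    n_pixels: int = 128


DEFAULT_AREAS = (
    ScanArea("3x3", 3.0),
    ScanArea("9x9", 9.0),
    ScanArea("18x18", 18.0),
)


@dataclass(frozen=True)
class CohortGroup:
    """A specimen group with per-area roughness targets (nm).

    ``target_Ra`` is either one value for all scan areas or a mapping from
    area label to Ra.  ``role`` marks the reference group ("healthy") that
    percent changes are computed against.
    """

    name: str
    n_specimens: int
    target_Ra: Union[float, Mapping[str, float]]
    role: str = "worn"
    correlation_length_nm: float = 250.0

    def ra_for(self, area_label: str) -> float:
        if isinstance(self.target_Ra, Mapping):
            return float(self.target_Ra[area_label])
        return float(self.target_Ra)


@dataclass(frozen=True)
class StageModulusModel:
    """Ground-truth E(h) anchors per cartilage layer for one wear stage.

    ``layers`` maps layer number (1 = surface, 2/3 = cross-sections) to a
    tuple of (h_nm, E_MPa) anchor points of a piecewise-linear profile.
    """

    stage: str
    layers: Mapping[int, tuple[tuple[float, float], ...]]


# Stage models emulating the reported E(h) behaviour: healthy surfaces
# decline monotonically 1.7 -> 0.5 MPa; worn surfaces rise from their
# surface value to a maximum (~1.2-1.3 MPa) before decreasing; deeper
# cross-section layers decline monotonically at every stage.
DEFAULT_MODULUS_MODELS = (
    StageModulusModel("healthy", {
        1: ((0.0, 1.7), (300.0, 0.5)),
        2: ((0.0, 1.7), (300.0, 0.5)),
        3: ((0.0, 1.7), (300.0, 0.5)),
    }),
    StageModulusModel("small", {
        1: ((0.0, 1.14), (120.0, 1.3), (300.0, 0.8)),
        2: ((0.0, 1.2), (300.0, 0.65)),
        3: ((0.0, 1.2), (300.0, 0.65)),
    }),
    StageModulusModel("medium", {
        1: ((0.0, 1.02), (120.0, 1.2), (300.0, 0.75)),
        2: ((0.0, 1.0), (300.0, 0.6)),
        3: ((0.0, 1.0), (300.0, 0.6)),
    }),
    StageModulusModel("heavy", {
        1: ((0.0, 0.82), (120.0, 1.2), (300.0, 0.7)),
        2: ((0.0, 0.8), (300.0, 0.6)),
        3: ((0.0, 0.8), (300.0, 0.6)),
    }),
)

# Per-area healthy Ra targets follow the study's summary table; the worn
# targets sit inside the worn range at each scale.
HEALTHY_RA = {"3x3": 28.0, "9x9": 86.0, "18x18": 96.0}
WORN_RA = {"3x3": 10.0, "9x9": 30.0, "18x18": 65.0}


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the full synthetic study."""

    groups: tuple[CohortGroup, ...]
    areas: tuple[ScanArea, ...] = DEFAULT_AREAS
    n_points: int = 5
    modulus_models: tuple[StageModulusModel, ...] = DEFAULT_MODULUS_MODELS
    n_repeats: int = 3
    curve_noise_sd_nm: float = 0.1
    hertz: HertzParams = field(default_factory=HertzParams)
    h_max_nm: float = 300.0
    n_contact: int = 100
    n_baseline: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort must contain at least one group")
        if any(g.n_specimens < 1 for g in self.groups):
            raise ValueError("each group needs at least one specimen")
        if self.n_points < 1 or self.n_points > 9:
            raise ValueError("n_points must be between 1 and 9 (3x3 sub-window slots)")


def default_config(
    n_healthy: int = 25, n_worn: int = 75, seed: int = 0, n_pixels: int = 128
) -> StudyConfig:
    """The study's default cohort: 25 healthy + 75 worn specimens."""
    areas = tuple(replace(a, n_pixels=n_pixels) for a in DEFAULT_AREAS)
    return StudyConfig(
        groups=(
            CohortGroup("healthy", n_healthy, HEALTHY_RA, role="healthy"),
            CohortGroup("worn", n_worn, WORN_RA, role="worn"),
        ),
        areas=areas,
        seed=seed,
    )


@dataclass(frozen=True)
class StudyReport:
    """Tabular outputs of the study (all pandas DataFrames).

    records        one row per measurement point (specimen x area x point);
    summaries      per-group RoughnessSummary;
    percent_change healthy-vs-worn change per area and parameter;
    stages         per-specimen wear stage from mean Ra at the staging area;
    modulus        per stage/layer surface, maximum and deepest modulus;
    failures       inputs that could not be processed.
    """

    records: pd.DataFrame
    summaries: Mapping[str, RoughnessSummary]
    percent_change: pd.DataFrame
    stages: pd.DataFrame
    modulus: Optional[pd.DataFrame] = None
    failures: tuple[str, ...] = ()


def _point_windows(n_pixels: int, n_points: int, rng: np.random.Generator):
    """Choose n_points non-overlapping sub-windows from a 3x3 slot grid."""
    win = n_pixels // 3
    slots = rng.choice(9, size=n_points, replace=False)
    for s in np.sort(slots):
        r, c = divmod(int(s), 3)
        yield slice(r * win, (r + 1) * win), slice(c * win, (c + 1) * win)


def run_roughness_study(config: StudyConfig, staging_area: str = "9x9") -> StudyReport:
    """Generate the cohort, measure roughness at every point, and tabulate.

    Per specimen and scan area a surface is generated at the group's
    target Ra; ``n_points`` sub-windows are levelled and measured
    (Ra/Rp/S), giving exactly n_points x n_specimens x n_areas records.
    Summaries, percent changes of the worn group against the healthy mean,
    and per-specimen wear stages (from mean Ra at ``staging_area``) follow.
    """
    seeds = np.random.SeedSequence(config.seed)
    records: list[dict] = []
    failures: list[str] = []
    for group in config.groups:
        for spec_idx in range(group.n_specimens):
            for area in config.areas:
                child = seeds.spawn(1)[0]
                rng = np.random.default_rng(child)
                ps = area.size_um * 1000.0 / area.n_pixels
                sspec = SurfaceSpec(
                    nx=area.n_pixels,
                    ny=area.n_pixels,
                    pixel_size=ps,
                    target_Ra=group.ra_for(area.label),
                    correlation_length=max(group.correlation_length_nm, 2.0 * ps),
                    seed=int(child.generate_state(1)[0] % (2**31)),
                    label=area.label,
                )
                try:
                    hmap = generate_height_map(sspec)
                except ValueError as exc:
                    msg = f"{group.name}/{spec_idx}/{area.label}: {exc}"
                    logger.warning("skipping specimen map: %s", msg)
                    failures.append(msg)
                    continue
                for point, (rows, cols) in enumerate(
                    _point_windows(area.n_pixels, config.n_points, rng)
                ):
                    sub = type(hmap)(hmap.heights[rows, cols], ps, area.label)
                    res = map_roughness(sub, level=True)
                    records.append(
                        {"group": group.name, "specimen": spec_idx,
                         "Ar": area.label, "point": point,
                         "Ra": res.Ra, "Rp": res.Rp, "S": res.S}
                    )
        logger.info("group %s: %d specimens measured", group.name, group.n_specimens)
    if not records:
        raise ValueError("empty cohort: no roughness records produced")
    rec = pd.DataFrame(records, columns=["group", "specimen", "Ar", "point", "Ra", "Rp", "S"])

    summaries = {}
    for group in config.groups:
        sub = rec[rec["group"] == group.name]
        grouped = {
            area.label: [
                RoughnessResult(r.Ra, r.Rp, r.S)
                for r in sub[sub["Ar"] == area.label].itertuples()
            ]
            for area in config.areas
        }
        summaries[group.name] = summarize_roughness(grouped)

    healthy = next((g.name for g in config.groups if g.role == "healthy"),
                   config.groups[0].name)
    pc_rows = []
    for area in config.areas:
        for param in ("Ra", "Rp", "S"):
            h = rec[(rec["group"] == healthy) & (rec["Ar"] == area.label)][param]
            healthy_mean = float(h.mean())
            for group in config.groups:
                if group.name == healthy:
                    continue
                w = rec[(rec["group"] == group.name) & (rec["Ar"] == area.label)][param]
                pc_rows.append(
                    {"Ar": area.label, "parameter": param, "worn_group": group.name,
                     "healthy_mean": healthy_mean,
                     "worn_min": float(w.min()), "worn_mean": float(w.mean()),
                     "worn_max": float(w.max()),
                     "pct_change_max": percent_change(healthy_mean, float(w.min())),
                     "pct_change_mean": percent_change(healthy_mean, float(w.mean()))}
                )
    pc = pd.DataFrame(pc_rows, columns=["Ar", "parameter", "worn_group", "healthy_mean",
                                        "worn_min", "worn_mean", "worn_max",
                                        "pct_change_max", "pct_change_mean"])

    stage_rows = []
    for (group, specimen), sub in rec[rec["Ar"] == staging_area].groupby(
        ["group", "specimen"], sort=True
    ):
        mean_ra = float(sub["Ra"].mean())
        stage_rows.append(
            {"group": group, "specimen": specimen, "mean_Ra": mean_ra,
             "stage": stage_wear(mean_ra).label}
        )
    stages = pd.DataFrame(stage_rows, columns=["group", "specimen", "mean_Ra", "stage"])
    return StudyReport(records=rec, summaries=summaries, percent_change=pc,
                       stages=stages, failures=tuple(failures))


def run_indentation_study(config: StudyConfig) -> pd.DataFrame:
    """Triplicate force curves per wear stage and layer, averaged and reduced.

    For each stage's ground-truth E(h) model and each layer, ``n_repeats``
    noisy curves are generated, converted to E(h) profiles, averaged on a
    common depth grid, and summarised as surface / maximum / deepest
    modulus.  Fewer than 3 repeats is allowed but logged as a warning.
    """
    if config.n_repeats < 3:
        logger.warning("averaging only %d repeats per site", config.n_repeats)
    seeds = np.random.SeedSequence((config.seed, 0x1D))
    rows = []
    for model in config.modulus_models:
        for layer, anchors in sorted(model.layers.items()):
            profile_fn = piecewise_modulus_profile(anchors)
            profiles = []
            for rep in range(config.n_repeats):
                child = seeds.spawn(1)[0]
                cspec = CurveSpec(
                    E_profile=profile_fn,
                    k=config.hertz.k, R=config.hertz.R, V=config.hertz.V,
                    h_max=config.h_max_nm,
                    n_contact=config.n_contact,
                    n_baseline=config.n_baseline,
                    noise_sd=config.curve_noise_sd_nm,
                    seed=int(child.generate_state(1)[0] % (2**31)),
                )
                profiles.append(compute_E_profile(generate_force_curve(cspec)))
            avg = average_profiles(profiles)
            summ = extract_modulus_summary(avg)
            rows.append(
                {"stage": model.stage, "layer": layer,
                 "E_surface_MPa": summ.E_surface, "E_max_MPa": summ.E_max,
                 "h_at_max_nm": summ.h_at_max, "E_deepest_MPa": float(avg.E[-1]),
                 "n_repeats": config.n_repeats}
            )
    return pd.DataFrame(rows, columns=["stage", "layer", "E_surface_MPa", "E_max_MPa",
                                       "h_at_max_nm", "E_deepest_MPa", "n_repeats"])


def write_report(report: StudyReport, modulus: Optional[pd.DataFrame], out_dir) -> None:
    """Write all report tables as CSV with fixed ordering and formatting."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.records.to_csv(out / "roughness_records.csv", index=False, float_format="%.4g")
    for name, summary in report.summaries.items():
        cio.write_roughness_summary_csv(summary, out / f"roughness_summary_{name}.csv")
    report.percent_change.to_csv(out / "percent_change.csv", index=False, float_format="%.4g")
    report.stages.to_csv(out / "wear_stages.csv", index=False, float_format="%.4g")
    if modulus is not None:
        modulus.to_csv(out / "modulus_summary.csv", index=False, float_format="%.4g")
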