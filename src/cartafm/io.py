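"""Reading and writing the package's file formats.

Height maps travel as plain-text matrices (one row per line, nm) with the
pixel size and label in ``#``-comment headers, or as single-channel
float32 TIFF.  Force curves and dehydration series are headered CSV, with
probe constants carried in comment lines.  All writers use fixed column
order and fixed float formatting so reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .dehydration import DehydrationSeries
from .indentation import ForceCurve, HertzParams, ModulusProfile, ModulusSummary
from .roughness import HeightMap, LacunaRegion, RoughnessSummary

FLOAT_FMT = "%.6g"


# -- height maps -----------------------------------------------------------

def write_height_map_txt(hmap: HeightMap, path) -> None:
    header = f"pixel_size_nm = {hmap.pixel_size!r}\nlabel = {hmap.label}"
    np.savetxt(path, hmap.heights, fmt=FLOAT_FMT, header=header)


def read_height_map_txt(path) -> HeightMap:
    pixel_size, label = 1.0, "custom"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").partition("=")
            key, val = key.strip(), val.strip()
            if key == "pixel_size_nm":
                pixel_size = float(val)
            elif key == "label":
                label = val
    return HeightMap(np.loadtxt(path), pixel_size, label)


def write_height_map_tiff(hmap: HeightMap, path) -> None:
    import tifffile

    tifffile.imwrite(
        path,
        hmap.heights.astype(np.float32),
        metadata={"pixel_size_nm": hmap.pixel_size, "label": hmap.label},
    )


def read_height_map_tiff(path, pixel_size: Optional[float] = None, label="custom") -> HeightMap:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        z = tif.asarray().astype(float)
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if pixel_size is None:
        pixel_size = float(meta.get("pixel_size_nm", 1.0))
    label = meta.get("label", label)
    return HeightMap(z, pixel_size, label)


# -- force curves ----------------------------------------------------------

def write_force_curve_csv(curve: ForceCurve, path) -> None:
    p = curve.params
    with open(path, "w") as fh:
        fh.write(f"# V = {p.V!r}\n# k_N_per_m = {p.k!r}\n# R_nm = {p.R!r}\n")
        fh.write(f"# z0_nm = {curve.z0!r}\n")
        fh.write("zpos_nm,zdefl_nm\n")
        for zp, zd in zip(curve.zpos, curve.zdefl):
            fh.write(f"{zp:.6g},{zd:.6g}\n")


def read_force_curve_csv(path, params: Optional[HertzParams] = None) -> ForceCurve:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = float(val)
    if params is None:
        params = HertzParams(
            V=meta.get("V", 0.5), k=meta.get("k_N_per_m", 0.08), R=meta.get("R_nm", 30.0)
        )
    df = pd.read_csv(path, comment="#")
    return ForceCurve(
        zpos=df["zpos_nm"].to_numpy(),
        zdefl=df["zdefl_nm"].to_numpy(),
        params=params,
        z0=meta.get("z0_nm", 0.0),
    )


# -- dehydration series ----------------------------------------------------

def write_dehydration_csv(series: DehydrationSeries, path) -> None:
    pd.DataFrame({"t_h": series.t, "m": series.m}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_dehydration_csv(path) -> DehydrationSeries:
    df = pd.read_csv(path, comment="#")
    return DehydrationSeries(t=df["t_h"].to_numpy(), m=df["m"].to_numpy())


# -- results ---------------------------------------------------------------

def write_roughness_summary_csv(summary: RoughnessSummary, path) -> None:
    summary.table.to_csv(path, index=False, float_format="%.4g")


def write_lacunae_csv(regions: list[LacunaRegion], path) -> None:
    rows = [
        {"id": r.id, "x_nm": r.x_nm, "y_nm": r.y_nm,
         "area_nm2": r.area_nm2, "depth_nm": r.depth_nm}
        for r in regions
    ]
    pd.DataFrame(rows, columns=["id", "x_nm", "y_nm", "area_nm2", "depth_nm"]).to_csv(
        path, index=False, float_format="%.4g"
    )


def write_modulus_profile_csv(profile: ModulusProfile, path) -> None:
    pd.DataFrame({"h_nm": profile.h, "E_MPa": profile.E}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def write_modulus_summary_json(summary: ModulusSummary, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "E_surface_MPa": round(summary.E_surface, 6),
                "E_max_MPa": round(summary.E_max, 6),
                "h_at_max_nm": round(summary.h_at_max, 6),
            },
            indent=2,
        )
        + "\n"
    )
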