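"""Construct geometry and cell-organisation statistics.

Covers the three morphological readouts of the culture time course:
per-cell acute angles to the tension axis (alignment), construct diameter
to cross-section and volume fold change (collagen compaction at fixed
anchor-to-anchor length), and centre-versus-periphery cell density.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .qpcr import mann_whitney_exact, significance_stars

#: protocol cell count per construct for orientation measurements
CELLS_PER_CONSTRUCT = 15


def axis_angle(cell_axis, construct_axis) -> float:
    """Acute angle (degrees, in [0, 90]) between a cell's major axis and
    the construct axis; orientation-insensitive (v and -v identical)."""
    v = np.asarray(cell_axis, dtype=float)
    a = np.asarray(construct_axis, dtype=float)
    nv, na = np.linalg.norm(v), np.linalg.norm(a)
    if nv == 0 or na == 0:
        raise InvalidParameterError("axis vectors must be non-zero")
    c = abs(float(np.dot(v, a)) / (nv * na))
    return math.degrees(math.acos(min(c, 1.0)))


def construct_mean_angle(orientations: pd.DataFrame, construct_id: str,
                         day: int) -> float:
    """Arithmetic mean of the per-cell acute angles of one construct
    (protocol: 15 cells per construct; fewer triggers a warning)."""
    g = orientations[(orientations["construct_id"] == construct_id)
                     & (orientations["day"] == day)]
    if g.empty:
        raise InvalidParameterError(
            f"no cells for construct {construct_id!r} at day {day}")
    if len(g) < CELLS_PER_CONSTRUCT:
        warnings.warn(
            f"construct {construct_id}: {len(g)} cells instead of "
            f"{CELLS_PER_CONSTRUCT}", stacklevel=2)
    return float(g["angle_deg"].mean())


def mean_angles_by_day(orientations: pd.DataFrame) -> pd.DataFrame:
    """Per-construct mean angles, one row per construct x day."""
    rows = [
        {"construct_id": cid, "day": day,
         "mean_angle_deg": float(g["angle_deg"].mean()), "n_cells": len(g)}
        for (cid, day), g in orientations.groupby(["construct_id", "day"])
    ]
    return pd.DataFrame(rows).sort_values(["day", "construct_id"],
                                          ignore_index=True)


def cross_sectional_area(diameter_mm: float) -> float:
    """Circular cross-section area pi d^2 / 4 (mm^2)."""
    if not (diameter_mm > 0):
        raise InvalidParameterError(
            f"diameter must be positive, got {diameter_mm}")
    return math.pi * diameter_mm ** 2 / 4.0


def volume_fold_change(d_start_mm: float, d_end_mm: float) -> float:
    """Volume reduction factor ``(d_start / d_end)^2`` for a cylindrical
    construct whose length is fixed by the anchor separation (the length
    cancels, only the cross-section shrinks)."""
    if not (d_start_mm > 0 and d_end_mm > 0):
        raise InvalidParameterError("diameters must be positive")
    return (d_start_mm / d_end_mm) ** 2


def geometry_summary(diameters: pd.DataFrame) -> pd.DataFrame:
    """Per-day diameter mean/SD and cross-sectional area, plus the volume
    fold change of each day's mean diameter relative to the first day."""
    days = sorted(diameters["day"].unique())
    d0 = diameters.loc[diameters["day"] == days[0], "diameter_mm"].mean()
    rows = []
    for day in days:
        d = diameters.loc[diameters["day"] == day, "diameter_mm"]
        mean = float(d.mean())
        rows.append({
            "day": day, "n": len(d), "diameter_mean_mm": mean,
            "diameter_sd_mm": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
            "area_mm2": cross_sectional_area(mean),
            "volume_fold_vs_first": volume_fold_change(float(d0), mean),
        })
    return pd.DataFrame(rows)


def cell_density(records: pd.DataFrame) -> pd.DataFrame:
    """Add a ``density_cells_per_mm2`` column (count / area) to
    centre/periphery count records.  Input columns: construct_id, day,
    region, cell_count, region_area_mm2."""
    df = records.copy()
    if (df["region_area_mm2"] <= 0).any():
        raise InvalidParameterError("region areas must be positive")
    df["density_cells_per_mm2"] = df["cell_count"] / df["region_area_mm2"]
    return df


def compare_regions(density: pd.DataFrame) -> pd.DataFrame:
    """Per-day Mann-Whitney comparison of centre vs periphery densities."""
    if "density_cells_per_mm2" not in density.columns:
        density = cell_density(density)
    rows = []
    for day, g in density.groupby("day"):
        centre = g.loc[g["region"] == "centre", "density_cells_per_mm2"]
        peri = g.loc[g["region"] == "periphery", "density_cells_per_mm2"]
        if centre.empty or peri.empty:
            continue
        u, p = mann_whitney_exact(centre, peri)
        rows.append({"day": day, "n_centre": len(centre),
                     "n_periphery": len(peri),
                     "centre_mean": float(centre.mean()),
                     "periphery_mean": float(peri.mean()),
                     "U": u, "p": p, "stars": significance_stars(p)})
    return pd.DataFrame(rows)
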