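"""Regional assignment, nuclear density, weighted aggregation and maps.

Measurement locations live in slice-plane um coordinates (image
convention: origin top-left, y increasing downward).  Anatomical regions
are polygons; a point on a shared boundary is assigned to the
first-listed region that covers it, which makes assignment deterministic
and the polygons effectively half-open on shared edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

__all__ = [
    "RegionGeometry",
    "assign_region",
    "NuclearDensity",
    "relative_nuclear_area",
    "slice_region_stats",
    "RegionSummary",
    "weighted_region_mean",
    "region_summaries",
    "reconstruct_map",
]

OUTSIDE = "outside"


@dataclass
class RegionGeometry:
    """Ordered list of labelled region polygons (um coordinates)."""

    regions: list[tuple[str, Polygon]]

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.regions]
        if len(labels) != len(set(labels)):
            raise ValueError("region labels must be unique")
        for lab, poly in self.regions:
            if not poly.is_valid:
                raise ValueError(f"region {lab!r} polygon is invalid")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.regions]

    def bounds(self) -> tuple[float, float, float, float]:
        b = np.array([poly.bounds for _, poly in self.regions])
        return float(b[:, 0].min()), float(b[:, 1].min()), float(b[:, 2].max()), float(b[:, 3].max())


def assign_region(point: tuple[float, float], geometry: RegionGeometry) -> str:
    """Label of the first-listed region covering the point, else "outside"."""
    p = Point(point)
    for label, poly in geometry.regions:
        if poly.covers(p):
            return label
    return OUTSIDE


@dataclass(frozen=True)
class NuclearDensity:
    """Relative nuclear area of one region from a binary nuclei mask."""

    A_nuclei: float       # um^2
    A_total: float        # um^2
    A_rel: float          # fraction in [0, 1]
    density_group: str    # "low" or "high"

    def __post_init__(self) -> None:
        if not 0.0 <= self.A_rel <= 1.0:
            raise ValueError("A_rel must lie in [0, 1]")


def relative_nuclear_area(
    mask: np.ndarray,
    region_polygon: Polygon,
    origin: tuple[float, float] = (0.0, 0.0),
    pixel_size: float = 1.0,
    group_threshold: float = 0.5,
) -> NuclearDensity:
    """A_rel = (nuclei pixels inside the polygon) / (total pixels inside).

    ``mask`` is a binary raster (rows = y, cols = x) sharing the polygon's
    coordinate frame via ``origin`` (um of pixel (0,0) corner) and
    ``pixel_size`` (um/pixel).  The density group splits at
    ``group_threshold``, which sits inside the empty interval between
    typical low (< ~0.3) and high (> ~0.7) nuclear-density tissue layers.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D raster")
    ny, nx = mask.shape
    xs = origin[0] + (np.arange(nx) + 0.5) * pixel_size
    ys = origin[1] + (np.arange(ny) + 0.5) * pixel_size
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(region_polygon, gx.ravel(), gy.ravel()).reshape(mask.shape)
    n_total = int(inside.sum())
    if n_total == 0:
        raise ValueError("polygon does not intersect the mask raster")
    n_nuc = int((mask & inside).sum())
    a_rel = n_nuc / n_total
    px_area = pixel_size**2
    return NuclearDensity(
        A_nuclei=n_nuc * px_area,
        A_total=n_total * px_area,
        A_rel=a_rel,
        density_group="low" if a_rel < group_threshold else "high",
    )


def slice_region_stats(
    moduli: pd.DataFrame,
    geometry: RegionGeometry | None = None,
    value: str = "E_storage_Pa",
    strain_center: float = 0.073,
    strain_halfwidth: float = 0.005,
    frequency: float | None = 5.62,
    freq_rtol: float = 0.01,
) -> pd.DataFrame:
    """Per-(slice, region, protocol) mean, SE and point count.

    Input is the tidy moduli table (one row per moduli point).  Only
    QC-passing points inside the strain bin (default 7.3% +- 0.5%, chosen
    to respect the small-strain regime eps < 0.08) and at the comparison
    frequency are used.  A ``region`` column is computed from ``geometry``
    when not already present.  Cells with a single point get SE = 0 and
    ``se_defined = False``; empty cells are omitted.
    """
    df = moduli.copy()
    if "region" not in df.columns:
        if geometry is None:
            raise ValueError("need either a 'region' column or a geometry")
        df["region"] = [
            assign_region((x, y), geometry) for x, y in zip(df["x_um"], df["y_um"])
        ]
    sel = df["qc_pass"].astype(bool)
    sel &= (df["strain"] - strain_center).abs() <= strain_halfwidth
    if frequency is not None:
        sel &= (df["freq_hz"] - frequency).abs() <= freq_rtol * frequency
    df = df[sel & (df["region"] != OUTSIDE)]

    rows = []
    for (slice_id, region, protocol), grp in df.groupby(["slice_id", "region", "protocol"]):
        vals = grp[value].to_numpy()
        n = vals.size
        se = float(np.std(vals, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "slice_id": slice_id,
                "region": region,
                "protocol": protocol,
                "mean_Pa": float(np.mean(vals)),
                "se_Pa": se,
                "n": n,
                "se_defined": n > 1,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegionSummary:
    """Cross-slice weighted regional summary of one modulus."""

    label: str
    weighted_mean_E: float   # Pa
    se_weighted_mean: float  # Pa
    n_points: int
    n_slices: int
    method: str              # protocol kind

    def __post_init__(self) -> None:
        if self.se_weighted_mean < 0:
            raise ValueError("SE must be non-negative")
        if self.n_points < self.n_slices:
            raise ValueError("n_points must be >= n_slices")


def weighted_region_mean(
    per_slice: list[tuple[float, float, int]],
    label: str = "",
    method: str = "",
    weighting: str = "points",
) -> RegionSummary:
    """Combine per-slice (mean, SE, n) into a weighted regional mean.

    Default weights are the per-slice point counts n_i (each measurement
    point contributes equally, so the weighted mean equals the pooled mean
    of all underlying points); ``weighting="inverse_variance"`` uses
    1/SE^2 instead.  SE of the weighted mean is
    sqrt(sum(w_i^2 SE_i^2)) / sum(w_i).
    """
    if not per_slice:
        raise ValueError("need at least one slice")
    means = np.array([m for m, _, _ in per_slice], dtype=float)
    ses = np.array([s for _, s, _ in per_slice], dtype=float)
    ns = np.array([n for _, _, n in per_slice], dtype=float)
    if weighting == "points":
        w = ns
    elif weighting == "inverse_variance":
        w = np.where(ses > 0, 1.0 / np.maximum(ses, 1e-300) ** 2, 0.0)
        if not np.any(w > 0):
            w = ns
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if w.sum() <= 0:
        raise ValueError("all-zero weights")
    mean = float(np.sum(w * means) / np.sum(w))
    se = float(math.sqrt(np.sum(w**2 * ses**2)) / np.sum(w))
    return RegionSummary(label, mean, se, int(ns.sum()), len(per_slice), method)


def region_summaries(
    slice_stats: pd.DataFrame, weighting: str = "points"
) -> pd.DataFrame:
    """Weighted regional means per (region, protocol) from per-slice stats."""
    rows = []
    for (region, protocol), grp in slice_stats.groupby(["region", "protocol"]):
        per_slice = list(zip(grp["mean_Pa"], grp["se_Pa"], grp["n"]))
        s = weighted_region_mean(per_slice, label=region, method=protocol, weighting=weighting)
        rows.append(
            {
                "region": s.label,
                "protocol": s.method,
                "weighted_mean_Pa": s.weighted_mean_E,
                "se_weighted_mean_Pa": s.se_weighted_mean,
                "n_points": s.n_points,
                "n_slices": s.n_slices,
            }
        )
    return pd.DataFrame(rows)


def reconstruct_map(
    geometry: RegionGeometry,
    summaries: pd.DataFrame,
    protocol: str | None = None,
    resolution: float = 10.0,
    extent: tuple[float, float, float, float] | None = None,
) -> tuple[np.ndarray, tuple[float, float, float, float]]:
    """Raster of regional weighted means (Pa); NaN marks unmeasured area.

    Each region polygon is filled with its weighted mean modulus;
    first-listed regions win on overlap.  Regions without a summary — and
    any point outside every polygon — stay NaN, which the plotting helper
    renders gray.  Returns (raster, extent) with extent (xmin, ymin, xmax,
    ymax) in um and ``resolution`` um per pixel.
    """
    values: dict[str, float] = {}
    df = summaries
    if protocol is not None:
        df = df[df["protocol"] == protocol]
    for _, row in df.iterrows():
        values.setdefault(row["region"], float(row["weighted_mean_Pa"]))
    unknown = set(values) - set(geometry.labels)
    if unknown:
        raise ValueError(f"summaries reference unknown regions: {sorted(unknown)}")

    if extent is None:
        extent = geometry.bounds()
    xmin, ymin, xmax, ymax = extent
    nx = max(int(math.ceil((xmax - xmin) / resolution)), 1)
    ny = max(int(math.ceil((ymax - ymin) / resolution)), 1)
    xs = xmin + (np.arange(nx) + 0.5) * resolution
    ys = ymin + (np.arange(ny) + 0.5) * resolution
    gx, gy = np.meshgrid(xs, ys)
    raster = np.full((ny, nx), np.nan)
    unset = np.ones((ny, nx), dtype=bool)
    for label, poly in geometry.regions:
        inside = shapely.contains_xy(poly, gx.ravel(), gy.ravel()).reshape(ny, nx)
        fill = inside & unset
        if label in values:
            raster[fill] = values[label]
        unset &= ~inside
    return raster, extent
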