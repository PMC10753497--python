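"""Quantification of labeled nuclei point clouds.

Implements the spheroid-invasion readouts used on stained cross-sectioned
cultures, operating on nucleus centre points instead of pixels: shell-binned
counts in expanding ROIs, maximum migration distance (mean of the six
furthest cells), the sectioning/imaging-depth sampling correction, covered
area, cell density, invasion-zone thickness and per-cell signal.

A nucleus table is a pandas DataFrame with columns ``x_um, y_um, z_um,
compartment`` (one of core / interface / bulk_top / bulk_bottom) and an
optional ``signal`` column. Coordinates are um relative to the spheroid
centre unless a ``center`` is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import closing, disk

COMPARTMENTS = ("core", "interface", "bulk_top", "bulk_bottom")
#: Compartments measured in the top view (planar rim distance).
PLANAR_COMPARTMENTS = frozenset({"core", "interface"})

__all__ = [
    "COMPARTMENTS",
    "ShellCounts",
    "read_nucleus_table",
    "write_nucleus_table",
    "rim_distances",
    "shell_counts",
    "max_migration_distance",
    "correction_factor",
    "sampling_correction",
    "covered_area",
    "cell_density",
    "invasion_zone_thickness",
    "signal_per_cell",
]


@dataclass
class ShellCounts:
    """Integer counts per half-open shell [k*w, (k+1)*w) outside the rim.

    ``rim_count`` reports points at negative rim distance (inside the rim)
    rather than silently dropping them.
    """

    counts: np.ndarray
    rim_count: int
    bin_width: float

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _validate_table(points: pd.DataFrame) -> None:
    for col in ("x_um", "y_um", "z_um", "compartment"):
        if col not in points.columns:
            raise ValueError(f"nucleus table lacks column {col!r}")
    coords = points[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("nucleus coordinates must be finite")
    bad = set(points["compartment"]) - set(COMPARTMENTS)
    if bad:
        raise ValueError(f"unknown compartment labels: {sorted(bad)}")


def read_nucleus_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(path, sep=sep)
    _validate_table(table)
    return table


def write_nucleus_table(points: pd.DataFrame, path) -> None:
    _validate_table(points)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    points.to_csv(path, sep=sep, index=False)


def rim_distances(
    points: pd.DataFrame,
    rim_radius: float,
    center=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Distance of each nucleus from the spheroid rim, um.

    Planar (xy) distance for core/interface nuclei (top-view measurement),
    3D distance for the bulk compartments (side-view measurement).
    """
    _validate_table(points)
    dx = points["x_um"].to_numpy(float) - center[0]
    dy = points["y_um"].to_numpy(float) - center[1]
    dz = points["z_um"].to_numpy(float) - center[2]
    planar = np.sqrt(dx * dx + dy * dy)
    spatial = np.sqrt(dx * dx + dy * dy + dz * dz)
    is_planar = points["compartment"].isin(PLANAR_COMPARTMENTS).to_numpy()
    return np.where(is_planar, planar, spatial) - rim_radius


def shell_counts(
    points: pd.DataFrame,
    rim_radius: float,
    bin_width: float,
    compartments=("interface", "bulk_top", "bulk_bottom"),
    center=(0.0, 0.0, 0.0),
) -> dict[str, ShellCounts]:
    """Per-compartment counts in expanding shells outside the rim.

    A nucleus falls in shell k iff its rim distance lies in
    ``[k * bin_width, (k+1) * bin_width)`` — a point exactly on a bin edge
    belongs to the outer shell.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d_all = rim_distances(points, rim_radius, center)
    out: dict[str, ShellCounts] = {}
    for comp in compartments:
        if comp == "core":
            raise ValueError("core nuclei are not shell-binned")
        d = d_all[(points["compartment"] == comp).to_numpy()]
        rim_count = int((d < 0).sum())
        d = d[d >= 0]
        k = np.floor(d / bin_width).astype(int)
        n_shells = int(k.max()) + 1 if k.size else 0
        counts = np.bincount(k, minlength=n_shells)
        out[comp] = ShellCounts(counts=counts, rim_count=rim_count, bin_width=bin_width)
    return out


def max_migration_distance(
    points: pd.DataFrame,
    rim_radius: float,
    compartments=("interface", "bulk_top", "bulk_bottom"),
    center=(0.0, 0.0, 0.0),
) -> float:
    """Mean rim distance of the six furthest non-core nuclei, um.

    With fewer than six nuclei, the mean of all of them; with none, NaN.
    """
    sel = points["compartment"].isin(set(compartments) - {"core"}).to_numpy()
    d = rim_distances(points, rim_radius, center)[sel]
    if d.size == 0:
        return float("nan")
    top = np.sort(d)[-6:]
    return float(top.mean())


def correction_factor(
    half_fraction: float,
    depth_imaged: float,
    depth_total: float,
    round_depth: bool = True,
) -> float:
    """Multiplicative count correction for sectioning and imaging depth.

    factor = 1 / (half_fraction * depth_fraction), with the depth fraction
    rounded to the nearest 0.05 by default (185/230 -> 0.80, so the canonical
    half-spheroid factor is exactly 2.5). ``round_depth=False`` uses the raw
    ratio.
    """
    if not 0 < half_fraction <= 1:
        raise ValueError("half_fraction must lie in (0, 1]")
    if depth_imaged <= 0 or depth_total <= 0 or depth_imaged > depth_total:
        raise ValueError("require 0 < depth_imaged <= depth_total")
    frac = depth_imaged / depth_total
    if round_depth:
        frac = round(frac / 0.05) * 0.05
    return 1.0 / (half_fraction * frac)


def sampling_correction(
    raw_count: float,
    half_fraction: float,
    depth_imaged: float,
    depth_total: float,
    round_depth: bool = True,
) -> float:
    """Scale a raw count up by the sectioning/depth correction factor."""
    if raw_count < 0:
        raise ValueError("raw_count must be non-negative")
    return raw_count * correction_factor(
        half_fraction, depth_imaged, depth_total, round_depth
    )


def covered_area(
    points: pd.DataFrame,
    pixel_size: float = 2.0,
    closing_radius: float = 20.0,
    nucleus_radius: float = 5.0,
) -> float:
    """Cell-populated area of the xy footprint, mm^2.

    Each nucleus is rasterized as a disc of ``nucleus_radius``; gaps up to
    ``closing_radius`` are bridged by a morphological closing and interior
    holes are filled. Deterministic for fixed inputs; empty input gives 0.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if len(points) == 0:
        return 0.0
    _validate_table(points)
    x = points["x_um"].to_numpy(float)
    y = points["y_um"].to_numpy(float)
    r_close = max(1, int(round(closing_radius / pixel_size)))
    r_nuc = max(1, int(round(nucleus_radius / pixel_size)))
    margin = r_close + r_nuc + 1
    ix = np.round((x - x.min()) / pixel_size).astype(int) + margin
    iy = np.round((y - y.min()) / pixel_size).astype(int) + margin
    img = np.zeros((ix.max() + margin + 1, iy.max() + margin + 1), dtype=bool)
    img[ix, iy] = True
    img = ndimage.binary_dilation(img, structure=disk(r_nuc))
    img = closing(img, disk(r_close))
    img = ndimage.binary_fill_holes(img)
    return float(img.sum()) * pixel_size**2 / 1e6


def cell_density(count: float, area_mm2: float) -> float:
    """Cells per mm^2."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / area_mm2


def invasion_zone_thickness(
    points: pd.DataFrame,
    rim_radius: float,
    rim_distances_um,
    window: float,
    nucleus_diameter: float = 10.0,
    center=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """z-extent of the cell layer at given distances from the rim, um.

    At each queried rim distance the nuclei whose planar rim distance lies
    within +/- window/2 are collected; thickness is max(z) - min(z) plus one
    nominal nucleus diameter (so a monolayer reads one diameter). NaN where
    the window is empty.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    _validate_table(points)
    dx = points["x_um"].to_numpy(float) - center[0]
    dy = points["y_um"].to_numpy(float) - center[1]
    z = points["z_um"].to_numpy(float)
    d = np.sqrt(dx * dx + dy * dy) - rim_radius
    out = []
    for q in np.atleast_1d(rim_distances_um):
        sel = np.abs(d - q) <= window / 2
        if not sel.any():
            out.append(float("nan"))
        else:
            out.append(float(z[sel].max() - z[sel].min() + nucleus_diameter))
    return np.asarray(out)


def signal_per_cell(total_signal: float, background: float, n_nuclei: int) -> float:
    """Background-subtracted signal divided by nucleus count, floored at 0."""
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    return max(0.0, total_signal - background) / n_nuclei
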