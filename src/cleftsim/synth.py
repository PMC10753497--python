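"""Seeded generator of synthetic spheroid-invasion nuclei point clouds.

Emulates the invasion patterns of MV3 melanoma spheroids embedded between
two collagen lattices: a dense spherical core, a sheet of interface cells
jammed in the cleft (radial density decaying out to ~400 um), and collective
strand-like emigration into the top and bottom 3D gels (decaying over
~150-175 um, with the printed ~350:150 top:bottom asymmetry). The bulk
compartments are subjected to the cross-section measurement geometry —
half-spheroid sectioning and limited imaging depth — while the interface is
"measured" from an untruncated top view, as in the experiment. Every draw is
reproducible from the seed, and a ground-truth table of per-shell counts is
emitted alongside the points.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PatternSpec", "GroundTruth", "generate_pattern", "generate_signal_field"]


@dataclass(frozen=True)
class PatternSpec:
    """Generation parameters; defaults reproduce the printed study pattern."""

    seed: int = 0
    spheroid_radius: float = 150.0  # um
    n_core: int = 1000
    n_interface: int = 2000
    interface_max_dist: float = 400.0  # um, truncation of interface decay
    interface_decay: float = 150.0  # um, exponential decay length
    n_bulk_top: int = 350
    n_bulk_bottom: int = 150
    bulk_decay: float = 175.0  # um, exponential decay length in the gels
    bulk_max_dist_top: float = 175.0  # um
    bulk_max_dist_bottom: float = 150.0  # um
    nucleus_diameter: float = 10.0  # um
    cleft_z_band: float = 20.0  # um, full z-extent of the jammed sheet
    depth_imaged: float = 185.0  # um
    depth_total: float = 230.0  # um
    half_section: bool = True
    monolayer: bool = False  # surface-assay mode: interface is one z layer
    n_strands_min: int = 6
    n_strands_max: int = 12
    strand_jitter: float = 12.0  # um, gaussian scatter around strand axes
    interface_bin: float = 50.0  # um, ROI expansion step in the top view
    bulk_bin: float = 25.0  # um, ROI expansion step in the side view

    def __post_init__(self) -> None:
        for name in ("n_core", "n_interface", "n_bulk_top", "n_bulk_bottom"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "spheroid_radius",
            "interface_max_dist",
            "interface_decay",
            "bulk_decay",
            "bulk_max_dist_top",
            "bulk_max_dist_bottom",
            "nucleus_diameter",
            "interface_bin",
            "bulk_bin",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.depth_imaged <= self.depth_total:
            raise ValueError("require 0 < depth_imaged <= depth_total")
        if self.interface_max_dist < self.nucleus_diameter:
            raise ValueError("interface annulus thinner than a nucleus")
        if not 1 <= self.n_strands_min <= self.n_strands_max:
            raise ValueError("require 1 <= n_strands_min <= n_strands_max")

    def replace(self, **changes) -> "PatternSpec":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Bookkeeping of what the generator placed, before and after truncation.

    ``totals`` count emitted nuclei per compartment (shell counts plus the
    inside-rim bucket); ``totals_raw`` count before sectioning/depth
    truncation.

    Shell counts use the same half-open binning convention as the
    quantification (interface: planar rim distance, bin ``interface_bin``;
    bulk: 3D rim distance, bin ``bulk_bin``).
    """

    shell_counts: dict = field(default_factory=dict)  # emitted points
    shell_counts_raw: dict = field(default_factory=dict)  # pre-truncation
    rim_counts: dict = field(default_factory=dict)
    totals: dict = field(default_factory=dict)
    totals_raw: dict = field(default_factory=dict)
    max_distances: dict = field(default_factory=dict)  # mean of six furthest
    generated_area_mm2: float = 0.0
    per_cell_signal: float | None = None
    bin_widths: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("shell_counts", "shell_counts_raw"):
            d[key] = {k: np.asarray(v).tolist() for k, v in d[key].items()}
        return d


def _trunc_exp(rng: np.random.Generator, scale: float, cutoff: float, n: int):
    """Exponential(scale) truncated to [0, cutoff], via inverse CDF."""
    u = rng.random(n)
    return -scale * np.log1p(-u * (1.0 - np.exp(-cutoff / scale)))


def _bin_counts(distances: np.ndarray, width: float):
    """(shell counts, inside-rim count) with the half-open [kw, (k+1)w) rule."""
    rim = int((distances < 0).sum())
    d = distances[distances >= 0]
    k = np.floor(d / width).astype(int)
    n = int(k.max()) + 1 if k.size else 0
    return np.bincount(k, minlength=n), rim


def _six_furthest(distances: np.ndarray) -> float:
    if distances.size == 0:
        return float("nan")
    return float(np.sort(distances)[-6:].mean())


def generate_pattern(spec: PatternSpec) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a labeled nuclei point cloud and its ground-truth table.

    Coordinates are um relative to the spheroid centre; the cleft plane is
    z = 0. Bulk nuclei lie on a few jittered radial strand axes per gel;
    their observed subset reflects half-sectioning (y >= 0 kept) and imaging
    depth (each bulk nucleus carries an independent position along the
    imaging axis, uniform over ``depth_total``, and survives if it lies
    within ``depth_imaged`` — the optical geometry itself is not modeled).
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.spheroid_radius
    frames = []
    truth = GroundTruth(
        bin_widths={
            "interface": spec.interface_bin,
            "bulk_top": spec.bulk_bin,
            "bulk_bottom": spec.bulk_bin,
        }
    )

    # -- core: uniform in the sphere
    if spec.n_core:
        u = rng.normal(size=(spec.n_core, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = R * rng.random(spec.n_core) ** (1 / 3)
        frames.append(
            pd.DataFrame(
                {
                    "x_um": u[:, 0] * r,
                    "y_um": u[:, 1] * r,
                    "z_um": u[:, 2] * r,
                    "compartment": "core",
                }
            )
        )

    # -- interface sheet: annulus in the cleft z-band, decaying radially
    if spec.n_interface:
        d = _trunc_exp(rng, spec.interface_decay, spec.interface_max_dist, spec.n_interface)
        theta = rng.uniform(0, 2 * np.pi, spec.n_interface)
        rad = R + d
        z = (
            np.zeros(spec.n_interface)
            if spec.monolayer
            else rng.uniform(-spec.cleft_z_band / 2, spec.cleft_z_band / 2, spec.n_interface)
        )
        frames.append(
            pd.DataFrame(
                {
                    "x_um": rad * np.cos(theta),
                    "y_um": rad * np.sin(theta),
                    "z_um": z,
                    "compartment": "interface",
                }
            )
        )
        counts, rim = _bin_counts(d, spec.interface_bin)
        truth.shell_counts["interface"] = counts
        truth.shell_counts_raw["interface"] = counts.copy()
        truth.rim_counts["interface"] = rim
        truth.totals["interface"] = int(counts.sum())
        truth.totals_raw["interface"] = int(counts.sum())
        truth.max_distances["interface"] = _six_furthest(d)
        truth.generated_area_mm2 = float(np.pi * (R + d.max()) ** 2 / 1e6)

    # -- bulk strands, per gel
    for comp, n_pts, cutoff, zsign in (
        ("bulk_top", spec.n_bulk_top, spec.bulk_max_dist_top, +1),
        ("bulk_bottom", spec.n_bulk_bottom, spec.bulk_max_dist_bottom, -1),
    ):
        if n_pts == 0:
            for store in (truth.shell_counts, truth.shell_counts_raw):
                store[comp] = np.zeros(0, dtype=int)
            truth.rim_counts[comp] = 0
            truth.totals[comp] = 0
            truth.totals_raw[comp] = 0
            truth.max_distances[comp] = float("nan")
            continue
        # An even number of azimuthally equispaced strand axes (random common
        # offset, random elevation into the gel): any section plane through
        # the centre then splits the strands — and, with cells allocated to
        # strands round-robin, the cells — into equal halves, so the
        # half-spheroid sampling correction stays unbiased and low-variance.
        lo = (spec.n_strands_min + 1) // 2
        hi = spec.n_strands_max // 2
        n_strands = 2 * int(rng.integers(lo, hi + 1))
        phi = rng.uniform(0, 2 * np.pi) + np.arange(n_strands) * 2 * np.pi / n_strands
        elev = rng.uniform(0.35, 0.95, n_strands)  # |z| component into the gel
        horiz = np.sqrt(1.0 - elev**2)
        axes = np.column_stack(
            [horiz * np.cos(phi), horiz * np.sin(phi), zsign * elev]
        )
        which = np.arange(n_pts) % n_strands
        s = _trunc_exp(rng, spec.bulk_decay, cutoff, n_pts)
        pos = (R + s)[:, None] * axes[which]
        pos += rng.normal(scale=spec.strand_jitter, size=(n_pts, 3))
        d3 = np.linalg.norm(pos, axis=1) - R

        counts_raw, rim_raw = _bin_counts(d3, spec.bulk_bin)
        truth.shell_counts_raw[comp] = counts_raw
        truth.totals_raw[comp] = n_pts  # shells plus inside-rim stragglers

        keep = np.ones(n_pts, dtype=bool)
        if spec.half_section:
            keep &= pos[:, 1] >= 0
        depth_pos = rng.uniform(0, spec.depth_total, n_pts)
        keep &= depth_pos <= spec.depth_imaged

        pos = pos[keep]
        d3 = d3[keep]
        counts, rim = _bin_counts(d3, spec.bulk_bin)
        truth.shell_counts[comp] = counts
        truth.rim_counts[comp] = rim
        truth.totals[comp] = int(counts.sum()) + rim
        truth.max_distances[comp] = _six_furthest(d3[d3 >= 0])
        frames.append(
            pd.DataFrame(
                {
                    "x_um": pos[:, 0],
                    "y_um": pos[:, 1],
                    "z_um": pos[:, 2],
                    "compartment": comp,
                }
            )
        )

    if frames:
        table = pd.concat(frames, ignore_index=True)
    else:
        table = pd.DataFrame(
            {"x_um": [], "y_um": [], "z_um": [], "compartment": []}
        )
    if "interface" not in truth.shell_counts:
        truth.shell_counts["interface"] = np.zeros(0, dtype=int)
        truth.shell_counts_raw["interface"] = np.zeros(0, dtype=int)
        truth.rim_counts["interface"] = 0
        truth.totals["interface"] = 0
        truth.totals_raw["interface"] = 0
        truth.max_distances["interface"] = float("nan")
    return table, truth


def generate_signal_field(
    table: pd.DataFrame,
    per_cell_signal: float,
    background: float,
    reduction_factor: float = 0.0,
) -> pd.Series:
    """Per-nucleus collagenolysis signal (e.g. the Col1-3/4 cleavage epitope).

    Control nuclei carry ``background + per_cell_signal``; MMP-inhibited mode
    scales the per-cell component by ``1 - reduction_factor`` (a reduction of
    0.9 leaves 10% of the control per-cell signal).
    """
    if not 0.0 <= reduction_factor <= 1.0:
        raise ValueError("reduction_factor must lie in [0, 1]")
    value = background + per_cell_signal * (1.0 - reduction_factor)
    return pd.Series(np.full(len(table), value), index=table.index, name="signal")
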