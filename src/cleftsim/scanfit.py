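"""Parameter scan of the cellular automaton and degradation-rate fitting.

The scan varies the bulk ECM density and the degradation constant over a
grid, reducing each 100-step run to its invasion summary. Fitting matches
each assay condition's printed targets — the fraction of emigrating cells in
the interface (0.80 high-density, 0.60 low-density) and the relative
interface cell mass (low = 0.4 x high) — by grid search over the degradation
constant, yielding the ratio of degradation rates between the high- and
low-density collagen conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import summarize_invasion
from .model import run
from .params import ModelParams, high_density_params, low_density_params

__all__ = [
    "DEFAULT_DELTA_GRID",
    "DEFAULT_ECM3D_GRID",
    "ECM_INT_SCAN",
    "ScanError",
    "ConditionFit",
    "FitResult",
    "scan",
    "fit_condition",
    "degradation_ratio",
    "fit_interface_conditions",
    "predict_mmp_inhibition",
    "plot_scan_heatmap",
]

#: Degradation-constant grid: 0 to 0.5 in steps of 0.005.
DEFAULT_DELTA_GRID = np.round(np.linspace(0.0, 0.5, 101), 10)
#: Bulk-density grid for the landscape scan (cleft fixed at the mean value
#: of the two assay conditions, 0.18, so the grid starts above it).
DEFAULT_ECM3D_GRID = np.round(np.arange(0.20, 0.9001, 0.05), 10)
#: Cleft density used for the landscape scan: mean of 0.10 and 0.26.
ECM_INT_SCAN = 0.18


class ScanError(RuntimeError):
    """A simulation failed at an identified grid point."""


def _single_summary(params: ModelParams):
    state = run(params).final
    return summarize_invasion(state, params)


def scan(
    params_base: ModelParams,
    ecm_3d_values,
    delta_values,
) -> pd.DataFrame:
    """One 100-step run per (ecm_3d, delta) grid point.

    Rows are independent and deterministic: the table is identical
    regardless of evaluation order.
    """
    ecm_3d_values = np.atleast_1d(np.asarray(ecm_3d_values, dtype=float))
    delta_values = np.atleast_1d(np.asarray(delta_values, dtype=float))
    if ecm_3d_values.size == 0 or delta_values.size == 0:
        raise ValueError("scan grids must be non-empty")
    rows = []
    for e in ecm_3d_values:
        for d in delta_values:
            try:
                p = params_base.replace(ecm_3d=float(e), delta=float(d))
                s = _single_summary(p)
            except Exception as err:  # noqa: BLE001 - re-raise with grid point
                raise ScanError(f"scan failed at ecm_3d={e}, delta={d}: {err}") from err
            rows.append(
                {
                    "ecm_int": p.ecm_int,
                    "ecm_3d": float(e),
                    "delta": float(d),
                    "interface_mass": s.interface_mass,
                    "bulk_mass": s.bulk_mass,
                    "interface_fraction": s.interface_fraction,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ConditionFit:
    """Best-fit degradation constant for one assay condition."""

    delta: float
    objective: float
    interface_fraction: float
    interface_mass: float
    targets: dict = field(default_factory=dict)


@dataclass
class FitResult:
    """Paired condition fits and their degradation-rate ratio."""

    high: ConditionFit
    low: ConditionFit
    ratio: float
    scan_high: pd.DataFrame = field(repr=False, default=None)
    scan_low: pd.DataFrame = field(repr=False, default=None)


def fit_condition(
    scan_table: pd.DataFrame,
    ecm_3d: float,
    target_fraction: float,
    target_mass: float | None = None,
    mass_ref: float | None = None,
    weights: tuple[float, float] = (1.0, 1.0),
) -> ConditionFit:
    """Grid-search the degradation constant against the condition's targets.

    Objective: ``w0 * (fraction - target_fraction)**2`` plus, if a mass
    target is given, ``w1 * (interface_mass / mass_ref - target_mass)**2``.
    Rows with undefined fraction (no emigration) are excluded; ties break
    toward the smaller delta.
    """
    rows = scan_table[np.isclose(scan_table["ecm_3d"], ecm_3d)]
    rows = rows[np.isfinite(rows["interface_fraction"])]
    if rows.empty:
        raise ValueError(f"scan table has no usable rows at ecm_3d={ecm_3d}")
    obj = weights[0] * (rows["interface_fraction"] - target_fraction) ** 2
    targets = {"fraction": target_fraction}
    if target_mass is not None:
        if mass_ref is None or mass_ref <= 0:
            raise ValueError("a positive mass_ref is required with target_mass")
        obj = obj + weights[1] * (rows["interface_mass"] / mass_ref - target_mass) ** 2
        targets.update({"mass": target_mass, "mass_ref": mass_ref})
    order = rows.assign(objective=obj).sort_values(["objective", "delta"])
    best = order.iloc[0]
    return ConditionFit(
        delta=float(best["delta"]),
        objective=float(best["objective"]),
        interface_fraction=float(best["interface_fraction"]),
        interface_mass=float(best["interface_mass"]),
        targets=targets,
    )


def degradation_ratio(delta_high: float, delta_low: float) -> float:
    """delta_high / delta_low."""
    if delta_high < 0 or delta_low <= 0:
        raise ValueError("degradation rates must be positive to form a ratio")
    return delta_high / delta_low


def fit_interface_conditions(
    delta_values=None,
    params_high: ModelParams | None = None,
    params_low: ModelParams | None = None,
    frac_high: float = 0.80,
    frac_low: float = 0.60,
    mass_ratio_low: float = 0.40,
    weights: tuple[float, float] = (1.0, 1.0),
) -> FitResult:
    """Full fitting pipeline for the two assay conditions.

    The high-density condition is fitted on its interface-fraction target
    and sets the absolute interface-mass scale; the low-density condition is
    then fitted on its fraction target plus the relative mass target
    (low interface mass = ``mass_ratio_low`` x high).
    """
    if delta_values is None:
        delta_values = DEFAULT_DELTA_GRID
    params_high = params_high or high_density_params()
    params_low = params_low or low_density_params()
    scan_high = scan(params_high, [params_high.ecm_3d], delta_values)
    scan_low = scan(params_low, [params_low.ecm_3d], delta_values)
    fit_high = fit_condition(scan_high, params_high.ecm_3d, frac_high, weights=weights)
    fit_low = fit_condition(
        scan_low,
        params_low.ecm_3d,
        frac_low,
        target_mass=mass_ratio_low,
        mass_ref=fit_high.interface_mass,
        weights=weights,
    )
    ratio = degradation_ratio(fit_high.delta, fit_low.delta)
    return FitResult(high=fit_high, low=fit_low, ratio=ratio,
                     scan_high=scan_high, scan_low=scan_low)


def predict_mmp_inhibition(params: ModelParams, fitted_delta: float) -> dict:
    """Paired run summaries with the fitted degradation rate and with delta=0.

    delta=0 models broad-spectrum MMP inhibition (no collagenolysis); the
    high-density prediction is that emigration shifts almost completely to
    interface-guided migration while bulk invasion collapses.
    """
    out = {}
    for label, d in (("fitted", fitted_delta), ("inhibited", 0.0)):
        s = _single_summary(params.replace(delta=float(d)))
        out[label] = {
            "delta": float(d),
            "interface_mass": s.interface_mass,
            "bulk_mass": s.bulk_mass,
            "interface_fraction": s.interface_fraction,
        }
    return out


def plot_scan_heatmap(scan_table: pd.DataFrame, path=None):
    """Interface-fraction landscape over (ecm_3d, delta) as a heatmap figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = scan_table.pivot_table(
        index="delta", columns="ecm_3d", values="interface_fraction"
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.pcolormesh(
        pivot.columns.to_numpy(), pivot.index.to_numpy(), pivot.to_numpy(),
        shading="nearest", vmin=0, vmax=1, cmap="viridis",
    )
    ax.set_xlabel("bulk ECM density")
    ax.set_ylabel("degradation constant")
    fig.colorbar(im, ax=ax, label="interface fraction of emigrated mass")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
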