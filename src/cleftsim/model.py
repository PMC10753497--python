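"""Deterministic cellular automaton of spheroid invasion into a collagen cleft.

State: two scalar fields on a 3D voxel lattice — cell density ``c`` and ECM
density ``m``, both in [0, 1]. Each timestep applies, in order,

1. proliferation  — ``c <- min(1, c * 2**(dt/t_d))``;
2. ECM degradation — ``m <- max(0, m * (1 - delta * L))`` with ``L`` the mean
   cell density over the voxel and its Von Neumann neighbours;
3. migration — pairwise cell-density fluxes into face neighbours, weighted by
   a two-regime response to the target voxel's ECM density (linear up to
   ``ecm_crit``, exponential decay above it), limited by available space, and
   amplified in-plane inside the cleft slab (interface guidance).

Boundaries are no-flux (truncated neighbourhoods); with proliferation off the
migration rule conserves total cell mass exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = [
    "SimulationState",
    "RunResult",
    "init_state",
    "migration_response",
    "step_proliferation",
    "step_degradation",
    "step_migration",
    "step",
    "run",
    "cleft_mask",
    "sphere_mask",
    "planar_rim_distance_field",
    "radial_rim_distance_field",
]

# Face-neighbour directions (axis, sign); order is part of the definition so
# that the vectorized and scalar-reference implementations agree bit-exactly.
_DIRS = ((0, +1), (0, -1), (1, +1), (1, -1), (2, +1), (2, -1))


@dataclass
class SimulationState:
    """Paired 3D fields of cell and ECM density plus the elapsed step count."""

    cells: np.ndarray
    ecm: np.ndarray
    step: int = 0

    def __post_init__(self) -> None:
        if self.cells.shape != self.ecm.shape:
            raise ValueError("cells and ecm must have identical shape")
        if self.step < 0:
            raise ValueError("step must be non-negative")

    def copy(self) -> "SimulationState":
        return SimulationState(self.cells.copy(), self.ecm.copy(), self.step)

    @property
    def total_cell_mass(self) -> float:
        return float(self.cells.sum())

    @property
    def total_ecm_mass(self) -> float:
        return float(self.ecm.sum())


@dataclass
class RunResult:
    final: SimulationState
    snapshots: list


# ---------------------------------------------------------------- geometry

def _center_um(params: ModelParams) -> tuple[float, float, float]:
    """Lattice centre in um; voxel centres sit at ``index * dx``."""
    return (
        (params.nx - 1) / 2 * params.dx,
        (params.ny - 1) / 2 * params.dx,
        (params.nz - 1) / 2 * params.dx,
    )


def _coord_grids(params: ModelParams):
    cx, cy, cz = _center_um(params)
    x = np.arange(params.nx)[:, None, None] * params.dx - cx
    y = np.arange(params.ny)[None, :, None] * params.dx - cy
    z = np.arange(params.nz)[None, None, :] * params.dx - cz
    return x, y, z


def cleft_mask(params: ModelParams) -> np.ndarray:
    """Boolean mask of the cleft slab (mid-z +/- cleft_half_thickness layers)."""
    mid = (params.nz - 1) // 2
    h = params.cleft_half_thickness
    mask = np.zeros((params.nx, params.ny, params.nz), dtype=bool)
    mask[:, :, mid - h : mid + h + 1] = True
    return mask


def sphere_mask(params: ModelParams) -> np.ndarray:
    """Voxels whose centre lies within ``spheroid_radius`` of the lattice centre."""
    if params.spheroid_radius == 0:
        return np.zeros((params.nx, params.ny, params.nz), dtype=bool)
    x, y, z = _coord_grids(params)
    return x * x + y * y + z * z <= params.spheroid_radius**2


def planar_rim_distance_field(params: ModelParams) -> np.ndarray:
    """Per-voxel xy distance from the lattice axis minus the spheroid radius, um."""
    x, y, _ = _coord_grids(params)
    d = np.sqrt(x * x + y * y) - params.spheroid_radius
    return np.broadcast_to(d, (params.nx, params.ny, params.nz)).copy()


def radial_rim_distance_field(params: ModelParams) -> np.ndarray:
    """Per-voxel 3D distance from the lattice centre minus the spheroid radius, um."""
    x, y, z = _coord_grids(params)
    return np.sqrt(x * x + y * y + z * z) - params.spheroid_radius


def _shift(a: np.ndarray, axis: int, sign: int) -> np.ndarray:
    """Zero-filled shift: result[i] = a[i + sign] along ``axis``."""
    out = np.zeros_like(a)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if sign > 0:
        dst[axis] = slice(0, -1)
        src[axis] = slice(1, None)
    else:
        dst[axis] = slice(1, None)
        src[axis] = slice(0, -1)
    out[tuple(dst)] = a[tuple(src)]
    return out


def _neighbor_count(shape: tuple[int, int, int]) -> np.ndarray:
    """Number of face neighbours per voxel (6 in the interior, fewer at faces)."""
    ones = np.ones(shape)
    n = np.zeros(shape)
    for axis, sign in _DIRS:
        n += _shift(ones, axis, sign)
    return n


# Per-geometry arrays reused across steps (keyed by the fields they depend on).
_GEOM_CACHE: dict = {}


def _geometry(params: ModelParams):
    key = (
        params.nx, params.ny, params.nz,
        params.cleft_half_thickness, params.guidance_g,
    )
    cached = _GEOM_CACHE.get(key)
    if cached is None:
        shape = (params.nx, params.ny, params.nz)
        slab = cleft_mask(params)
        cached = {
            "nbr_count": _neighbor_count(shape),
            "g_inplane": np.where(slab, params.guidance_g, 1.0),
            "ones": np.ones(shape),
        }
        _GEOM_CACHE.clear()  # keep at most one geometry resident
        _GEOM_CACHE[key] = cached
    return cached


# ---------------------------------------------------------------- operations

def init_state(params: ModelParams) -> SimulationState:
    """Initial condition: low-ECM cleft slab in a high-ECM lattice, with a
    fully cell-occupied spheroid centred on the cleft plane.

    The spheroid volume holds no bulk matrix (cells replace it), but the
    pre-existing cleft runs through the spheroid: slab voxels keep
    ``ecm_int`` even inside the sphere. Because migration requires a
    substrate (f(0) = 0), this through-going channel is what lets the
    spheroid interior feed the interface sheet, as observed in vitro.
    """
    slab = cleft_mask(params)
    if not slab.any():
        raise ValueError("cleft slab contains no voxels")
    sph = sphere_mask(params)
    if params.spheroid_radius > 0 and not sph.any():
        raise ValueError("spheroid sphere contains no voxels")

    ecm = np.full((params.nx, params.ny, params.nz), params.ecm_3d, dtype=float)
    cells = np.zeros_like(ecm)
    cells[sph] = 1.0
    ecm[sph] = 0.0
    ecm[slab] = params.ecm_int
    return SimulationState(cells=cells, ecm=ecm, step=0)


def migration_response(m, params: ModelParams):
    """Flux response f(m) of migration to the target voxel's ECM density.

    Two regimes: linear increase ``m / ecm_crit`` up to the critical density
    (where f = 1, the global maximum), exponential decay
    ``exp(-decay_k * (m - ecm_crit))`` above it. Continuous at ``ecm_crit``.
    """
    arr = np.asarray(m, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("ECM density must lie in [0, 1]")
    out = np.where(
        arr <= params.ecm_crit,
        arr / params.ecm_crit,
        np.exp(-params.decay_k * (arr - params.ecm_crit)),
    )
    if np.isscalar(m) or np.ndim(m) == 0:
        return float(out)
    return out


def step_proliferation(state: SimulationState, params: ModelParams) -> SimulationState:
    """Exponential growth at the doubling time, capped at carrying capacity 1."""
    cells = np.minimum(1.0, state.cells * 2.0 ** (params.dt / params.t_d))
    return SimulationState(cells, state.ecm.copy(), state.step)


def step_degradation(state: SimulationState, params: ModelParams) -> SimulationState:
    """Proportional ECM decay, linear in the local-neighbourhood cell density."""
    c = state.cells
    # accumulate opposite neighbours pairwise so mirror symmetry is exact
    nbr = np.zeros_like(c)
    for axis in range(3):
        nbr += _shift(c, axis, +1) + _shift(c, axis, -1)
    load = (c + nbr) / (1.0 + _geometry(params)["nbr_count"])
    ecm = np.maximum(0.0, state.ecm * (1.0 - params.delta * load))
    return SimulationState(c.copy(), ecm, state.step)


def step_migration(state: SimulationState, params: ModelParams) -> SimulationState:
    """Simultaneous pairwise fluxes c_i -> neighbours, from the pre-step field.

    J_{i->j} = mu * c_i * f(m_j) * (1 - c_j) * g_ij / Z_i with
    Z_i = max(1, sum_j f(m_j) * g_ij), so total outflow <= mu * c_i.
    g_ij = guidance_g for in-plane neighbours inside the cleft slab, else 1.
    A per-target inflow rescaling s_j = min(1, (1 - c_j) / inflow_j) keeps
    c <= 1; unsent flux stays at its source, so mass is conserved exactly.
    """
    c = state.cells
    f = migration_response(state.ecm, params)
    geom = _geometry(params)
    g_inplane = geom["g_inplane"]

    # accumulations pair opposite directions per axis so that lattice mirror
    # symmetries of the fields are preserved bit-exactly
    fj = []
    cj = []
    g = []
    wsum = np.zeros_like(c)
    for axis, sign in _DIRS:
        fj.append(_shift(f, axis, sign))
        cj.append(_shift(c, axis, sign))
        g.append(g_inplane if axis in (0, 1) else geom["ones"])
    for axis in range(3):
        wsum += fj[2 * axis] * g[2 * axis] + fj[2 * axis + 1] * g[2 * axis + 1]
    Z = np.maximum(1.0, wsum)

    J = [params.mu * c * fj[k] * (1.0 - cj[k]) * g[k] / Z for k in range(6)]

    inflow = np.zeros_like(c)
    for axis in range(3):
        inflow += _shift(J[2 * axis], axis, -1) + _shift(J[2 * axis + 1], axis, +1)

    avail = 1.0 - c
    s = np.ones_like(c)
    over = inflow > avail
    s[over] = avail[over] / inflow[over]

    out_eff = np.zeros_like(c)
    for axis in range(3):
        out_eff += J[2 * axis] * _shift(s, axis, +1) + J[2 * axis + 1] * _shift(
            s, axis, -1
        )

    cells = c - out_eff + s * inflow
    np.clip(cells, 0.0, 1.0, out=cells)
    return SimulationState(cells, state.ecm.copy(), state.step)


def step(state: SimulationState, params: ModelParams) -> SimulationState:
    """One timestep: proliferation, then degradation, then migration."""
    s = step_proliferation(state, params)
    s = step_degradation(s, params)
    s = step_migration(s, params)
    s.step = state.step + 1
    return s


def run(
    params: ModelParams,
    n_steps: int | None = None,
    record_every: int | None = None,
    log=None,
) -> RunResult:
    """Iterate ``step`` from the initial condition.

    Parameters
    ----------
    n_steps : int, optional
        Overrides ``params.n_steps``.
    record_every : int, optional
        If given, keep a snapshot copy of the state every that many steps
        (the initial state is always snapshot 0).
    log : callable, optional
        Called as ``log(step, cell_mass, ecm_mass)`` every 10 steps.
    """
    n = params.n_steps if n_steps is None else n_steps
    state = init_state(params)
    snapshots = [state.copy()] if record_every else []
    for _ in range(n):
        state = step(state, params)
        if record_every and state.step % record_every == 0:
            snapshots.append(state.copy())
        if log is not None and state.step % 10 == 0:
            log(state.step, state.total_cell_mass, state.total_ecm_mass)
    return RunResult(final=state, snapshots=snapshots)
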