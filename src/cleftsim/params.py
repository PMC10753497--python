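"""Model parameters for the collagen-interface cellular automaton.

All distances are in micrometres, times in hours, densities dimensionless
in [0, 1]. The two experimental assay conditions (high-density 6 mg/ml and
low-density 2 mg/ml collagen) are exposed as ready-made parameter sets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = [
    "ModelParams",
    "high_density_params",
    "low_density_params",
    "ECM_INT_HIGH",
    "ECM_INT_LOW",
    "ECM_3D_HIGH",
    "ECM_3D_LOW",
]

#: Cleft ECM density measured for the high-density (6 mg/ml) assay.
ECM_INT_HIGH = 0.10
#: Cleft ECM density measured for the low-density (2 mg/ml) assay.
ECM_INT_LOW = 0.26
#: Bulk 3D ECM densities per assay condition. The cleft densities above are
#: measured quantities; the bulk densities are calibrated model parameters,
#: chosen so the automaton reproduces the observed invasion regimes: in the
#: high-density assay, 3D invasion is abolished without collagenolysis while
#: the interface sheet persists; in the low-density assay, emigration remains
#: interface-dominant but with substantially more 3D invasion.
ECM_3D_HIGH = 0.87
ECM_3D_LOW = 0.55


@dataclass(frozen=True)
class ModelParams:
    """Constants of the cellular automaton.

    Attributes
    ----------
    nx, ny, nz : int
        Lattice extents in voxels. ``nz`` should be odd so the cleft
        mid-plane sits on a voxel layer.
    dx : float
        Lattice spacing, um (one voxel ~ one cell diameter).
    dt : float
        Timestep, hours. The default 0.48 h makes the default 100-step run
        span the 48 h culture window.
    t_d : float
        Cell doubling time, hours (MV3 melanoma, ~24 h).
    delta : float
        ECM degradation rate constant, per step per unit local cell density.
    mu : float
        Mobility: maximum fraction of a voxel's cell density transferable
        per step, in [0, 1].
    ecm_crit : float
        Critical ECM density at which the migration flux response peaks.
    ecm_int : float
        ECM density assigned to the cleft slab.
    ecm_3d : float
        ECM density of the bulk 3D lattice (>= ecm_int).
    decay_k : float
        Exponential decay constant of the flux response above ecm_crit.
    guidance_g : float
        In-plane flux multiplier (>= 1) applied inside the cleft slab.
    spheroid_radius : float
        Initial spheroid radius, um.
    cleft_half_thickness : int
        The cleft slab spans ``2 * cleft_half_thickness + 1`` voxel layers.
    n_steps : int
        Number of timesteps for a full run.
    """

    nx: int = 60
    ny: int = 60
    nz: int = 31
    dx: float = 10.0
    dt: float = 0.48
    t_d: float = 24.0
    delta: float = 0.05
    mu: float = 0.6
    ecm_crit: float = 0.1
    ecm_int: float = 0.1
    ecm_3d: float = 0.87
    decay_k: float = 20.0
    guidance_g: float = 2.0
    spheroid_radius: float = 100.0
    cleft_half_thickness: int = 0
    n_steps: int = 100

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("lattice extents must be positive")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_d <= 0:
            raise ValueError("t_d must be positive")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if not 0.0 < self.ecm_crit <= 1.0:
            raise ValueError("ecm_crit must lie in (0, 1]")
        for name in ("ecm_int", "ecm_3d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ecm_int > self.ecm_3d:
            raise ValueError("ecm_int must not exceed ecm_3d")
        if self.decay_k < 0:
            raise ValueError("decay_k must be non-negative")
        if self.guidance_g < 1.0:
            raise ValueError("guidance_g must be >= 1")
        if self.spheroid_radius < 0:
            raise ValueError("spheroid_radius must be non-negative")
        if self.spheroid_radius >= min(self.nx, self.ny, self.nz) * self.dx / 2:
            raise ValueError("spheroid does not fit inside the lattice")
        h = self.cleft_half_thickness
        if h < 0:
            raise ValueError("cleft_half_thickness must be non-negative")
        mid = (self.nz - 1) // 2
        if mid - h < 0 or mid + h >= self.nz:
            raise ValueError("cleft slab does not fit inside the lattice")
        if self.n_steps < 0:
            raise ValueError("n_steps must be non-negative")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def high_density_params(**overrides) -> ModelParams:
    """Parameters of the high-density (6 mg/ml) collagen assay condition."""
    base = dict(ecm_int=ECM_INT_HIGH, ecm_3d=ECM_3D_HIGH)
    base.update(overrides)
    return ModelParams(**base)


def low_density_params(**overrides) -> ModelParams:
    """Parameters of the low-density (2 mg/ml) collagen assay condition."""
    base = dict(ecm_int=ECM_INT_LOW, ecm_3d=ECM_3D_LOW)
    base.update(overrides)
    return ModelParams(**base)
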