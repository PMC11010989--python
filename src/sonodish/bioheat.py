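"""Reduced Pennes bioheat solver with duty-cycle-gated acoustic heating.

The temperature field obeys

    rho C dT/dt = div(k grad T) - wb Cb (T - Tb) + gate(t) Q_US + Qm,

backward-Euler in time (dt = 0.01 s default) on the same layered lattice
as the acoustic solve.  For the in vitro dish the perfusion sink and the
metabolic source default to zero -- there is no blood flow in a Petri dish
and metabolic heat is negligible against ultrasound heating -- but both
terms are kept so the reduction is explicit.  Conduction into the glass
coverslip and the dish bottom is part of the same operator (their cells
simply carry glass/polymer properties).

Boundaries: mirror symmetry at x=0 and y=0.  In the default 'dish' mode
the z ends are held at the laboratory temperature (25 C) -- the top of
the water column is pumped cooling water, the dish bottom rests on the
lab-temperature surround -- while the lateral dish wall is adiabatic
(polystyrene + air insulates against the aqueous path; a clamped lateral
wall would also contradict the near-uniform low-pressure cell-plane
temperatures the model is meant to produce).  'dirichlet' clamps every
outer wall, 'insulated' makes all faces zero-flux (energy bookkeeping).
Temperatures are handled in degrees C; the perfusion difference (T - Tb)
is offset-invariant.

The acoustic heat source is switched by the burst protocol.  The gate is
integrated exactly over each thermal step (the ON fraction of [t, t+dt]),
so burst periods need not be multiples of the step; 'averaged' gating
replaces the switching by its duty-cycle mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _fv
from .acoustic import PulseProtocol, QField
from .geometry import Grid

__all__ = [
    "PerfusionSpec",
    "ThermalState",
    "TemperatureHistory",
    "duty_gate",
    "gate_fraction",
    "BioheatSolver",
    "run_thermal",
    "coarsen_q",
]

LAB_TEMP_C = 25.0


@dataclass(frozen=True)
class PerfusionSpec:
    """Pennes perfusion/metabolism terms; all zero for in vitro cultures."""

    wb: float = 0.0  # blood perfusion rate kg/(s m^3)
    Cb: float = 0.0  # blood specific heat J/(kg K)
    Tb: float = LAB_TEMP_C  # blood temperature, deg C
    Qm: float = 0.0  # metabolic heat W/m^3

    def __post_init__(self) -> None:
        if self.wb < 0 or self.Cb < 0 or self.Qm < 0:
            raise ValueError("perfusion parameters must be >= 0")


def duty_gate(t: float, prot: PulseProtocol) -> float:
    """Instantaneous gate factor: 1 inside the ON window of each burst,
    0 otherwise; the constant duty cycle in averaged mode."""
    if prot.gating == "averaged":
        return prot.duty_cycle
    return 1.0 if (t % prot.burst_period) < prot.duty_cycle * prot.burst_period else 0.0


def _on_time(t: float, prot: PulseProtocol) -> float:
    """Cumulative source-ON time in [0, t]."""
    tbd = prot.burst_period
    on = prot.duty_cycle * tbd
    full, rem = divmod(t, tbd)
    return full * on + min(rem, on)


def gate_fraction(t0: float, t1: float, prot: PulseProtocol) -> float:
    """Exact ON fraction of the interval [t0, t1] under the protocol."""
    if prot.gating == "averaged":
        return prot.duty_cycle
    if t1 <= t0:
        return 0.0
    return (_on_time(t1, prot) - _on_time(t0, prot)) / (t1 - t0)


@dataclass
class ThermalState:
    T: np.ndarray  # deg C, flattened (n_cells,)
    t: float
    dt: float


@dataclass
class TemperatureHistory:
    """Cell-plane summaries over time plus the final field."""

    times: np.ndarray
    t_min: np.ndarray
    t_max: np.ndarray
    t_mean: np.ndarray
    T_final: np.ndarray  # (nx, ny, nz) deg C
    cell_plane_final: np.ndarray  # (nx, ny) deg C, max over cell-layer cells
    max_so_far: float
    grid: Grid


class BioheatSolver:
    """Backward-Euler integrator of the reduced Pennes equation.

    ``boundary``: 'dish' (default -- z ends clamped, lateral walls
    adiabatic), 'dirichlet' (all outer walls clamped) or 'insulated'
    (all faces zero-flux, for energy-bookkeeping tests).  ``wall_temp``
    is a temperature in deg C or a mapping with keys 'z_low', 'z_high',
    'lateral' for unequal clamps.  ``k_scale`` multiplies every medium's
    conductivity (scaled desk fixtures use it to preserve the conduction
    Fourier number of the full-size problem).
    """

    def __init__(
        self,
        grid: Grid,
        q_us: np.ndarray,
        prot: PulseProtocol,
        *,
        perfusion: PerfusionSpec = PerfusionSpec(),
        dt: float = 0.01,
        t0_temp: float = LAB_TEMP_C,
        wall_temp=LAB_TEMP_C,
        boundary: str = "dish",
        k_scale: float = 1.0,
    ):
        if q_us.shape != grid.shape:
            raise ValueError(f"q_us shape {q_us.shape} != grid shape {grid.shape}")
        if np.any(q_us < 0):
            raise ValueError("q_us must be >= 0")
        self.grid = grid
        self.prot = prot
        self.perf = perfusion
        self.dt = dt
        nx, ny, nz = grid.shape

        rho_z = grid.prop_z("rho")
        c_heat_z = grid.prop_z("C")
        k_z = grid.prop_z("k") * k_scale
        self.rho_c = np.broadcast_to(rho_z * c_heat_z, (nx, ny, nz)).ravel()
        self.q = q_us.ravel()

        if boundary == "dish":
            lat_hi, z_lo, z_hi = "mirror", "dirichlet", "dirichlet"
        elif boundary == "dirichlet":
            lat_hi, z_lo, z_hi = "dirichlet", "dirichlet", "dirichlet"
        elif boundary == "insulated":
            lat_hi, z_lo, z_hi = "mirror", "mirror", "mirror"
        else:
            raise ValueError("boundary must be 'dish', 'dirichlet' or 'insulated'")
        A, affine = _fv.assemble_weighted_laplacian(
            nx,
            ny,
            grid.dx,
            grid.dy,
            grid.dz,
            w_z=k_z,
            bc_lateral_low="mirror",
            bc_lateral_high=lat_hi,
            bc_z_low=z_lo,
            bc_z_high=z_hi,
        )
        if not isinstance(wall_temp, dict):
            wall_temp = {"lateral": wall_temp, "z_low": wall_temp, "z_high": wall_temp}
        self._wall_affine = (
            affine["lateral"] * wall_temp.get("lateral", LAB_TEMP_C)
            + affine["z_low"] * wall_temp.get("z_low", LAB_TEMP_C)
            + affine["z_high"] * wall_temp.get("z_high", LAB_TEMP_C)
        )
        M = (
            sp.diags(self.rho_c / dt + perfusion.wb * perfusion.Cb) - A
        ).tocsc()
        self._lu = spla.splu(M)

        self.state = ThermalState(
            T=np.full(grid.n_cells, float(t0_temp)), t=0.0, dt=dt
        )

    def step(self) -> ThermalState:
        """Advance one thermal step with the exactly integrated gate."""
        st = self.state
        gate = gate_fraction(st.t, st.t + self.dt, self.prot)
        rhs = (
            self.rho_c / self.dt * st.T
            + gate * self.q
            + self.perf.Qm
            + self.perf.wb * self.perf.Cb * self.perf.Tb
            + self._wall_affine
        )
        T_new = self._lu.solve(rhs)
        if not np.all(np.isfinite(T_new)):
            raise RuntimeError(f"temperature field non-finite at t = {st.t:.3f} s")
        st.T = T_new
        st.t += self.dt
        return st

    def run(self, record_every: float = 0.1) -> TemperatureHistory:
        """Integrate to the end of sonication, recording cell-plane
        min/max/mean at the given cadence and the final field."""
        grid = self.grid
        nx, ny, nz = grid.shape
        cell_z = grid.layer_cells("Cells")
        n_steps = int(round(self.prot.sonication_duration / self.dt))
        rec_stride = max(1, int(round(record_every / self.dt)))

        times, tmin, tmax, tmean = [], [], [], []
        max_so_far = float(np.max(self.state.T))

        def record() -> None:
            plane = self.state.T.reshape(nx, ny, nz)[:, :, cell_z]
            times.append(self.state.t)
            tmin.append(float(plane.min()))
            tmax.append(float(plane.max()))
            tmean.append(float(plane.mean()))

        record()
        for i in range(n_steps):
            self.step()
            max_so_far = max(max_so_far, float(np.max(self.state.T)))
            if (i + 1) % rec_stride == 0 or i == n_steps - 1:
                record()
        T_final = self.state.T.reshape(nx, ny, nz)
        return TemperatureHistory(
            times=np.asarray(times),
            t_min=np.asarray(tmin),
            t_max=np.asarray(tmax),
            t_mean=np.asarray(tmean),
            T_final=T_final,
            cell_plane_final=T_final[:, :, cell_z].max(axis=2),
            max_so_far=max_so_far,
            grid=grid,
        )


def run_thermal(
    q_field: QField,
    prot: PulseProtocol,
    *,
    perfusion: PerfusionSpec = PerfusionSpec(),
    dt: float = 0.01,
    record_every: float = 0.1,
    **solver_kwargs,
) -> TemperatureHistory:
    """Integrate the thermal stage driven by a steady acoustic Q field."""
    solver = BioheatSolver(
        q_field.grid, q_field.q_us, prot, perfusion=perfusion, dt=dt, **solver_kwargs
    )
    return solver.run(record_every=record_every)


def coarsen_q(q_us: np.ndarray, factor_xy: int) -> np.ndarray:
    """Conservative block-mean aggregation of Q onto a transverse grid
    coarsened by an integer factor (z resolution is kept: the thin layers
    live there)."""
    nx, ny, nz = q_us.shape
    if nx % factor_xy or ny % factor_xy:
        raise ValueError(f"grid {nx}x{ny} not divisible by factor {factor_xy}")
    return q_us.reshape(
        nx // factor_xy, factor_xy, ny // factor_xy, factor_xy, nz
    ).mean(axis=(1, 3))
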