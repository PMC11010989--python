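"""Session-scoped heavy simulation fixtures shared across test modules.

The expensive runs (the 3D focused-bowl solve, the scaled end-to-end
scenarios, the full-frequency 1D columns) are computed once per session;
several tests assert different properties of the same fields.
"""

from __future__ import annotations

import numpy as np
import pytest

import sonodish as sd
from sonodish.acoustic import PMLConfig, PulseProtocol, SourceSpec, WesterveltSolver
from sonodish.bioheat import BioheatSolver
from sonodish.fixtures import make_scaled_scenario
from sonodish.geometry import LayerStack, build_grid
from sonodish.oracles import rayleigh_bowl_field
from sonodish.scenarios import run_scenario

from _utils import grid_1d


@pytest.fixture(scope="session")
def water():
    return sd.medium_properties("Water")


@pytest.fixture(scope="session")
def focused_linear(water):
    """Linear lossless quarter-domain solve of the focused source at
    desk scale (f0 = 100 kHz, d = 4 lambda, aperture ratio preserved),
    with the on-axis Rayleigh-integral oracle."""
    f0 = 100.0e3
    lam = water.c0 / f0
    d = 4.0 * lam
    a = d * 16.5 / 51.4
    stack = LayerStack(layers=((water, 5.5 * lam),), radial_extent=2.0 * lam)
    grid = build_grid(stack, f0, scale=(0.75, 0.75, 1.0))
    src = SourceSpec(p0=1.0, f0=f0, d=d, a=a, c0=water.c0)
    solver = WesterveltSolver(grid, src, nonlinear=False, pml=PMLConfig(), ramp_cycles=3)
    qf = solver.run_to_steady_state(residual_tol=1.0e-6, max_cycles=300)
    oracle_axis = np.abs(rayleigh_bowl_field(src, grid.zc, c0=water.c0))
    return {"grid": grid, "src": src, "qf": qf, "oracle_axis": oracle_axis}


SCALED_LABELS = (
    "monolayer_dc15_p0433",
    "monolayer_dc30_p0433",
    "monolayer_dc15_p0661",
    "monolayer_dc30_p0661",
)


@pytest.fixture(scope="session")
def scaled_summaries():
    """End-to-end scaled variants of the registered scenarios (duty-cycle
    and pressure axes of the study at desk scale)."""
    return {label: run_scenario(make_scaled_scenario(label)) for label in SCALED_LABELS}


def run_full_frequency_column(configuration: str, dc: float = 0.15, p0: float = 0.433e6):
    """Full-frequency (2 MHz) 1D layered column with the real layer
    thicknesses, attenuations and a 5-minute duty-cycled soak: the
    monolayer-vs-spheroid mechanism (growth-medium conductivity vs cell
    layer absorption) at the true physical regime, with the transverse
    focusing replaced by a plane wave.  The water column is shortened to
    10 wavelengths so the source-glass standing-wave cavity rings up in
    tractable time."""
    f0 = 2.0e6
    water = sd.medium_properties("Water")
    lam = water.c0 / f0
    medium = sd.medium_properties("DMEM" if configuration == "monolayer" else "Hydrogel")
    cells_t = 15.0e-6 if configuration == "monolayer" else 117.0e-6
    grid = grid_1d(
        [
            (water, 10 * lam),
            (medium, 2.0e-3),
            (sd.medium_properties("Cells"), cells_t),
            (sd.medium_properties("Glass"), 170.0e-6),
            (sd.medium_properties("Petri Dish"), 1.0e-3),
        ],
        f0,
    )
    src = SourceSpec(p0=p0, f0=f0, d=51.4e-3, a=16.5e-3, c0=water.c0)
    solver = WesterveltSolver(
        grid, src, lateral_bc="mirror", nonlinear=True, pml=PMLConfig(), ramp_cycles=3
    )
    qf = solver.run_to_steady_state(residual_tol=5.0e-4, max_cycles=1500)
    prot = PulseProtocol(
        duty_cycle=dc, burst_period=1.0, sonication_duration=300.0, gating="averaged"
    )
    hist = BioheatSolver(grid, qf.q_us, prot, dt=0.01, boundary="dish").run(
        record_every=10.0
    )
    return hist


@pytest.fixture(scope="session")
def greens_comparison():
    """Point energy release in uniform water on a 3D lattice vs the
    free-space conduction kernel: returns (numerical, expected) profiles
    along the axis through the release cell."""
    from sonodish.oracles import conduction_kernel

    medium = sd.medium_properties("Water")
    f0 = 100.0e3
    lam = medium.c0 / f0
    stack = LayerStack(
        layers=((medium, 31 * 0.1 * lam),), radial_extent=31 * 0.2 * lam
    )
    g = build_grid(stack, f0)
    dz = g.dz[0]
    kz = g.nz // 2
    dV = g.dx * g.dy * dz
    prot = PulseProtocol(1.0, 1.0, 0.0)
    solver = BioheatSolver(g, np.zeros(g.shape), prot, dt=2.0, boundary="insulated")
    T = solver.state.T.reshape(g.shape)
    # octant release against the two mirror planes: images complete 4x
    T[0, 0, kz] += 1.0 / (medium.rho * medium.C * dV)
    solver.state.T = T.ravel()
    t_end = 400.0  # spread sigma ~ 7 cells: well resolved, far from walls
    for _ in range(int(t_end / solver.dt)):
        solver.step()
    T = solver.state.T.reshape(g.shape) - 25.0
    z_rel = g.zc - g.zc[kz]
    r = np.sqrt(g.xc[0] ** 2 + g.yc[0] ** 2 + z_rel**2)
    expected = conduction_kernel(4.0, medium.rho, medium.C, medium.k, t_end, r)
    sel = np.abs(z_rel) < 8 * dz
    return T[0, 0, sel], expected[sel]


@pytest.fixture(scope="session")
def column_temperatures():
    """Final cell-plane temperatures of the two culture configurations in
    the full-frequency column."""
    return {
        "monolayer": run_full_frequency_column("monolayer").t_max[-1],
        "spheroid": run_full_frequency_column("spheroid").t_max[-1],
    }
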