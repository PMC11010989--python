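"""Reduced Pennes solver: gating, conduction, interfaces, invariants."""

import numpy as np
import pytest

import sonodish as sd
from sonodish.acoustic import PulseProtocol
from sonodish.bioheat import (
    BioheatSolver,
    PerfusionSpec,
    duty_gate,
    gate_fraction,
)
from sonodish.geometry import LayerStack, build_grid
from sonodish.oracles import adiabatic_heating_rate

from _utils import grid_1d

WATER = sd.medium_properties("Water")
CELLS = sd.medium_properties("Cells")
F0 = 100.0e3
LAM = WATER.c0 / F0


def small_grid(medium=CELLS, depth_lam=20, radial_lam=2):
    stack = LayerStack(layers=((medium, depth_lam * LAM),), radial_extent=radial_lam * LAM)
    return build_grid(stack, F0)


# ------------------------------------------------------------------ gate
class TestDutyGate:
    prot = PulseProtocol(duty_cycle=0.15, burst_period=1.0, sonication_duration=3.0)

    def test_full_duty_always_on(self):
        p = PulseProtocol(duty_cycle=1.0, burst_period=1.0, sonication_duration=2.0)
        assert all(duty_gate(t, p) == 1.0 for t in (0.0, 0.3, 1.7))

    def test_off_phase(self):
        assert duty_gate(0.5, self.prot) == 0.0
        assert duty_gate(0.1, self.prot) == 1.0

    def test_time_average_over_period_equals_duty_cycle(self):
        assert gate_fraction(0.0, 1.0, self.prot) == pytest.approx(0.15)
        assert gate_fraction(1.0, 3.0, self.prot) == pytest.approx(0.15)

    def test_averaged_mode_constant(self):
        p = PulseProtocol(0.3, 1.0, 2.0, gating="averaged")
        assert duty_gate(0.9, p) == 0.3
        assert gate_fraction(0.31, 0.47, p) == 0.3

    def test_partial_interval_fraction_exact(self):
        # [0.1, 0.2]: ON until 0.15 -> half the interval
        assert gate_fraction(0.1, 0.2, self.prot) == pytest.approx(0.5)


# ----------------------------------------------------------- equilibria
def test_no_heating_is_equilibrium():
    g = small_grid()
    prot = PulseProtocol(1.0, 1.0, 0.0)
    solver = BioheatSolver(g, np.zeros(g.shape), prot, dt=0.05)
    for _ in range(40):
        solver.step()
    np.testing.assert_allclose(solver.state.T, 25.0, atol=1e-10)


def test_zero_duration_returns_initial_field():
    g = small_grid()
    prot = PulseProtocol(0.5, 1.0, 0.0)
    hist = BioheatSolver(g, np.zeros(g.shape), prot).run()
    assert hist.times[-1] == 0.0
    np.testing.assert_allclose(hist.T_final, 25.0)


def test_adiabatic_heating_rate_limit():
    """Early times, insulated, uniform Q: dT/dt = Q/(rho C) within 1%."""
    g = small_grid(CELLS)
    q = np.full(g.shape, 1.19e5)
    prot = PulseProtocol(1.0, 0.1, 0.5)
    hist = BioheatSolver(g, q, prot, dt=0.01, boundary="insulated").run(record_every=0.1)
    rate = (hist.t_mean[-1] - 25.0) / hist.times[-1]
    assert rate == pytest.approx(adiabatic_heating_rate(1.19e5, CELLS), rel=0.01)


def test_two_layer_slab_steady_state_flux_continuity():
    """1D DMEM/Cells slab held between unequal end temperatures relaxes
    to the piecewise-linear Fourier profile with continuous k dT/dz."""
    dmem = sd.medium_properties("DMEM")
    f0 = 1.0e6  # 1.52 mm wavelength -> 15 mm half-slabs reach steady state
    lam = WATER.c0 / f0
    grid = grid_1d([(dmem, 10 * lam), (CELLS, 10 * lam)], f0)
    prot = PulseProtocol(1.0, 1.0, 0.0)
    solver = BioheatSolver(
        grid,
        np.zeros(grid.shape),
        prot,
        dt=50.0,
        boundary="dish",  # lateral faces are symmetry planes: a true 1D slab
        wall_temp={"z_low": 50.0, "z_high": 20.0},
    )
    for _ in range(4000):
        solver.step()
    T = solver.state.T.reshape(grid.shape)[0, 0, :]
    L = grid.depth / 2
    k1, k2 = dmem.k, CELLS.k
    # series resistances give the interface temperature
    T_int = 50.0 + (20.0 - 50.0) * (L / k1) / (L / k1 + L / k2)
    z = grid.zc
    expected = np.where(
        z < L, 50.0 + (T_int - 50.0) * z / L, T_int + (20.0 - T_int) * (z - L) / L
    )
    np.testing.assert_allclose(T, expected, atol=0.05)
    # flux continuity across the interface
    i = len(z) // 2
    flux1 = k1 * (T[i - 1] - T[i - 2]) / (z[i - 1] - z[i - 2])
    flux2 = k2 * (T[i + 2] - T[i + 1]) / (z[i + 2] - z[i + 1])
    assert flux1 == pytest.approx(flux2, rel=1e-3)


def test_point_release_matches_conduction_kernel(greens_comparison):
    """Instantaneous energy release in a uniform medium spreads as the
    free-space Gaussian kernel within 2%."""
    numerical, expected = greens_comparison
    np.testing.assert_allclose(numerical, expected, rtol=0.02)


# ------------------------------------------------------------ invariants
def test_maximum_principle_with_heating():
    """Q >= 0 and cool walls: the field never drops below the initial /
    wall temperature."""
    rng = np.random.default_rng(7)
    g = small_grid()
    q = rng.uniform(0, 2e5, size=g.shape)
    prot = PulseProtocol(0.3, 0.2, 1.0)
    solver = BioheatSolver(g, q, prot, dt=0.01)
    t_min = 25.0
    for _ in range(100):
        solver.step()
        assert solver.state.T.min() >= t_min - 1e-9
    assert solver.state.T.max() > 25.0


def test_energy_bookkeeping_insulated():
    """Insulated box: total enthalpy gain equals the gated integral of Q
    over volume and time within 1%."""
    g = small_grid()
    q = np.zeros(g.shape)
    q[2:5, 1:4, 5:12] = 3.0e5
    prot = PulseProtocol(0.35, 0.2, 1.0)
    solver = BioheatSolver(g, q, prot, dt=0.013, boundary="insulated")
    n_steps = int(round(prot.sonication_duration / solver.dt))
    on_integral = 0.0
    for i in range(n_steps):
        t0 = i * solver.dt
        on_integral += gate_fraction(t0, t0 + solver.dt, prot) * solver.dt
        solver.step()
    dV = g.dx * g.dy * g.dz[None, None, :]
    rho_c = solver.rho_c.reshape(g.shape)
    gained = float(((solver.state.T.reshape(g.shape) - 25.0) * rho_c * dV).sum())
    expected = float((q * dV).sum()) * on_integral
    assert gained == pytest.approx(expected, rel=0.01)


def test_gated_and_averaged_modes_agree_for_fast_bursts():
    """As the burst period shrinks below ~10 thermal steps, gated and
    duty-averaged runs give the same end temperature."""
    g = small_grid()
    q = np.full(g.shape, 5.0e6)
    kwargs = dict(dt=0.01)
    gated = PulseProtocol(0.3, 0.1, 2.0, gating="gated")
    avg = PulseProtocol(0.3, 0.1, 2.0, gating="averaged")
    h1 = BioheatSolver(g, q, gated, **kwargs).run()
    h2 = BioheatSolver(g, q, avg, **kwargs).run()
    assert h1.t_max[-1] - 25 > 0.5  # a K-scale rise, so 0.1 C is meaningful
    assert abs(h1.t_max[-1] - h2.t_max[-1]) < 0.1


def test_max_so_far_monotone_and_final_range_ordered():
    g = small_grid()
    q = np.full(g.shape, 1.0e6)
    prot = PulseProtocol(0.5, 0.2, 1.0)
    hist = BioheatSolver(g, q, prot).run(record_every=0.1)
    assert hist.max_so_far >= hist.t_max[-1] - 1e-12
    assert np.all(np.diff(hist.times) > 0)
    assert np.all(hist.t_min <= hist.t_max + 1e-12)


def test_perfusion_term_cools_toward_blood_temperature():
    """Nonzero Pennes sink pulls a heated field toward Tb (kept for
    completeness although in vitro runs use wb = 0)."""
    g = small_grid()
    q = np.full(g.shape, 1.0e6)
    prot = PulseProtocol(1.0, 1.0, 2.0)
    perf = PerfusionSpec(wb=5.0, Cb=3800.0, Tb=25.0)
    hot = BioheatSolver(g, q, prot, boundary="insulated").run()
    cooled = BioheatSolver(g, q, prot, perfusion=perf, boundary="insulated").run()
    assert cooled.t_max[-1] < hot.t_max[-1]


def test_invalid_inputs_rejected():
    g = small_grid()
    prot = PulseProtocol(0.5, 1.0, 1.0)
    with pytest.raises(ValueError):
        BioheatSolver(g, -np.ones(g.shape), prot)
    with pytest.raises(ValueError):
        BioheatSolver(g, np.zeros((2, 2, 2)), prot)
    with pytest.raises(ValueError):
        PerfusionSpec(wb=-1.0)
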