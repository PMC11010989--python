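"""Westervelt solver: source term, propagation, losses, nonlinearity,
absorbing boundary, symmetry and heat deposition."""

import math

import numpy as np
import pytest

import sonodish as sd
from sonodish.acoustic import (
    NonConvergenceError,
    PMLConfig,
    PulseProtocol,
    SourceSpec,
    WesterveltSolver,
    heat_deposition,
    source_pressure,
)
from sonodish.materials import with_overrides

from _utils import grid_1d, plane_wave_solver, record_probe

WATER = sd.medium_properties("Water")
F0 = 100.0e3
LAM = WATER.c0 / F0


# ---------------------------------------------------------------- source
class TestSourceTerm:
    src = SourceSpec(p0=2.0e5, f0=2.0e6, d=51.4e-3, a=16.5e-3)
    prot = PulseProtocol(duty_cycle=0.15, burst_period=1.0, sonication_duration=10.0)

    def test_on_axis_reduces_to_plain_sinusoid(self):
        t = 0.8 / self.src.f0 % (0.15)  # inside first ON window
        assert source_pressure(t, 0.0, self.src, self.prot) == pytest.approx(
            self.src.p0 * math.sin(self.src.omega * t), rel=1e-12
        )

    def test_outside_aperture_is_zero(self):
        assert source_pressure(1e-7, self.src.a * 1.01, self.src, self.prot) == 0.0

    def test_off_window_is_zero(self):
        r = np.linspace(0, self.src.a, 5)
        assert np.all(source_pressure(0.5, r, self.src, self.prot) == 0.0)

    def test_amplitude_and_phase_grow_off_axis(self):
        # sample over a full cycle: envelope carries the sqrt(1 + r^2/d^2)
        ts = np.linspace(0, 1 / self.src.f0, 400)
        r = self.src.a * 0.9
        env = max(abs(source_pressure(t, r, self.src, None)) for t in ts)
        assert env == pytest.approx(
            self.src.p0 * math.sqrt(1 + r**2 / self.src.d**2), rel=1e-4
        )

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            source_pressure(0.0, -1.0, self.src, self.prot)

    def test_protocol_invariants(self):
        with pytest.raises(ValueError):
            PulseProtocol(duty_cycle=0.0)
        with pytest.raises(ValueError):
            PulseProtocol(duty_cycle=0.5, burst_period=0.3, sonication_duration=1.0)
        assert PulseProtocol(0.5, 0.25, 1.0).n_bursts == 4


# ---------------------------------------------------- linear propagation
class TestLinearPropagation:
    @staticmethod
    def _measure_wavenumber(dz_scale):
        """Fitted axial wavenumber of a settled lossless plane wave."""
        grid = grid_1d([(with_overrides(WATER, alpha_ref=0.0), 20 * LAM)], F0,
                       dz_scale=dz_scale)
        solver = plane_wave_solver(grid)
        # lossless interior: the only residual decay channel is the tiny
        # boundary leakage, so the envelope settles to ~1e-5 and stays
        qf = solver.run_to_steady_state(residual_tol=3e-5, max_cycles=300)
        nper = solver.steps_per_cycle
        rec = np.zeros((nper, grid.nz), dtype=float)
        ts = np.zeros(nper)
        for i in range(nper):
            solver.step()
            rec[i] = solver.state.p
            ts[i] = solver.state.t
        proj = (rec * np.exp(-1j * solver.src.omega * ts)[:, None]).mean(axis=0)
        phase = np.unwrap(np.angle(proj))
        k_fit = -np.polyfit(grid.zc[:-8], phase[:-8], 1)[0]
        return qf, k_fit, solver.src.omega / WATER.c0

    def test_lossless_plane_wave_amplitude_preserved(self):
        """Uniform lossless medium: unit amplitude along 20 wavelengths."""
        qf, _, _ = self._measure_wavenumber(1.0)
        np.testing.assert_allclose(qf.p_amp[0, 0, :-8], 1.0, atol=0.01)

    def test_numerical_dispersion_second_order(self):
        """The axial phase-speed error of the central stencil is
        (k dz)^2/24: ~1.6% at the production dz = 0.1 lambda, below 1%
        (indeed ~0.4%) at dz = 0.05 lambda, converging at second order."""
        _, k_coarse, k_exact = self._measure_wavenumber(1.0)
        _, k_fine, _ = self._measure_wavenumber(0.5)
        err_coarse = abs(k_coarse - k_exact) / k_exact
        err_fine = abs(k_fine - k_exact) / k_exact
        assert err_coarse < 0.02
        assert err_fine < 0.01
        assert err_coarse / err_fine == pytest.approx(4.0, rel=0.4)

    def test_lossy_decay_matches_exponential_within_1pct(self):
        """delta > 0: the envelope follows exp(-alpha z) to <1%."""
        alpha = 0.01 / LAM
        medium = with_overrides(WATER, alpha_ref=alpha, eta=0.0)
        grid = grid_1d([(medium, 20 * LAM)], F0)
        solver = plane_wave_solver(grid)
        qf = solver.run_to_steady_state(residual_tol=1e-7, max_cycles=300)
        expected = np.exp(-alpha * grid.zc)
        err = np.abs(qf.p_amp[0, 0, :] / expected - 1.0)
        assert err.max() < 0.01

    def test_energy_flux_conserved_without_absorption(self):
        """alpha = 0: the plane-wave intensity is uniform along z."""
        grid = grid_1d([(with_overrides(WATER, alpha_ref=0.0), 15 * LAM)], F0)
        qf = plane_wave_solver(grid).run_to_steady_state(residual_tol=3e-5, max_cycles=300)
        intensity = qf.intensity[0, 0, :-8]
        assert np.ptp(intensity) / intensity.mean() < 0.03

    def test_zero_source_stays_zero(self):
        grid = grid_1d([(WATER, 5 * LAM)], F0)
        solver = plane_wave_solver(grid)
        solver._src_amp *= 0.0
        for _ in range(50):
            solver.step()
        assert np.all(solver.state.p == 0.0)


# ------------------------------------------------------- absorbing layer
class TestAbsorbingBoundary:
    def _burst_probe(self, domain_lam, n_cycles):
        grid = grid_1d([(with_overrides(WATER, alpha_ref=0.0), domain_lam * LAM)], F0)
        solver = plane_wave_solver(grid)
        probe = int(10 * LAM / grid.dz[0])
        return record_probe(solver, probe, n_cycles, burst_cycles=16, taper_cycles=6)

    def test_pulse_reflection_below_1pct_of_incident(self):
        """Narrowband burst into the absorber: the reflected signal at a
        mid-domain probe is <1% of the incident, using a long-domain run
        (no reflection can return in the window) as the oracle."""
        short = self._burst_probe(25, 80)
        long_ = self._burst_probe(95, 80)
        incident = np.abs(long_).max()
        reflected = np.abs(short - long_)[int(len(short) * 0.69):].max()
        assert reflected / incident < 0.01

    def test_disabled_absorber_builds_standing_waves(self):
        """Regression guard: with the absorber off the hard far wall
        produces a strong standing-wave envelope ripple."""
        grid = grid_1d([(with_overrides(WATER, alpha_ref=0.0), 10 * LAM)], F0)
        solver = plane_wave_solver(grid, pml=None)
        env = None
        for _ in range(60):
            env = solver.run_cycle()
        interior = env[5:-5]
        assert interior.max() / max(interior.min(), 1e-12) > 2.0

    def test_zero_field_in_absorber_stays_zero(self):
        grid = grid_1d([(WATER, 10 * LAM)], F0)
        solver = plane_wave_solver(grid)
        solver._src_amp *= 0.0
        for _ in range(30):
            solver.step()
        assert np.all(solver.state.p == 0.0)


# ------------------------------------------------------------ 3D focused
class TestFocusedField:
    def test_focal_amplitude_within_10pct_of_rayleigh(self, focused_linear):
        qf = focused_linear["qf"]
        oracle = focused_linear["oracle_axis"]
        assert qf.p_amp.max() == pytest.approx(oracle.max(), rel=0.10)

    def test_amplitude_field_symmetric_under_xy_reflection(self, focused_linear):
        """Axisymmetric source on a square quarter grid: swapping x and y
        leaves the steady amplitude unchanged."""
        p = focused_linear["qf"].p_amp
        np.testing.assert_allclose(p, p.transpose(1, 0, 2), rtol=1e-7, atol=1e-10)

    def test_q_field_invariants(self, focused_linear):
        """Q >= 0 everywhere and Q = 2 alpha I nodewise."""
        from sonodish.materials import attenuation_coefficient

        qf = focused_linear["qf"]
        grid = focused_linear["grid"]
        assert np.all(qf.q_us >= 0)
        alpha_z = np.array(
            [attenuation_coefficient(m, grid.f0) for m in grid.media]
        )[grid.mat_z]
        np.testing.assert_allclose(
            qf.q_us, 2.0 * alpha_z[None, None, :] * qf.intensity, rtol=1e-12
        )


# -------------------------------------------------------- quadratic drive
def test_heat_deposition_scales_as_p0_squared():
    """Linear regime (beta off): doubling p0 quadruples Q everywhere."""
    medium = with_overrides(WATER, alpha_ref=0.02 / LAM, eta=0.0)
    grid = grid_1d([(medium, 10 * LAM)], F0)
    q = {}
    for p0 in (1.0, 2.0):
        qf = plane_wave_solver(grid, p0=p0).run_to_steady_state(
            residual_tol=1e-6, max_cycles=250
        )
        q[p0] = qf.q_us
    ratio = q[2.0] / q[1.0]
    np.testing.assert_allclose(ratio, 4.0, rtol=0.01)


# ----------------------------------------------------------- nonlinearity
def test_second_harmonic_matches_fubini_term():
    """beta > 0, sigma << 1: the second harmonic grows linearly with
    distance at the Fubini rate p2 = p0 J2(2 sigma)/sigma."""
    medium = with_overrides(WATER, alpha_ref=0.0, eta=0.0)
    grid = grid_1d([(medium, 12 * LAM)], F0, dz_scale=0.5)
    rho, c = WATER.rho, WATER.c0
    beta = 1 + 3.5 / 2
    omega = 2 * math.pi * F0
    z_shock = 50 * LAM
    p0 = rho * c**3 / (beta * omega * z_shock)
    solver = plane_wave_solver(grid, p0=p0, nonlinear=True, dt=0.005 / F0, ramp_cycles=4)
    solver.run_to_steady_state(residual_tol=1e-5, max_cycles=250)
    nper = solver.steps_per_cycle
    probe = int(8 * LAM / grid.dz[0])
    rec = np.array([solver.step().p[probe] for _ in range(nper)])
    spectrum = np.abs(np.fft.rfft(rec)) / nper * 2
    sigma = grid.zc[probe] / z_shock
    from scipy.special import jv

    fubini_p2 = p0 * jv(2, 2 * sigma) / sigma
    assert spectrum[2] == pytest.approx(fubini_p2, rel=0.10)
    # fundamental barely depleted at this distance
    assert spectrum[1] == pytest.approx(p0, rel=0.02)


# ------------------------------------------------------- heat deposition
class TestHeatDeposition:
    def test_unit_plugin(self):
        assert heat_deposition(1.0, 1.0, 1.0) == 1.0

    def test_cells_at_source_pressure(self):
        cells = sd.medium_properties("Cells")
        alpha = cells.alpha(2.0e6)
        q = heat_deposition(0.433e6, alpha, cells.impedance)
        assert q == pytest.approx(alpha * 0.433e6**2 / (1066 * 1423), rel=1e-9)
        assert q == pytest.approx(1.19e5, rel=0.02)

    def test_zero_absorption_zero_heat(self):
        assert heat_deposition(1e6, 0.0, 1.5e6) == 0.0


# ----------------------------------------------------------- diagnostics
def test_nonconvergence_carries_residual_trace():
    grid = grid_1d([(WATER, 10 * LAM)], F0)
    solver = plane_wave_solver(grid)
    with pytest.raises(NonConvergenceError) as err:
        solver.run_to_steady_state(residual_tol=1e-14, max_cycles=8)
    assert len(err.value.residuals) > 0


def test_excessive_loss_number_rejected():
    medium = with_overrides(WATER, alpha_ref=0.2 / LAM, eta=0.0)
    grid = grid_1d([(medium, 5 * LAM)], F0)
    with pytest.raises(ValueError, match="loss number"):
        plane_wave_solver(grid)
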