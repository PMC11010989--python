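"""Independent closed-form references used by the test suite.

These are deliberately simple, grid-free formulas sharing no code with the
solvers: a lossy plane wave, the Rayleigh integral of the focused source,
the free-space conduction Green's function, and the adiabatic heating
limit.  The solver modules never import this one.
"""

from __future__ import annotations

import math

import numpy as np

from .materials import MediumLayer

__all__ = [
    "lossy_plane_wave",
    "rayleigh_bowl_field",
    "conduction_kernel",
    "adiabatic_heating_rate",
]


def lossy_plane_wave(p0: float, alpha: float, z) -> np.ndarray:
    """Amplitude of a plane wave after distance z in a medium with
    attenuation alpha (Np/m): p0 * exp(-alpha z)."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return p0 * np.exp(-alpha * np.asarray(z, dtype=float))


def rayleigh_bowl_field(
    src,
    z_points,
    c0: float = 1520.0,
    n_quad: int = 4000,
) -> np.ndarray:
    """On-axis complex pressure of the focused source in the linear
    lossless regime, by numerically integrating the Rayleigh--Sommerfeld
    integral of the first kind over the phased source plane.

    The source prescribes on z=0, for r <= a, the complex amplitude
    u(r) = p0 sqrt(1+r^2/d^2) exp(i (w d / c0)(sqrt(1+r^2/d^2)-1)), i.e.
    outer annuli lead in phase so all contributions arrive in phase at the
    geometric focus z=d.  For a Dirichlet (pressure) plane source,

        p(z) = -d/dz  Int_0^a u(r') exp(-i k R)/R  r' dr',
        R = sqrt(z^2 + r'^2),

    which reduces to u exp(-i k z) for an unapodised infinite aperture.
    The z derivative is taken analytically inside the integral and the
    radial integral evaluated by the trapezoid rule with ``n_quad`` panels.
    """
    k = 2.0 * math.pi * src.f0 / c0
    a = src.a
    d = src.d
    rp = np.linspace(0.0, a, n_quad + 1)
    amp = src.p0 * np.sqrt(1.0 + rp**2 / d**2)
    phase = (2.0 * math.pi * src.f0 * d / c0) * (np.sqrt(1.0 + rp**2 / d**2) - 1.0)
    u = amp * np.exp(1j * phase)
    z_points = np.atleast_1d(np.asarray(z_points, dtype=float))
    out = np.empty(z_points.shape, dtype=complex)
    for i, z in enumerate(z_points):
        R = np.sqrt(z**2 + rp**2)
        # -d/dz (e^{-ikR}/R) = (z/R^2)(ik + 1/R) e^{-ikR}
        kern = (z / R**2) * (1j * k + 1.0 / R) * np.exp(-1j * k * R)
        out[i] = np.trapezoid(u * kern * rp, rp)
    return out


def conduction_kernel(
    energy: float,
    rho: float,
    C: float,
    k: float,
    t: float,
    r,
) -> np.ndarray:
    """Temperature rise of an instantaneous point release of ``energy`` J
    in an infinite uniform medium (free-space heat kernel):

        dT(r, t) = E / (rho C (4 pi a_d t)^{3/2}) exp(-r^2 / (4 a_d t)),

    with thermal diffusivity a_d = k/(rho C)."""
    if not (t > 0):
        raise ValueError("t must be > 0")
    a_d = k / (rho * C)
    r = np.asarray(r, dtype=float)
    return (
        energy
        / (rho * C * (4.0 * math.pi * a_d * t) ** 1.5)
        * np.exp(-(r**2) / (4.0 * a_d * t))
    )


def adiabatic_heating_rate(q: float, medium: MediumLayer) -> float:
    """Early-time temperature slope of a uniformly heated parcel before
    conduction matters: dT/dt = Q / (rho C), K/s."""
    return q / (medium.rho * medium.C)
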