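"""Shared helpers for the test suite: 1D grids and canned solver runs."""

from __future__ import annotations

import numpy as np

from sonodish.geometry import Grid, LayerStack, build_grid
from sonodish.acoustic import PMLConfig, SourceSpec, WesterveltSolver


def grid_1d(layers, f0, radial=None, dz_scale=1.0):
    """Cell-centred 1D (nx = ny = 1) grid for plane-wave runs.

    ``layers``: list of (MediumLayer, thickness) from the source downward.
    """
    ref = layers[0][0]
    lam = ref.c0 / f0
    stack = LayerStack(
        layers=tuple(layers),
        radial_extent=radial if radial is not None else lam,
        sub_grid=frozenset(m.name for m, t in layers if t < 0.1 * lam * dz_scale),
    )
    g = build_grid(stack, f0, scale=(1.0, 1.0, dz_scale))
    return Grid(
        dx=g.dx,
        dy=g.dy,
        z_edges=g.z_edges,
        nx=1,
        ny=1,
        lambda0=g.lambda0,
        f0=f0,
        media=g.media,
        mat_z=g.mat_z,
    )


def plane_source(p0, f0, c0):
    """Effectively unfocused source (huge focal distance): p0 sin(w t)."""
    return SourceSpec(p0=p0, f0=f0, d=1.0e3, a=1.0, c0=c0)


def plane_wave_solver(grid, p0=1.0, nonlinear=False, dt=None, ramp_cycles=3.0, pml=PMLConfig()):
    src = plane_source(p0, grid.f0, grid.media[0].c0)
    return WesterveltSolver(
        grid,
        src,
        lateral_bc="mirror",
        nonlinear=nonlinear,
        pml=pml,
        dt=dt,
        ramp_cycles=ramp_cycles,
    )


def record_probe(solver, probe_cell, n_cycles, burst_cycles=None, taper_cycles=None):
    """March ``n_cycles`` and record p at one cell each step.  If
    ``burst_cycles`` is given the source is cosine-tapered off over
    ``taper_cycles`` so the emitted burst is narrowband."""
    base_amp = solver._src_amp.copy()
    nper = solver.steps_per_cycle
    ndrive = None if burst_cycles is None else int(burst_cycles * nper)
    ntaper = 0 if taper_cycles is None else int(taper_cycles * nper)
    rec = []
    for _ in range(int(n_cycles * nper)):
        n = solver._step_index
        if ndrive is not None and n > ndrive - ntaper:
            frac = max(0.0, (ndrive - n) / max(ntaper, 1))
            solver._src_amp = base_amp * 0.5 * (1.0 - np.cos(np.pi * frac))
        solver.step()
        rec.append(solver.state.p[probe_cell])
    return np.asarray(rec)
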