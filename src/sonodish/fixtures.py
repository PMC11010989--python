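"""Self-contained scenario generators: the registered full-scale study
scenarios and their scaled desk-size variants.

A full-scale run (2 MHz, 51.4 mm focal path, minutes of heating) needs
millions of acoustic cells and is an opt-in, hours-long computation.  The
scaled variants keep the layered structure, the duty cycles and the
attenuation-per-wavelength of every medium while shrinking the problem to
a few wavelengths and a few seconds, so every stage of the pipeline runs
end-to-end in seconds-to-minutes and the qualitative orderings (duty-cycle
monotonicity, monolayer-vs-spheroid, pressure scaling) survive.

Scaling rule (factor ``scale`` = f0'/f0, default 0.05 -> 100 kHz):
frequency and all diffraction-relevant lengths shrink in wavelengths
(focal distance becomes ``focal_wavelengths`` lambda with the aperture
ratio a/d preserved); cell and glass layers keep their thickness in
wavelengths; the attenuation of every medium is evaluated at the
full-scale frequency and multiplied by ``scale`` so alpha * lambda is
unchanged; sonication shrinks to seconds with a 0.2 s burst period; and
every thermal conductivity is multiplied by
(lambda_full/lambda_scaled)^2 * (SD_full/SD_scaled) so the conduction
Fourier number -- which decides how much deposited heat is carried away
within one treatment, and with it the monolayer-vs-spheroid ordering --
matches the full-size problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (
    NumericsSection,
    OutputSection,
    ProtocolSection,
    RunConfig,
    ScenarioSection,
    SourceSection,
)
from .geometry import build_grid
from .scenarios import SCENARIO_TABLE, build_stack

__all__ = ["FixtureSpec", "make_study_scenarios", "make_scaled_scenario", "perturbed_scenario"]

FULL_F0 = 2.0e6
FULL_D = 51.4e-3
FULL_A = 16.5e-3
WATER_C0 = 1520.0


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic description of a generated fixture: base scenario,
    scale factor, and the seed used by randomised perturbation studies."""

    base: str
    scale: float = 0.05
    seed: int = 0


def make_study_scenarios() -> dict[str, RunConfig]:
    """The eight registered full-scale scenarios (six model-vs-experiment
    points, plus the two 30 %/0.661 MPa range-table points)."""
    out: dict[str, RunConfig] = {}
    for label, (configuration, dc, p0_mpa) in SCENARIO_TABLE.items():
        out[label] = RunConfig(
            scenario=ScenarioSection(label=label, configuration=configuration),
            source=SourceSection(p0=p0_mpa * 1.0e6, f0=FULL_F0, d=FULL_D, a=FULL_A),
            protocol=ProtocolSection(
                duty_cycle=dc / 100.0, burst_period=1.0, sonication_duration=300.0
            ),
            numerics=NumericsSection(),
            output=OutputSection(),
        ).validate()
    return out


def make_scaled_scenario(
    base: str,
    scale: float = 0.05,
    *,
    sonication_duration: float = 3.0,
    focal_wavelengths: float = 4.0,
    residual_tol: float = 1.0e-6,
) -> RunConfig:
    """Scaled desk-size variant of a registered scenario (see module
    docstring for the scaling rule).  Deterministic: identical arguments
    produce identical configs."""
    if base not in SCENARIO_TABLE:
        raise KeyError(f"unknown scenario {base!r}; choose from {list(SCENARIO_TABLE)}")
    if not (0 < scale < 1):
        raise ValueError("scale must be in (0, 1)")
    configuration, dc, p0_mpa = SCENARIO_TABLE[base]
    f0 = FULL_F0 * scale
    lam = WATER_C0 / f0
    d = focal_wavelengths * lam
    a = d * (FULL_A / FULL_D)
    cells_full = 15.0e-6 if configuration == "monolayer" else 117.0e-6
    cells = cells_full / scale  # thickness in wavelengths preserved
    glass = 170.0e-6 / scale
    medium = 0.5 * lam  # compressed so the focus stays reachable
    dish = 1.0 * lam  # deep enough to hold the absorbing layer
    water = d - medium - 0.5 * cells
    if water <= 0:
        raise ValueError("scale/focal_wavelengths leave no room for the water column")
    cfg = RunConfig(
        scenario=ScenarioSection(
            label=f"{base}_scaled{scale:g}",
            configuration=configuration,
            thickness_water=water,
            thickness_medium=medium,
            thickness_cells=cells,
            thickness_glass=glass,
            thickness_dish=dish,
            radial_extent=2.0 * lam,
        ),
        source=SourceSection(p0=p0_mpa * 1.0e6, f0=f0, d=d, a=a),
        protocol=ProtocolSection(
            duty_cycle=dc / 100.0,
            burst_period=0.2,
            sonication_duration=sonication_duration,
        ),
        numerics=NumericsSection(
            acoustic_residual=residual_tol,
            max_cycles=300,
            alpha_frequency=FULL_F0,
            alpha_scale=scale,
            # preserve the conduction Fourier number a_d SD / lambda^2 of
            # the full-size problem (see module docstring)
            k_scale=(1.0 / scale**2) * (300.0 / sonication_duration),
        ),
        output=OutputSection(record_every=0.1),
    ).validate()
    # desk-scale budget guard: the grid must stay small
    grid = build_grid(build_stack(cfg), f0, scale=tuple(cfg.numerics.grid_scale))
    if grid.n_cells > 1.0e5:
        raise ValueError(f"scaled grid has {grid.n_cells} cells (> 1e5 budget)")
    return cfg


def perturbed_scenario(base: str, seed: int, rel: float = 0.02, scale: float = 0.05) -> RunConfig:
    """Scaled scenario with material-free geometric jitter: layer
    thicknesses and source pressure perturbed by ~``rel`` relative, for
    sensitivity studies.  Same seed -> same config."""
    rng = np.random.default_rng(seed)
    cfg = make_scaled_scenario(base, scale=scale)
    sc = cfg.scenario
    factor = lambda: float(1.0 + rel * rng.standard_normal())
    sc.thickness_medium *= factor()
    sc.thickness_glass *= factor()
    sc.thickness_dish *= factor()
    cfg.source.p0 *= factor()
    sc.label = f"{base}_perturbed_seed{seed}"
    return cfg.validate()
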