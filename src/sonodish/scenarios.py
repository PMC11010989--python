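"""Scenario orchestration: acoustic solve -> Q_US -> thermal solve ->
reported metrics, for the registered study scenarios and parameter sweeps.

The registered scenarios are the simulated operating points of the study:
monolayer and spheroid cultures at duty cycles 15/30/55 % and source
pressures 0.433 / 0.661 MPa (six model-vs-experiment points plus the two
high-pressure 30 % points that only appear in the final-temperature-range
table).  The reported metrics per run are the cell-plane maximum
temperature at the end of sonication and the cell-plane (min; max) range,
whose width is the focal-to-surroundings temperature gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .acoustic import PulseProtocol, PMLConfig, SourceSpec, WesterveltSolver
from .bioheat import BioheatSolver, coarsen_q
from .config import RunConfig, SUMMARY_COLUMNS
from .geometry import Grid, LayerStack, build_grid
from .materials import medium_properties

__all__ = [
    "RunSummary",
    "SCENARIO_TABLE",
    "scenario_labels",
    "build_stack",
    "run_scenario",
    "summarize_cell_plane",
    "compare_to_experiment",
    "experiment_error_table",
    "final_range_gradients",
    "load_experiment_table",
    "load_range_table",
    "sweep",
]

# (configuration, DC %, p0 MPa); six model-vs-experiment points + the two
# high-pressure 30 % points of the final-range table.
SCENARIO_TABLE: dict[str, tuple[str, float, float]] = {
    "monolayer_dc15_p0433": ("monolayer", 15.0, 0.433),
    "monolayer_dc15_p0661": ("monolayer", 15.0, 0.661),
    "monolayer_dc30_p0433": ("monolayer", 30.0, 0.433),
    "spheroid_dc15_p0433": ("spheroid", 15.0, 0.433),
    "spheroid_dc30_p0433": ("spheroid", 30.0, 0.433),
    "spheroid_dc55_p0433": ("spheroid", 55.0, 0.433),
    "monolayer_dc30_p0661": ("monolayer", 30.0, 0.661),
    "spheroid_dc30_p0661": ("spheroid", 30.0, 0.661),
}

CORE_SCENARIOS = list(SCENARIO_TABLE)[:6]


def scenario_labels() -> list[str]:
    return list(SCENARIO_TABLE)


@dataclass
class RunSummary:
    """Per-run reported metrics plus convergence metadata."""

    label: str
    configuration: str
    dc_percent: float
    p0_mpa: float
    sd_s: float
    t_max_c: float
    t_min_c: float
    cycles: int = 0
    residual: float = float("nan")
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t_min_c > self.t_max_c + 1e-12:
            raise ValueError("t_min_c must not exceed t_max_c")

    @property
    def gradient_c(self) -> float:
        return self.t_max_c - self.t_min_c

    def to_row(self) -> dict:
        return {
            "label": self.label,
            "configuration": self.configuration,
            "dc_percent": self.dc_percent,
            "p0_mpa": self.p0_mpa,
            "sd_s": self.sd_s,
            "t_max_c": self.t_max_c,
            "t_min_c": self.t_min_c,
            "gradient_c": self.gradient_c,
            "cycles": self.cycles,
            "residual": self.residual,
        }


def _default_cells_thickness(configuration: str) -> float:
    return 15.0e-6 if configuration == "monolayer" else 117.0e-6


def _default_medium(configuration: str) -> str:
    return "DMEM" if configuration == "monolayer" else "Hydrogel"


def build_stack(cfg: RunConfig) -> LayerStack:
    """Layer stack from a config: cooling water, growth medium, cells,
    glass, dish bottom.  An unset water column is sized so the geometric
    focus z = d lands in the middle of the cell layer."""
    sc = cfg.scenario
    cells_t = (
        sc.thickness_cells
        if sc.thickness_cells is not None
        else _default_cells_thickness(sc.configuration)
    )
    medium_name = sc.medium if sc.medium is not None else _default_medium(sc.configuration)
    water_t = sc.thickness_water
    if water_t is None:
        water_t = cfg.source.d - sc.thickness_medium - 0.5 * cells_t
        if water_t <= 0:
            raise ValueError(
                "auto water column is non-positive; focal distance shorter than the stack"
            )
    layers = (
        (medium_properties("Water"), water_t),
        (medium_properties(medium_name), sc.thickness_medium),
        (medium_properties("Cells"), cells_t),
        (medium_properties("Glass"), sc.thickness_glass),
        (medium_properties("Petri Dish"), sc.thickness_dish),
    )
    return LayerStack(
        layers=layers,
        radial_extent=sc.radial_extent,
        sub_grid=frozenset({"Cells", "Glass"}),
    )


def summarize_cell_plane(
    T_field: np.ndarray, grid: Grid, radial_extent: float | None = None
) -> tuple[float, float, float]:
    """(T_min, T_max, gradient) over the cell-plane cells inside the dish
    radius.  The gradient (max - min) is the focal-to-surroundings
    temperature difference the range tables report."""
    cell_z = grid.layer_cells("Cells")
    plane = T_field[:, :, cell_z]
    rr = np.sqrt(grid.xc[:, None] ** 2 + grid.yc[None, :] ** 2)
    radius = radial_extent if radial_extent is not None else max(grid.xc[-1], grid.yc[-1])
    mask = rr <= radius + 1e-12
    values = plane[mask, :]
    t_min = float(values.min())
    t_max = float(values.max())
    return t_min, t_max, t_max - t_min


def run_scenario(cfg: RunConfig) -> RunSummary:
    """Execute one full acoustic -> Q_US -> thermal run for a config.

    Deterministic given the config: the steady acoustic solve is run for
    continuous ON drive, the duty-cycle gating switches the heat source in
    the thermal stage, and the summary is taken from the stored cell-plane
    field with no further post-processing."""
    cfg.validate()
    sc, so, pr, nu = cfg.scenario, cfg.source, cfg.protocol, cfg.numerics
    try:
        stack = build_stack(cfg)
        grid = build_grid(stack, so.f0, scale=tuple(nu.grid_scale))
        src = SourceSpec(
            p0=so.p0, f0=so.f0, d=so.d, a=so.a, c0=stack.reference_medium.c0
        )
        prot = PulseProtocol(
            duty_cycle=pr.duty_cycle,
            burst_period=pr.burst_period,
            sonication_duration=pr.sonication_duration,
            gating=pr.gating,
        )
        solver = WesterveltSolver(
            grid,
            src,
            dt=nu.acoustic_dt,
            theta=nu.theta,
            nonlinear=nu.nonlinear,
            pml=PMLConfig(
                nodes=nu.pml_nodes,
                target_reflection=nu.pml_target_reflection,
                lateral=nu.pml_lateral,
            ),
            alpha_frequency=nu.alpha_frequency,
            alpha_scale=nu.alpha_scale,
            ramp_cycles=nu.ramp_cycles,
        )
        q_field = solver.run_to_steady_state(
            residual_tol=nu.acoustic_residual, max_cycles=nu.max_cycles
        )
        q = q_field.q_us
        thermal_grid = grid
        if nu.thermal_xy_coarsen > 1:
            q = coarsen_q(q, nu.thermal_xy_coarsen)
            thermal_grid = _coarsen_grid(grid, nu.thermal_xy_coarsen)
        heat = BioheatSolver(
            thermal_grid, q, prot, dt=nu.thermal_dt,
            boundary=nu.thermal_boundary, k_scale=nu.k_scale,
        )
        history = heat.run(record_every=cfg.output.record_every)
        t_min, t_max, _ = summarize_cell_plane(
            history.T_final, thermal_grid, sc.radial_extent
        )
    except Exception as exc:
        raise RuntimeError(f"scenario {sc.label!r} failed: {exc}") from exc
    return RunSummary(
        label=sc.label,
        configuration=sc.configuration,
        dc_percent=100.0 * pr.duty_cycle,
        p0_mpa=so.p0 / 1.0e6,
        sd_s=pr.sonication_duration,
        t_max_c=t_max,
        t_min_c=t_min,
        cycles=q_field.cycles,
        residual=q_field.residual,
        extras={"focal_p_amp_pa": float(q_field.p_amp.max())},
    )


def _coarsen_grid(grid: Grid, factor: int) -> Grid:
    if grid.nx % factor or grid.ny % factor:
        raise ValueError("grid not divisible by thermal coarsening factor")
    return Grid(
        dx=grid.dx * factor,
        dy=grid.dy * factor,
        z_edges=grid.z_edges,
        nx=grid.nx // factor,
        ny=grid.ny // factor,
        lambda0=grid.lambda0,
        f0=grid.f0,
        media=grid.media,
        mat_z=grid.mat_z,
    )


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("sonodish.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_experiment_table() -> pd.DataFrame:
    """Packaged experimental-vs-numerical maximum-temperature table."""
    return _read_csv("max_temperature_comparison.csv")


def load_range_table() -> pd.DataFrame:
    """Packaged final cell-plane temperature ranges."""
    return _read_csv("final_temperature_ranges.csv")


def _relative_error(t_exp, t_model, relative_to: str):
    if relative_to == "experimental":
        return np.abs(t_exp - t_model) / np.abs(t_exp) * 100.0
    if relative_to == "numerical":
        return np.abs(t_exp - t_model) / np.abs(t_model) * 100.0
    raise ValueError("relative_to must be 'experimental' or 'numerical'")


def experiment_error_table(relative_to: str = "experimental") -> pd.DataFrame:
    """Recompute the model-vs-experiment error column from the packaged
    temperature pairs.  Two denominator conventions are shipped because
    the printed column is not consistent with a single one (see
    docs/methods.md)."""
    df = load_experiment_table().copy()
    df["error_recomputed_pct"] = _relative_error(
        df["t_exp_c"].to_numpy(), df["t_num_c"].to_numpy(), relative_to
    )
    return df


def final_range_gradients() -> pd.DataFrame:
    """Focal-to-surroundings gradients: the widths of the packaged final
    cell-plane temperature ranges."""
    df = load_range_table().copy()
    df["gradient_c"] = df["t_final_max_c"] - df["t_final_min_c"]
    return df


def compare_to_experiment(
    summaries, relative_to: str = "experimental"
) -> pd.DataFrame:
    """Join computed run summaries against the packaged experimental
    maxima and report per-row relative error (%) and the maximum error.

    Rows of the experiment table with no matching summary are kept and
    flagged (``matched = False``) rather than dropped."""
    table = load_experiment_table().copy()
    by_key = {}
    for s in summaries:
        by_key[(s.configuration, round(s.dc_percent, 6), round(s.p0_mpa, 6))] = s
    t_model, matched = [], []
    for _, row in table.iterrows():
        key = (row["configuration"], round(row["dc_percent"], 6), round(row["p0_mpa"], 6))
        s = by_key.get(key)
        matched.append(s is not None)
        t_model.append(s.t_max_c if s is not None else np.nan)
    table["t_model_c"] = t_model
    table["matched"] = matched
    table["error_model_pct"] = _relative_error(
        table["t_exp_c"].to_numpy(), table["t_model_c"].to_numpy(), relative_to
    )
    return table


def sweep(configs) -> pd.DataFrame:
    """Run every config; one summary row per point, in input order.
    Failed runs are recorded with their error message, not dropped."""
    rows = []
    for cfg in configs:
        try:
            summary = run_scenario(cfg)
            row = summary.to_row()
            row["error"] = ""
        except Exception as exc:  # recorded, not silently dropped
            row = {c: np.nan for c in SUMMARY_COLUMNS}
            row["label"] = cfg.scenario.label
            row["configuration"] = cfg.scenario.configuration
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS + ["error"])
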