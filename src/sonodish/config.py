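"""Run configuration: a documented, validated, YAML-backed description of
one simulated sonication.

A config has five sections -- scenario (layer stack and culture
configuration), source (transducer drive), protocol (burst timing),
numerics (grid/time-step/solver settings) and output.  Unknown keys are
rejected so a typo cannot silently fall back to a default; every field
has a documented default so a minimal config (a scenario label and
configuration) is complete.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "ScenarioSection",
    "SourceSection",
    "ProtocolSection",
    "NumericsSection",
    "OutputSection",
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "config_hash",
    "write_summary",
    "read_summary",
    "SUMMARY_COLUMNS",
]


class ConfigError(ValueError):
    """Validation failure; the message names the offending key path."""


@dataclass
class ScenarioSection:
    """Layer stack description.  Thickness ``None`` means auto: the water
    column fills the transducer-to-cells standoff so the geometric focus
    lands in the cell layer; the cell layer defaults to 15 um (monolayer)
    or 117 um (spheroid); the growth medium defaults to DMEM (monolayer)
    or Hydrogel (spheroid)."""

    label: str = "custom"
    configuration: str = "monolayer"
    medium: str | None = None
    thickness_water: float | None = None
    thickness_medium: float = 2.0e-3
    thickness_cells: float | None = None
    thickness_glass: float = 170.0e-6
    thickness_dish: float = 1.0e-3
    radial_extent: float = 18.0e-3


@dataclass
class SourceSection:
    """Transducer drive: surface pressure (Pa), fundamental (Hz), focal
    distance and aperture radius (m)."""

    p0: float = 0.433e6
    f0: float = 2.0e6
    d: float = 51.4e-3
    a: float = 16.5e-3


@dataclass
class ProtocolSection:
    duty_cycle: float = 0.15
    burst_period: float = 1.0
    sonication_duration: float = 300.0
    gating: str = "gated"


@dataclass
class NumericsSection:
    """Solver knobs.  grid_scale multiplies the (0.2, 0.2, 0.1) lambda
    spacings; alpha_frequency/alpha_scale re-anchor the attenuation law
    (used by scaled fixtures to preserve attenuation-per-wavelength)."""

    grid_scale: list = field(default_factory=lambda: [1.0, 1.0, 1.0])
    acoustic_dt: float | None = None
    thermal_dt: float = 0.01
    acoustic_residual: float = 1.0e-8
    max_cycles: int = 400
    pml_nodes: int = 8
    pml_target_reflection: float = 1.0e-4
    pml_lateral: bool = True
    theta: float = 0.25
    nonlinear: bool = True
    alpha_frequency: float | None = None
    alpha_scale: float = 1.0
    ramp_cycles: float = 3.0
    thermal_xy_coarsen: int = 1
    k_scale: float = 1.0
    thermal_boundary: str = "dish"


@dataclass
class OutputSection:
    out_dir: str | None = None
    record_every: float = 0.1


_SECTION_TYPES = {
    "scenario": ScenarioSection,
    "source": SourceSection,
    "protocol": ProtocolSection,
    "numerics": NumericsSection,
    "output": OutputSection,
}


@dataclass
class RunConfig:
    scenario: ScenarioSection = field(default_factory=ScenarioSection)
    source: SourceSection = field(default_factory=SourceSection)
    protocol: ProtocolSection = field(default_factory=ProtocolSection)
    numerics: NumericsSection = field(default_factory=NumericsSection)
    output: OutputSection = field(default_factory=OutputSection)

    def validate(self) -> "RunConfig":
        sc, so, pr, nu = self.scenario, self.source, self.protocol, self.numerics
        if sc.configuration not in ("monolayer", "spheroid"):
            raise ConfigError(
                f"scenario.configuration must be monolayer|spheroid, got {sc.configuration!r}"
            )
        for key in ("thickness_medium", "thickness_glass", "thickness_dish", "radial_extent"):
            if not (getattr(sc, key) > 0):
                raise ConfigError(f"scenario.{key} must be > 0")
        for key in ("thickness_water", "thickness_cells"):
            v = getattr(sc, key)
            if v is not None and not (v > 0):
                raise ConfigError(f"scenario.{key} must be > 0 or null")
        for key in ("p0", "f0", "d", "a"):
            if not (getattr(so, key) > 0):
                raise ConfigError(f"source.{key} must be > 0")
        if not (so.a < so.d):
            raise ConfigError("source.a must be smaller than source.d")
        if not (0 < pr.duty_cycle <= 1):
            raise ConfigError("protocol.duty_cycle must be in (0, 1]")
        if not (pr.burst_period > 0):
            raise ConfigError("protocol.burst_period must be > 0")
        if pr.sonication_duration < 0:
            raise ConfigError("protocol.sonication_duration must be >= 0")
        if pr.gating not in ("gated", "averaged"):
            raise ConfigError("protocol.gating must be gated|averaged")
        if len(nu.grid_scale) != 3 or any(s <= 0 for s in nu.grid_scale):
            raise ConfigError("numerics.grid_scale must be three positive factors")
        for key in ("thermal_dt", "acoustic_residual", "pml_target_reflection", "alpha_scale", "k_scale"):
            if not (getattr(nu, key) > 0):
                raise ConfigError(f"numerics.{key} must be > 0")
        if nu.thermal_boundary not in ("dish", "dirichlet", "insulated"):
            raise ConfigError("numerics.thermal_boundary must be dish|dirichlet|insulated")
        if nu.max_cycles < 1 or nu.pml_nodes < 4 or nu.thermal_xy_coarsen < 1:
            raise ConfigError("numerics: max_cycles >= 1, pml_nodes >= 4, thermal_xy_coarsen >= 1")
        return self

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {name: dataclasses.asdict(getattr(self, name)) for name in _SECTION_TYPES}

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
        unknown = set(data) - set(_SECTION_TYPES)
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
        sections = {}
        for name, typ in _SECTION_TYPES.items():
            payload = data.get(name, {}) or {}
            if not isinstance(payload, dict):
                raise ConfigError(f"section {name!r} must be a mapping")
            valid = {f.name for f in dataclasses.fields(typ)}
            bad = set(payload) - valid
            if bad:
                raise ConfigError(f"unknown key(s) in section {name!r}: {sorted(bad)}")
            sections[name] = typ(**payload)
        return cls(**sections).validate()


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run config."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: YAML parse error: {exc}") from exc
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the fully resolved config (reproducibility log)."""
    canon = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


SUMMARY_COLUMNS = [
    "label",
    "configuration",
    "dc_percent",
    "p0_mpa",
    "sd_s",
    "t_max_c",
    "t_min_c",
    "gradient_c",
    "cycles",
    "residual",
]


def write_summary(summaries, path: str | Path) -> None:
    """Write run summaries as CSV with the fixed documented column order.

    Accepts a single summary or an iterable; an empty iterable produces a
    header-only file."""
    if hasattr(summaries, "to_row"):
        summaries = [summaries]
    rows = [s.to_row() for s in summaries]
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df.to_csv(path, index=False)


def read_summary(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != SUMMARY_COLUMNS:
        raise ConfigError(f"{path}: unexpected summary columns {list(df.columns)}")
    return df
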