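"""Acoustic and thermal material properties of the culture-dish layers.

The simulated Petri dish is a stack of media — cooling water, cell growth
medium (DMEM for monolayers, hydrogel/RPMI for spheroids), the cell layer
itself, the glass coverslip and the polymer dish bottom.  Each medium is
described by its density ``rho``, sound speed ``c0``, specific heat ``C``,
thermal conductivity ``k``, and a power-law acoustic attenuation
``alpha(f) = alpha_ref * (f / f_ref) ** eta`` referenced to 1 MHz, plus the
nonlinearity parameter B/A.  Fluid-like biological media with no published
acoustic constants take water's values, the usual approximation for dilute
aqueous media.

The property table ships as ``data/materials.csv``; the loader checks it
against the hard-coded reference values so a corrupted data file cannot
silently change the physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import pandas as pd

__all__ = [
    "MediumLayer",
    "medium_properties",
    "available_media",
    "acoustic_impedance",
    "attenuation_coefficient",
    "acoustic_diffusivity",
    "nonlinearity_coefficient",
    "load_material_table",
]

F_REF_DEFAULT = 1.0e6  # Hz, reference frequency of the attenuation power law


@dataclass(frozen=True)
class MediumLayer:
    """One medium of the layer stack with its acoustic + thermal constants.

    Units: ``rho`` kg/m^3, ``c0`` m/s, ``C`` J/(kg K), ``k`` W/(m K),
    ``alpha_ref`` Np/m at ``f_ref`` Hz, ``eta`` and ``BA`` dimensionless.
    ``alpha_ref``/``eta``/``BA`` may be ``None`` for fluid-like media; the
    registry resolves those to water's values.
    """

    name: str
    rho: float
    c0: float
    C: float
    k: float
    alpha_ref: float | None = None
    eta: float | None = None
    BA: float | None = None
    f_ref: float = F_REF_DEFAULT

    def __post_init__(self) -> None:
        for field in ("rho", "c0", "C", "k"):
            value = getattr(self, field)
            if not (value > 0):
                raise ValueError(f"{self.name}: {field} must be > 0, got {value!r}")
        if self.alpha_ref is not None and self.alpha_ref < 0:
            raise ValueError(f"{self.name}: alpha_ref must be >= 0")
        if self.eta is not None and self.eta < 0:
            raise ValueError(f"{self.name}: eta must be >= 0")
        if not (self.f_ref > 0):
            raise ValueError(f"{self.name}: f_ref must be > 0")

    @property
    def impedance(self) -> float:
        """Characteristic acoustic impedance Z = rho * c0 in kg/(m^2 s)."""
        return self.rho * self.c0

    def alpha(self, f: float) -> float:
        """Attenuation coefficient at frequency ``f`` (Np/m)."""
        return attenuation_coefficient(self, f)


# Reference values; the packaged CSV must agree with these.
_TABLE: dict[str, dict[str, float | None]] = {
    "Water": dict(rho=1000.0, C=4180.0, k=0.615, c0=1520.0, alpha_ref=2.8e-4, BA=3.5, eta=2.0),
    "DMEM": dict(rho=1023.0, C=3800.0, k=0.13, c0=1560.0, alpha_ref=None, BA=None, eta=None),
    "Hydrogel": dict(rho=1060.0, C=3770.0, k=0.53, c0=1560.0, alpha_ref=None, BA=None, eta=None),
    "Cells": dict(rho=1066.0, C=3610.0, k=0.442, c0=1423.0, alpha_ref=0.57, BA=None, eta=0.75),
    "Glass": dict(rho=2500.0, C=880.0, k=1.1, c0=4500.0, alpha_ref=0.27, BA=6.8, eta=1.32),
    "Petri Dish": dict(rho=1000.0, C=1350.0, k=0.165, c0=2000.0, alpha_ref=0.27, BA=6.8, eta=1.32),
}

_ALIASES = {
    "water": "Water",
    "dmem": "DMEM",
    "hydrogel": "Hydrogel",
    "cells": "Cells",
    "glass": "Glass",
    "petridish": "Petri Dish",
    "petri dish": "Petri Dish",
}


def _canonical(name: str) -> str:
    key = name.strip().lower().replace("_", " ")
    key = key.replace(" ", "") if key.replace(" ", "") == "petridish" else key
    if key in _ALIASES:
        return _ALIASES[key]
    raise KeyError(
        f"unknown medium {name!r}; valid media: {sorted(set(_ALIASES.values()))}"
    )


def available_media() -> list[str]:
    return sorted(set(_ALIASES.values()))


def load_material_table(validate: bool = True) -> pd.DataFrame:
    """Load the packaged material table (columns: layer, rho, C, k, c0,
    alpha_ref, BA, eta).  With ``validate`` the values are checked against
    the in-code reference table."""
    with resources.files("sonodish.data").joinpath("materials.csv").open() as fh:
        df = pd.read_csv(fh)
    expected_cols = ["layer", "rho", "C", "k", "c0", "alpha_ref", "BA", "eta"]
    if list(df.columns) != expected_cols:
        raise ValueError(f"material table columns {list(df.columns)} != {expected_cols}")
    if validate:
        for _, row in df.iterrows():
            ref = _TABLE[row["layer"]]
            for col in ("rho", "C", "k", "c0", "alpha_ref", "BA", "eta"):
                got = row[col]
                want = ref[col]
                if want is None:
                    if not pd.isna(got):
                        raise ValueError(f"{row['layer']}.{col}: expected blank, got {got}")
                elif not math.isclose(float(got), want, rel_tol=1e-12):
                    raise ValueError(f"{row['layer']}.{col}: {got} != {want}")
    return df


def medium_properties(name: str) -> MediumLayer:
    """Return the named medium with unset acoustic fields filled from water.

    Media without published attenuation/nonlinearity data (DMEM, hydrogel)
    are acoustically water-like, so their ``alpha_ref``, ``eta`` and ``BA``
    resolve to water's values; the cell layer keeps its own attenuation law
    but takes water's B/A.
    """
    canonical = _canonical(name)
    raw = _TABLE[canonical]
    water = _TABLE["Water"]
    layer = MediumLayer(
        name=canonical,
        rho=float(raw["rho"]),
        c0=float(raw["c0"]),
        C=float(raw["C"]),
        k=float(raw["k"]),
        alpha_ref=float(raw["alpha_ref"] if raw["alpha_ref"] is not None else water["alpha_ref"]),
        eta=float(raw["eta"] if raw["eta"] is not None else water["eta"]),
        BA=float(raw["BA"] if raw["BA"] is not None else water["BA"]),
    )
    return layer


def acoustic_impedance(layer: MediumLayer) -> float:
    """Z = rho * c0, kg/(m^2 s)."""
    return layer.rho * layer.c0


def attenuation_coefficient(layer: MediumLayer, f: float) -> float:
    """Power-law attenuation alpha = alpha_ref * (f/f_ref)**eta (Np/m)."""
    if not (f > 0):
        raise ValueError(f"frequency must be > 0, got {f!r}")
    alpha_ref = layer.alpha_ref if layer.alpha_ref is not None else 0.0
    eta = layer.eta if layer.eta is not None else 0.0
    return alpha_ref * (f / layer.f_ref) ** eta


def acoustic_diffusivity(layer: MediumLayer, omega: float) -> float:
    """Sound diffusivity delta = 2 c0^3 alpha / omega^2 (m^2/s).

    This is the thermoviscous diffusivity that makes the loss term of the
    nonlinear wave equation reproduce the power-law attenuation at the
    drive frequency: a plane wave then decays as exp(-alpha z) with
    alpha = delta * omega^2 / (2 c0^3).
    """
    if not (omega > 0):
        raise ValueError(f"omega must be > 0, got {omega!r}")
    alpha = attenuation_coefficient(layer, omega / (2.0 * math.pi))
    return 2.0 * layer.c0**3 * alpha / omega**2


def nonlinearity_coefficient(layer: MediumLayer) -> float:
    """beta = 1 + B/(2A)."""
    ba = layer.BA if layer.BA is not None else 0.0
    return 1.0 + 0.5 * ba


def with_overrides(layer: MediumLayer, **kwargs) -> MediumLayer:
    """Copy of ``layer`` with selected fields replaced (sensitivity hooks)."""
    return replace(layer, **kwargs)
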