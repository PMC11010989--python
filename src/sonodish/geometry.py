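"""Layered Petri-dish geometry and the finite-volume simulation lattice.

The computational domain is a rectangular box spanning one quarter of the
dish (mirror symmetry planes at x=0 and y=0), with the beam axis along z
and z=0 at the transducer surface plane.  Materials vary only along z: the
stack runs transducer -> cooling water -> growth medium -> cells -> glass
-> dish bottom.  The lattice is cell-centred; spacings follow the
resolution rule dx = dy = 0.2 lambda, dz = 0.1 lambda of the driving
wavelength in the reference medium (cooling water), optionally scaled.

Layers thinner than dz (the 15 um cell monolayer) must be explicitly
flagged ``sub_grid``; they are then resolved as a single thin cell of
their true thickness, a local dz refinement, because the reported metric
is the temperature in the cell plane itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import MediumLayer

__all__ = ["LayerStack", "Grid", "build_grid"]


@dataclass(frozen=True)
class LayerStack:
    """Ordered media from the transducer surface downward.

    ``layers`` is a list of ``(MediumLayer, thickness_m)``;
    ``radial_extent`` is the half-width of the simulated quarter domain;
    ``sub_grid`` names layers allowed to be thinner than dz.
    """

    layers: tuple[tuple[MediumLayer, float], ...]
    radial_extent: float
    sub_grid: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("LayerStack needs at least one layer")
        for medium, thickness in self.layers:
            if not (thickness > 0):
                raise ValueError(f"layer {medium.name}: thickness must be > 0")
        if not (self.radial_extent > 0):
            raise ValueError("radial_extent must be > 0")

    @property
    def depth(self) -> float:
        return float(sum(t for _, t in self.layers))

    @property
    def reference_medium(self) -> MediumLayer:
        """Medium defining the grid wavelength: the first (cooling-water) layer."""
        return self.layers[0][0]

    def thickness_of(self, name: str) -> float:
        for medium, thickness in self.layers:
            if medium.name == name:
                return thickness
        raise KeyError(f"no layer named {name!r}")


@dataclass
class Grid:
    """Cell-centred rectilinear lattice over the quarter domain.

    x/y cells are uniform (``dx``, ``dy``); z cells are non-uniform
    (``z_edges`` has nz+1 entries).  ``mat_z`` maps each z cell to an index
    into ``media``; materials do not vary within an xy plane.
    """

    dx: float
    dy: float
    z_edges: np.ndarray
    nx: int
    ny: int
    lambda0: float
    f0: float
    media: list[MediumLayer]
    mat_z: np.ndarray  # (nz,) int index into media

    @property
    def nz(self) -> int:
        return len(self.mat_z)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.z_edges)

    @property
    def zc(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def xc(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.dx

    @property
    def yc(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dy

    @property
    def depth(self) -> float:
        return float(self.z_edges[-1])

    def prop_z(self, name: str, default: float | None = None) -> np.ndarray:
        """Per-z-cell array of a material attribute (e.g. 'rho', 'c0')."""
        values = []
        for m in self.media:
            v = getattr(m, name)
            if v is None:
                if default is None:
                    raise ValueError(f"medium {m.name} has no {name}")
                v = default
            values.append(v)
        return np.asarray(values, dtype=float)[self.mat_z]

    def layer_cells(self, name: str) -> np.ndarray:
        """z indices of the cells belonging to the named layer."""
        idx = [i for i, m in enumerate(self.media) if m.name == name]
        if not idx:
            raise KeyError(f"no layer named {name!r}")
        return np.where(np.isin(self.mat_z, idx))[0]

    def material_name_z(self) -> list[str]:
        return [self.media[i].name for i in self.mat_z]


def build_grid(
    stack: LayerStack,
    f0: float,
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Grid:
    """Discretise the stack at dx = dy = 0.2 lambda, dz = 0.1 lambda.

    ``scale`` multiplies the three default spacings (coarser fixtures use
    scale > 1, convergence studies scale < 1).  Every layer interface is
    snapped to a cell face: each layer is meshed with an integer number of
    equal cells of size closest to the target dz.  A layer thinner than the
    target dz raises unless flagged sub_grid, in which case it becomes one
    thin cell of its true thickness.
    """
    if not (f0 > 0):
        raise ValueError("f0 must be > 0")
    lambda0 = stack.reference_medium.c0 / f0
    dx = 0.2 * lambda0 * scale[0]
    dy = 0.2 * lambda0 * scale[1]
    dz_target = 0.1 * lambda0 * scale[2]

    media: list[MediumLayer] = []
    mat_z: list[int] = []
    edges = [0.0]
    for layer_idx, (medium, thickness) in enumerate(stack.layers):
        media.append(medium)
        if thickness < dz_target and medium.name not in stack.sub_grid:
            raise ValueError(
                f"layer {medium.name} ({thickness:.3e} m) is thinner than dz "
                f"({dz_target:.3e} m) and not flagged sub_grid"
            )
        if thickness < dz_target:
            n = 1
        else:
            n = max(1, int(round(thickness / dz_target)))
        h = thickness / n
        for _ in range(n):
            edges.append(edges[-1] + h)
            mat_z.append(layer_idx)

    nx = max(1, int(round(stack.radial_extent / dx)))
    ny = max(1, int(round(stack.radial_extent / dy)))
    return Grid(
        dx=dx,
        dy=dy,
        z_edges=np.asarray(edges),
        nx=nx,
        ny=ny,
        lambda0=lambda0,
        f0=f0,
        media=media,
        mat_z=np.asarray(mat_z, dtype=int),
    )
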