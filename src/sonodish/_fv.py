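"""Finite-volume operator assembly shared by the wave and heat solvers.

Both solvers discretise a divergence-form operator div(w grad u) on the
same cell-centred lattice (uniform x/y, non-uniform z, material varying
only along z).  The 3D operator separates into Kronecker products of 1D
operators; Dirichlet boundaries contribute an affine vector holding the
coefficient that multiplies the prescribed boundary value.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

MIRROR = "mirror"
DIRICHLET = "dirichlet"


def axis_operator(
    dz: np.ndarray,
    w: np.ndarray,
    bc_low: str,
    bc_high: str,
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """1D cell-centred div(w grad) operator along one axis.

    ``dz``: cell sizes (n,), ``w``: cell diffusivity-like weight (n,).
    Interior face weights are distance-weighted harmonic means, which keeps
    the flux continuous across material interfaces.  Returns the (n, n)
    matrix plus affine coefficient vectors ``b_low``/``b_high``: for a
    Dirichlet face value g the operator contribution is ``D @ u + b * g``.
    Mirror faces are zero-flux (symmetry planes).
    """
    n = len(dz)
    dz = np.asarray(dz, dtype=float)
    w = np.broadcast_to(np.asarray(w, dtype=float), (n,))
    diag = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    for i in range(n - 1):
        delta = 0.5 * (dz[i] + dz[i + 1])
        wf = delta / (0.5 * dz[i] / w[i] + 0.5 * dz[i + 1] / w[i + 1])
        # flux wf*(u[i+1]-u[i])/delta through the shared face
        upper[i] += wf / (delta * dz[i])
        diag[i] -= wf / (delta * dz[i])
        lower[i] += wf / (delta * dz[i + 1])
        diag[i + 1] -= wf / (delta * dz[i + 1])
    b_low = np.zeros(n)
    b_high = np.zeros(n)
    if bc_low == DIRICHLET:
        coef = w[0] / (0.5 * dz[0] * dz[0])
        diag[0] -= coef
        b_low[0] = coef
    elif bc_low != MIRROR:
        raise ValueError(f"unknown bc {bc_low!r}")
    if bc_high == DIRICHLET:
        coef = w[-1] / (0.5 * dz[-1] * dz[-1])
        diag[-1] -= coef
        b_high[-1] = coef
    elif bc_high != MIRROR:
        raise ValueError(f"unknown bc {bc_high!r}")
    D = sp.diags([lower, diag, upper], offsets=[-1, 0, 1], format="csr")
    return D, b_low, b_high


def assemble_weighted_laplacian(
    nx: int,
    ny: int,
    dx: float,
    dy: float,
    dz: np.ndarray,
    w_z: np.ndarray,
    bc_lateral_low: str = MIRROR,
    bc_lateral_high: str = DIRICHLET,
    bc_z_low: str = DIRICHLET,
    bc_z_high: str = DIRICHLET,
) -> tuple[sp.csr_matrix, np.ndarray, dict[str, np.ndarray]]:
    """3D div(w grad) on the (nx, ny, nz) lattice, C-ordered flat index.

    ``w_z`` is the per-z-cell weight (1/rho for the wave operator, k for
    conduction); it multiplies the transverse stencil of its plane.
    Returns (L, affine) where ``affine`` maps boundary names
    ('z_low', 'z_high', 'lateral') to flattened affine coefficient arrays
    (per-cell factor multiplying the prescribed face value).
    """
    nz = len(dz)
    Dx, bx_lo, bx_hi = axis_operator(np.full(nx, dx), np.ones(nx), bc_lateral_low, bc_lateral_high)
    Dy, by_lo, by_hi = axis_operator(np.full(ny, dy), np.ones(ny), bc_lateral_low, bc_lateral_high)
    Dz, bz_lo, bz_hi = axis_operator(dz, w_z, bc_z_low, bc_z_high)
    Ix = sp.identity(nx, format="csr")
    Iy = sp.identity(ny, format="csr")
    Wz = sp.diags(w_z, format="csr")
    L = (
        sp.kron(sp.kron(Dx, Iy), Wz)
        + sp.kron(sp.kron(Ix, Dy), Wz)
        + sp.kron(sp.kron(Ix, Iy), Dz)
    ).tocsr()

    ones_x = np.ones(nx)
    ones_y = np.ones(ny)
    ones_z = np.ones(nz)
    lateral = (
        np.einsum("i,j,k->ijk", bx_hi, ones_y, w_z)
        + np.einsum("i,j,k->ijk", ones_x, by_hi, w_z)
    ).ravel()
    z_low = np.einsum("i,j,k->ijk", ones_x, ones_y, bz_lo).ravel()
    z_high = np.einsum("i,j,k->ijk", ones_x, ones_y, bz_hi).ravel()
    affine = {"lateral": lateral, "z_low": z_low, "z_high": z_high}
    return L, affine
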