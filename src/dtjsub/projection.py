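"""Projected current density from a single measured Bz.

One measurable flux-density component cannot determine the full 3-D current,
but its in-plane, divergence-free part can.  Starting from the current J0 of
a homogeneous reference conductor carrying the same electrode current, the
recoverable ("projected") current is

    Jp = J0 + curl2(psi),    curl2(psi) = (d psi/dy, -d psi/dx, 0),

where the stream correction psi solves the 2-D Poisson problem

    lap2(psi) = (1/mu0) lap2(Bz - Bz0)   in the slice,
    curl2(psi) . nu = 0                  on its boundary,

i.e. psi is constant along each boundary component (taken 0 on the outer
boundary), so the correction carries no normal flux and Jp inherits the
electrode boundary data of J0.  Subtracting the reference Bz0 — synthesized
by the same Biot-Savart operator — removes the harmonic background and
cancels the shared discretization error of the field synthesis.

Discretely, psi lives on cell corners (nodes); the correction face fluxes are
pure differences of node values, so their divergence vanishes identically and
Jp is conservative wherever J0 is.  When the true current is in-plane and
z-invariant and Bz is noise-free, Jp recovers J up to discretization error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .forward import (MU0, CurrentDensityField, FluxDensityField,
                      PotentialField, biot_savart_bz, compute_current_density,
                      solve_potential)
from .grids import ConductivityTensorField, ElectrodeConfiguration, VoxelGrid

logger = logging.getLogger("dtjsub")


@dataclass
class HomogeneousReference:
    """Homogeneous-conductor reference solve: u0, J0 = -sigma0 grad u0, Bz0."""

    sigma0: float
    u0: PotentialField
    J0: CurrentDensityField
    Bz0: FluxDensityField


@dataclass
class StreamCorrection:
    """Stream-function correction psi (A/m) on grid nodes and its curl."""

    grid: VoxelGrid
    psi: np.ndarray          # (nx+1, ny+1) node values, 0 on/outside boundary
    corr_x: np.ndarray       # cell-centered d psi/dy  (A/m^2)
    corr_y: np.ndarray       # cell-centered -d psi/dx (A/m^2)


def initial_current(grid: VoxelGrid, electrodes: ElectrodeConfiguration,
                    sigma0: float, slab_thickness_mm: float = None,
                    bz_at: str = "nodes") -> HomogeneousReference:
    """Solve the homogeneous isotropic reference problem and synthesize Bz0.

    Because the boundary data prescribe the current directly, J0 does not
    depend on the value of sigma0 (only u0 scales by 1/sigma0).  ``bz_at``
    chooses where Bz0 is sampled; the default ("nodes") matches the
    stream-function discretization of :func:`solve_psi`.
    """
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    C0 = ConductivityTensorField.isotropic(grid, sigma0)
    u0 = solve_potential(C0, electrodes, grid)
    J0 = compute_current_density(C0, u0, grid, electrodes=electrodes,
                                 provenance="initial")
    Bz0 = biot_savart_bz(J0, grid, slab_thickness_mm=slab_thickness_mm,
                         at=bz_at)
    return HomogeneousReference(sigma0=sigma0, u0=u0, J0=J0, Bz0=Bz0)


def _node_interior(grid: VoxelGrid):
    """Nodes strictly interior to the mask (all 4 surrounding cells in-mask)."""
    m = grid.domain_mask
    nx, ny = grid.shape
    node_in = np.zeros((nx + 1, ny + 1), dtype=bool)
    node_in[1:nx, 1:ny] = (m[:-1, :-1] & m[1:, :-1] & m[:-1, 1:] & m[1:, 1:])
    return node_in


def _cells_to_nodes(a: np.ndarray) -> np.ndarray:
    """Cubic-spline resampling of a cell-centered field to the grid nodes,
    with quadratic extrapolation on the outermost node ring.  Only used when
    the measured Bz is not already co-registered with the nodes; accuracy at
    the domain boundary is limited because the field kinks there."""
    nx, ny = a.shape
    ni, nj = np.meshgrid(np.arange(nx + 1) - 0.5, np.arange(ny + 1) - 0.5,
                         indexing="ij")
    out = ndimage.map_coordinates(a, [ni, nj], order=3, mode="nearest")
    out[0, :] = 3 * out[1, :] - 3 * out[2, :] + out[3, :]
    out[-1, :] = 3 * out[-2, :] - 3 * out[-3, :] + out[-4, :]
    out[:, 0] = 3 * out[:, 1] - 3 * out[:, 2] + out[:, 3]
    out[:, -1] = 3 * out[:, -2] - 3 * out[:, -3] + out[:, -4]
    return out


def solve_psi(Bz_measured: FluxDensityField, reference: HomogeneousReference,
              grid: VoxelGrid, smooth_sd: float = 0.0) -> StreamCorrection:
    """Solve the 2-D stream-correction Poisson problem from measured Bz.

    The right-hand side is the in-plane Laplacian of (Bz - Bz0)/mu0 on the
    grid nodes, optionally Gaussian-presmoothed (``smooth_sd`` in voxels)
    for noisy data.  psi is solved on interior grid nodes with psi = 0 on
    the boundary (implementing the zero-normal-flux condition exactly on
    grid-aligned boundaries) and the correction is returned both as node
    differences (used for conservative face fluxes) and cell-centered
    components.

    ``Bz_measured`` may be sampled on the grid nodes (shape (nx+1, ny+1),
    the dual grid of :func:`biot_savart_bz` with ``at="nodes"``; preferred —
    the discretization is then fully co-registered) or at voxel centers
    (shape (nx, ny); resampled internally).  The reference Bz0 must be
    sampled the same way.
    """
    nx, ny = grid.shape
    dx = grid.spacing[0] * 1e-3
    dy = grid.spacing[1] * 1e-3
    if Bz_measured.Bz.shape != reference.Bz0.Bz.shape:
        raise ValueError("measured and reference Bz sampled differently")
    delta = Bz_measured.Bz - reference.Bz0.Bz
    if delta.shape == (nx + 1, ny + 1):
        pass
    elif delta.shape == (nx, ny):
        delta = _cells_to_nodes(delta)
    else:
        raise ValueError("Bz shape matches neither the grid nor its nodes")
    if smooth_sd > 0:
        delta = ndimage.gaussian_filter(delta, smooth_sd)
    # node 5-point Laplacian of delta / mu0
    rhs_node = np.zeros((nx + 1, ny + 1))
    rhs_node[1:-1, 1:-1] = ((delta[2:, 1:-1] - 2 * delta[1:-1, 1:-1]
                             + delta[:-2, 1:-1]) / dx ** 2
                            + (delta[1:-1, 2:] - 2 * delta[1:-1, 1:-1]
                               + delta[1:-1, :-2]) / dy ** 2) / MU0

    m = grid.domain_mask
    node_in = _node_interior(grid)
    nid = -np.ones(node_in.shape, dtype=int)
    nid[node_in] = np.arange(node_in.sum())
    ii, jj = np.nonzero(node_in)
    nun = len(ii)
    rows, cols, vals_ = [], [], []
    b = np.zeros(nun)
    for k, (i, j) in enumerate(zip(ii, jj)):
        diag = 0.0
        for (ni, nj, w) in ((i - 1, j, 1 / dx ** 2), (i + 1, j, 1 / dx ** 2),
                            (i, j - 1, 1 / dy ** 2), (i, j + 1, 1 / dy ** 2)):
            diag -= w
            if node_in[ni, nj]:
                rows.append(k)
                cols.append(nid[ni, nj])
                vals_.append(w)
            # else: Dirichlet psi = 0, no contribution
        rows.append(k)
        cols.append(k)
        vals_.append(diag)
        b[k] = rhs_node[i, j]
    A = sparse.csr_matrix((vals_, (rows, cols)), shape=(nun, nun))
    psi_v = spsolve(A.tocsc(), b)
    psi = np.zeros(node_in.shape)
    psi[node_in] = psi_v

    # cell-centered curl components from node values
    # d psi/dy at cell (i,j): average over the two x-edges of the cell
    dpsidy = 0.5 * ((psi[:-1, 1:] - psi[:-1, :-1])
                    + (psi[1:, 1:] - psi[1:, :-1])) / dy
    dpsidx = 0.5 * ((psi[1:, :-1] - psi[:-1, :-1])
                    + (psi[1:, 1:] - psi[:-1, 1:])) / dx
    corr_x = np.where(m, dpsidy, 0.0)
    corr_y = np.where(m, -dpsidx, 0.0)
    return StreamCorrection(grid=grid, psi=psi, corr_x=corr_x, corr_y=corr_y)


def projected_current_density(reference: HomogeneousReference,
                              correction: StreamCorrection,
                              provenance: str = "projected"
                              ) -> CurrentDensityField:
    """Jp = J0 + curl2(psi), with conservative face fluxes.

    The correction face fluxes are node differences of psi (per unit slab
    thickness), so their discrete divergence is identically zero and Jp
    inherits both the conservation and the boundary flux of J0.
    """
    grid = correction.grid
    if reference.J0.grid is not grid and reference.J0.grid.shape != grid.shape:
        raise ValueError("reference and correction grids do not match")
    psi = correction.psi
    # flux through x-face (i, j) (between cells (i-1,j),(i,j)), +x direction:
    # integral of corr_x over the face = psi(i, j+1) - psi(i, j)
    ffx = reference.J0.face_flux_x + (psi[:, 1:] - psi[:, :-1])
    ffy = reference.J0.face_flux_y - (psi[1:, :] - psi[:-1, :])
    return CurrentDensityField(
        grid=grid,
        Jx=reference.J0.Jx + correction.corr_x,
        Jy=reference.J0.Jy + correction.corr_y,
        provenance=provenance, face_flux_x=ffx, face_flux_y=ffy)


def recover_projected_current(Bz_measured: FluxDensityField, grid: VoxelGrid,
                              electrodes: ElectrodeConfiguration,
                              sigma0: float, smooth_sd: float = 0.0,
                              slab_thickness_mm: float = None
                              ) -> CurrentDensityField:
    """Convenience chain: homogeneous reference -> psi -> Jp.

    The reference Bz0 is synthesized with the same sampling (cells or nodes)
    as the measured Bz.
    """
    nx, ny = grid.shape
    bz_at = "nodes" if Bz_measured.Bz.shape == (nx + 1, ny + 1) else "cells"
    ref = initial_current(grid, electrodes, sigma0,
                          slab_thickness_mm=slab_thickness_mm, bz_at=bz_at)
    corr = solve_psi(Bz_measured, ref, grid, smooth_sd=smooth_sd)
    return projected_current_density(ref, corr)
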