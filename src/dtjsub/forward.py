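"""Forward electromagnetics: anisotropic Neumann potential solve, current
density, and Biot-Savart synthesis of the z-component magnetic flux density.

The conduction problem is

    div( C grad u ) = 0        in Omega,
    (C grad u) . nu = -g       on the boundary,

with C the (possibly anisotropic) conductivity tensor and g the prescribed
outward normal current density of the electrode montage, so that
J = -C grad u satisfies J . nu = g.  The Neumann problem is solvable only for
a conserved montage (total signed flux zero) and determines u up to a
constant; a zero-mean gauge over the domain mask is applied.

Discretization: cell-centered finite volumes on the regular grid.  The
normal-normal tensor coefficient on each interior face is harmonically
averaged (exact for piecewise-constant 1-D profiles, robust across
discontinuities); the cross (off-diagonal) coefficient is arithmetically
averaged and multiplied by the face-averaged tangential derivative.  Face
fluxes are assembled exactly once and reused for the potential system, so
the discrete divergence of the resulting current density vanishes to solver
tolerance by construction.

All solver-internal lengths are SI (meters); grid spacings are given in mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.signal import fftconvolve
from scipy.sparse.linalg import splu, spsolve

from .grids import ConductivityTensorField, ElectrodeConfiguration, VoxelGrid

logger = logging.getLogger("dtjsub")

MU0 = 4.0e-7 * np.pi  # vacuum permeability, T.m/A


# ---------------------------------------------------------------------------
# Field containers
# ---------------------------------------------------------------------------

@dataclass
class PotentialField:
    """Electric potential u (V) on the grid, zero-mean over the domain mask."""

    grid: VoxelGrid
    u: np.ndarray
    residual: float = 0.0   # relative discrete residual of the solve
    iterations: int = 0

    def gradient(self):
        """Cell-centered masked gradient (V/m), components (Gx, Gy)."""
        ops = _grid_operators(self.grid)
        uv = self.u[self.grid.domain_mask]
        gx = np.zeros(self.grid.shape)
        gy = np.zeros(self.grid.shape)
        gx[self.grid.domain_mask] = ops.Gx @ uv
        gy[self.grid.domain_mask] = ops.Gy @ uv
        return gx, gy


@dataclass
class CurrentDensityField:
    """Current density J (A/m^2): cell-centered components plus the exactly
    conservative face fluxes of the finite-volume stencil.

    ``face_flux_x[i, j]`` is the flux per unit slab thickness (A/m) through
    the face between cells ``(i-1, j)`` and ``(i, j)`` in the +x direction;
    likewise ``face_flux_y``.  Boundary faces carry the prescribed electrode
    flux.  ``provenance`` is one of ``"true"``, ``"initial"``, ``"projected"``,
    ``"assistant"``.
    """

    grid: VoxelGrid
    Jx: np.ndarray
    Jy: np.ndarray
    provenance: str = "true"
    face_flux_x: np.ndarray = None  # (nx+1, ny), A/m
    face_flux_y: np.ndarray = None  # (nx, ny+1), A/m

    @property
    def magnitude(self):
        return np.hypot(self.Jx, self.Jy)


@dataclass
class FluxDensityField:
    """z-component of the magnetic flux density, Tesla."""

    grid: VoxelGrid
    Bz: np.ndarray
    provenance: str = "simulated"


# ---------------------------------------------------------------------------
# Discrete operators (cached per grid)
# ---------------------------------------------------------------------------

class _GridOperators:
    """Sparse masked operators shared by the solver and derived quantities."""

    def __init__(self, grid: VoxelGrid):
        nx, ny = grid.shape
        m = grid.domain_mask
        self.idx = -np.ones(grid.shape, dtype=int)
        self.idx[m] = np.arange(m.sum())
        n = m.sum()
        dx = grid.spacing[0] * 1e-3
        dy = grid.spacing[1] * 1e-3
        self.dx_m, self.dy_m = dx, dy

        # --- cell-centered gradient (central where possible, else one-sided)
        self.Gx = self._cell_gradient(grid, axis=0)
        self.Gy = self._cell_gradient(grid, axis=1)

        # --- interior faces
        # x-faces: between (i-1, j) and (i, j), both in mask
        Lm = np.zeros((nx + 1, ny), dtype=bool)
        Lm[1:nx, :] = m[:-1, :] & m[1:, :]
        fi, fj = np.nonzero(Lm)
        self.xface_loc = (fi, fj)           # face between cells (fi-1,fj),(fi,fj)
        self.xL = self.idx[fi - 1, fj]
        self.xR = self.idx[fi, fj]
        Lm = np.zeros((nx, ny + 1), dtype=bool)
        Lm[:, 1:ny] = m[:, :-1] & m[:, 1:]
        fi, fj = np.nonzero(Lm)
        self.yface_loc = (fi, fj)
        self.yL = self.idx[fi, fj - 1]
        self.yR = self.idx[fi, fj]
        nfx, nfy = len(self.xL), len(self.yL)

        def diff_avg(L, R, nf):
            rows = np.repeat(np.arange(nf), 2)
            cols = np.column_stack([L, R]).ravel()
            dvals = np.tile([-1.0, 1.0], nf)
            avals = np.tile([0.5, 0.5], nf)
            D = sparse.csr_matrix((dvals, (rows, cols)), shape=(nf, n))
            A = sparse.csr_matrix((avals, (rows, cols)), shape=(nf, n))
            return D, A

        self.Dxf, self.Axf = diff_avg(self.xL, self.xR, nfx)
        self.Dyf, self.Ayf = diff_avg(self.yL, self.yR, nfy)

        # incidence: +flux leaves L, enters R
        rows = np.concatenate([self.xL, self.xR])
        cols = np.concatenate([np.arange(nfx)] * 2)
        vals = np.concatenate([np.ones(nfx), -np.ones(nfx)])
        self.Divx = sparse.csr_matrix((vals, (rows, cols)), shape=(n, nfx))
        rows = np.concatenate([self.yL, self.yR])
        cols = np.concatenate([np.arange(nfy)] * 2)
        vals = np.concatenate([np.ones(nfy), -np.ones(nfy)])
        self.Divy = sparse.csr_matrix((vals, (rows, cols)), shape=(n, nfy))

    def _cell_gradient(self, grid, axis):
        nx, ny = grid.shape
        m = grid.domain_mask
        h = grid.spacing[axis] * 1e-3
        shift = (1, 0) if axis == 0 else (0, 1)
        has_p = np.zeros_like(m)
        has_m = np.zeros_like(m)
        if axis == 0:
            has_p[:-1, :] = m[:-1, :] & m[1:, :]
            has_m[1:, :] = m[1:, :] & m[:-1, :]
        else:
            has_p[:, :-1] = m[:, :-1] & m[:, 1:]
            has_m[:, 1:] = m[:, 1:] & m[:, :-1]
        rows, cols, vals = [], [], []
        ii, jj = np.nonzero(m)
        for i, j in zip(ii, jj):
            c = self.idx[i, j]
            ip = (i + shift[0], j + shift[1])
            im = (i - shift[0], j - shift[1])
            if has_p[i, j] and has_m[i, j]:
                rows += [c, c]
                cols += [self.idx[ip], self.idx[im]]
                vals += [0.5 / h, -0.5 / h]
            elif has_p[i, j]:
                rows += [c, c]
                cols += [self.idx[ip], c]
                vals += [1.0 / h, -1.0 / h]
            elif has_m[i, j]:
                rows += [c, c]
                cols += [c, self.idx[im]]
                vals += [1.0 / h, -1.0 / h]
        nin = m.sum()
        return sparse.csr_matrix((vals, (rows, cols)), shape=(nin, nin))


def _grid_operators(grid: VoxelGrid) -> _GridOperators:
    # cached on the grid instance; masks are immutable after construction
    ops = getattr(grid, "_ops", None)
    if ops is None:
        ops = _GridOperators(grid)
        grid._ops = ops
    return ops


def _check_spd_inplane(C: ConductivityTensorField, grid: VoxelGrid):
    m = grid.domain_mask
    cxx = C.components[..., 0][m]
    cxy = C.components[..., 1][m]
    cyy = C.components[..., 2][m]
    if (cxx <= 0).any() or (cyy <= 0).any() or (cxx * cyy - cxy ** 2 <= 0).any():
        raise ValueError("conductivity tensor not SPD in-plane on the mask")


def _flux_operators(C: ConductivityTensorField, grid: VoxelGrid):
    """Sparse maps u -> face flux per unit thickness (A/m) for x and y faces."""
    ops = _grid_operators(grid)
    m = grid.domain_mask
    cxx = C.components[..., 0]
    cxy = C.components[..., 1]
    cyy = C.components[..., 2]

    def harm(a, b):
        return 2.0 * a * b / (a + b)

    # x-faces
    fi, fj = ops.xface_loc
    cL = cxx[fi - 1, fj]
    cR = cxx[fi, fj]
    w_nn = harm(cL, cR) / ops.dx_m
    w_ct = 0.5 * (cxy[fi - 1, fj] + cxy[fi, fj])
    Fx = -(sparse.diags(w_nn) @ ops.Dxf
           + sparse.diags(w_ct) @ (ops.Axf @ ops.Gy)) * ops.dy_m
    # y-faces
    fi, fj = ops.yface_loc
    cL = cyy[fi, fj - 1]
    cR = cyy[fi, fj]
    w_nn = harm(cL, cR) / ops.dy_m
    w_ct = 0.5 * (cxy[fi, fj - 1] + cxy[fi, fj])
    Fy = -(sparse.diags(w_nn) @ ops.Dyf
           + sparse.diags(w_ct) @ (ops.Ayf @ ops.Gx)) * ops.dx_m
    return Fx, Fy


def _boundary_source(grid: VoxelGrid, electrodes: ElectrodeConfiguration):
    """Per-cell boundary outflow per unit thickness (A/m)."""
    ops = _grid_operators(grid)
    bf = grid.boundary_faces
    flen = grid.face_lengths_mm() * 1e-3
    out = np.zeros(grid.n_in)
    np.add.at(out, ops.idx[bf["i"], bf["j"]], electrodes.g * flen)
    return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def solve_potential(conductivity: ConductivityTensorField,
                    electrodes: ElectrodeConfiguration,
                    grid: VoxelGrid, tol: float = 1e-10) -> PotentialField:
    """Solve the anisotropic Neumann conduction problem.

    Returns the zero-mean potential; raises if the montage flux is not
    conserved (the singular system would be incompatible) or if the tensor is
    not SPD in-plane.  The discrete residual ``|A u - b| / |b|`` is checked
    against ``tol``.
    """
    _check_spd_inplane(conductivity, grid)
    ops = _grid_operators(grid)
    n = grid.n_in
    bvec = -_boundary_source(grid, electrodes)
    scale = np.abs(bvec).sum()
    if scale > 0 and abs(bvec.sum()) > 1e-10 * scale:
        raise ValueError("electrode flux not conserved: Neumann problem incompatible")
    Fx, Fy = _flux_operators(conductivity, grid)
    A = (ops.Divx @ Fx + ops.Divy @ Fy).tocsr()
    if scale == 0.0:
        u = np.zeros(grid.shape)
        return PotentialField(grid=grid, u=u, residual=0.0, iterations=0)
    # gauge-augmented saddle system: A is singular with constant nullspace
    ones = np.ones((n, 1))
    K = sparse.bmat([[A, ones], [ones.T, None]], format="csc")
    rhs = np.concatenate([bvec, [0.0]])
    lu = splu(K)
    sol = lu.solve(rhs)
    bnorm = np.linalg.norm(bvec)
    for _ in range(3):  # iterative refinement against rounding in the factors
        uv = sol[:n] - sol[:n].mean()
        res = np.linalg.norm(A @ uv - bvec) / bnorm
        if res <= 0.1 * tol:
            break
        r_full = rhs - np.concatenate([A @ sol[:n] + sol[n] * np.ones(n),
                                       [sol[:n].sum()]])
        sol = sol + lu.solve(r_full)
    uv = sol[:n] - sol[:n].mean()
    res = np.linalg.norm(A @ uv - bvec) / bnorm
    if res > tol:
        raise RuntimeError(f"potential solve residual {res:.3e} exceeds tol {tol:.1e}")
    logger.debug("solve_potential: n=%d residual=%.3e", n, res)
    u = np.zeros(grid.shape)
    u[grid.domain_mask] = uv
    return PotentialField(grid=grid, u=u, residual=res, iterations=1)


def compute_current_density(conductivity: ConductivityTensorField,
                            u: PotentialField, grid: VoxelGrid,
                            electrodes: ElectrodeConfiguration = None,
                            provenance: str = "true") -> CurrentDensityField:
    """J = -C grad u: cell-centered components plus conservative face fluxes.

    The face fluxes reuse the solver stencil, so their per-cell divergence
    equals the solve residual (zero to solver tolerance).  If ``electrodes``
    is given, boundary faces carry the prescribed g.
    """
    if u.grid is not grid and u.grid.shape != grid.shape:
        raise ValueError("potential and grid do not match")
    ops = _grid_operators(grid)
    m = grid.domain_mask
    uv = u.u[m]
    gx, gy = u.gradient()
    cxx = conductivity.components[..., 0]
    cxy = conductivity.components[..., 1]
    cyy = conductivity.components[..., 2]
    Jx = np.where(m, -(cxx * gx + cxy * gy), 0.0)
    Jy = np.where(m, -(cxy * gx + cyy * gy), 0.0)

    Fx, Fy = _flux_operators(conductivity, grid)
    nx, ny = grid.shape
    ffx = np.zeros((nx + 1, ny))
    ffy = np.zeros((nx, ny + 1))
    ffx[ops.xface_loc] = Fx @ uv
    ffy[ops.yface_loc] = Fy @ uv
    if electrodes is not None:
        bf = grid.boundary_faces
        flen = grid.face_lengths_mm() * 1e-3
        for k in range(len(bf)):
            i, j, d = bf["i"][k], bf["j"][k], bf["dir"][k]
            val = electrodes.g[k] * flen[k]
            if d == 0:      # outward -x: outgoing flux = -face flux
                ffx[i, j] = -val
            elif d == 1:
                ffx[i + 1, j] = val
            elif d == 2:
                ffy[i, j] = -val
            else:
                ffy[i, j + 1] = val
    return CurrentDensityField(grid=grid, Jx=Jx, Jy=Jy, provenance=provenance,
                               face_flux_x=ffx, face_flux_y=ffy)


def face_averaged_components(J: CurrentDensityField, grid: VoxelGrid):
    """Cell-centered (Jx, Jy) obtained by averaging the two face fluxes of
    each cell — the representation consistent across differently-built
    conservative fields (used when comparing currents)."""
    dx = grid.spacing[0] * 1e-3
    dy = grid.spacing[1] * 1e-3
    m = grid.domain_mask
    Jx = 0.5 * (J.face_flux_x[:-1, :] + J.face_flux_x[1:, :]) / dy
    Jy = 0.5 * (J.face_flux_y[:, :-1] + J.face_flux_y[:, 1:]) / dx
    return np.where(m, Jx, 0.0), np.where(m, Jy, 0.0)


def divergence_residual(J: CurrentDensityField, grid: VoxelGrid) -> float:
    """Max interior cell divergence of the face fluxes, relative to the
    characteristic gradient scale mean|J|/dx."""
    ops = _grid_operators(grid)
    m = grid.domain_mask
    div = (np.diff(J.face_flux_x, axis=0) + np.diff(J.face_flux_y, axis=1))
    div = div / (ops.dx_m * ops.dy_m)          # A/m^3 per unit thickness
    interior = m & ~_mask_boundary_cells(grid)
    scale = J.magnitude[m].mean() / ops.dx_m
    if scale == 0:
        return 0.0
    return float(np.abs(div[interior]).max() / scale)


def _mask_boundary_cells(grid: VoxelGrid) -> np.ndarray:
    bf = grid.boundary_faces
    out = np.zeros(grid.shape, dtype=bool)
    out[bf["i"], bf["j"]] = True
    return out


def biot_savart_bz(J: CurrentDensityField, grid: VoxelGrid,
                   slab_thickness_mm: float = None, at: str = "cells",
                   quad: int = 3,
                   provenance: str = "simulated") -> FluxDensityField:
    """Bz at the slab mid-plane from the in-plane current density.

    The current is taken z-invariant over a slab of the given thickness
    (default: the grid's own ``thickness_mm``).  The z-integral of the
    Biot-Savart kernel over the slab is carried out analytically:

        Bz(r) = (mu0/4pi) * sum_{r'} [ (y-y') Jx(r') - (x-x') Jy(r') ]
                * T / ( rho^2 * sqrt(rho^2 + T^2/4) ) * dA

    with rho = |r - r'| in-plane.  The in-plane integral over each source
    voxel uses ``quad`` x ``quad`` midpoint subsamples (the self-voxel
    quadrature nodes at the singularity are dropped; by symmetry they cancel).
    For thickness much larger than the domain this reproduces 2-D
    magnetostatics, in which the in-plane Laplacian of Bz equals mu0 times
    the in-plane curl of J; for a thin slab it reproduces the single-slice
    geometry.  The field is linear in J.

    ``at="cells"`` samples Bz at voxel centers (the grid of J);
    ``at="nodes"`` samples at the cell corners — the dual grid used by the
    stream-function solve — and returns a field on :func:`node_grid`.
    """
    from .grids import node_grid

    T = (grid.thickness_mm if slab_thickness_mm is None else slab_thickness_mm)
    if T <= 0:
        raise ValueError("slab thickness must be positive")
    if quad < 1:
        raise ValueError("quad must be >= 1")
    T_m = T * 1e-3
    nx, ny = grid.shape
    dx = grid.spacing[0] * 1e-3
    dy = grid.spacing[1] * 1e-3
    if at == "cells":
        ix = np.arange(-(nx - 1), nx) * dx
        iy = np.arange(-(ny - 1), ny) * dy
    elif at == "nodes":
        # displacement from cell centers to node positions
        ix = (np.arange(-(nx - 1), nx + 1) - 0.5) * dx
        iy = (np.arange(-(ny - 1), ny + 1) - 0.5) * dy
    else:
        raise ValueError("at must be 'cells' or 'nodes'")
    DX, DY = np.meshgrid(ix, iy, indexing="ij")
    kx = np.zeros_like(DX)
    ky = np.zeros_like(DX)
    offs = (np.arange(quad) + 0.5) / quad - 0.5
    for ox in offs:
        for oy in offs:
            dxx = DX - ox * dx
            dyy = DY - oy * dy
            rho2 = dxx ** 2 + dyy ** 2
            with np.errstate(divide="ignore", invalid="ignore"):
                K = T_m / (rho2 * np.sqrt(rho2 + 0.25 * T_m ** 2))
            K[~np.isfinite(K)] = 0.0
            kx += dyy * K        # multiplies Jx:  (y - y') with d = r - r'
            ky += -dxx * K       # multiplies Jy: -(x - x')
    pref = MU0 / (4.0 * np.pi) * dx * dy / quad ** 2
    kx *= pref
    ky *= pref
    Jx = np.where(grid.domain_mask, J.Jx, 0.0)
    Jy = np.where(grid.domain_mask, J.Jy, 0.0)
    if at == "cells":
        Bz = (fftconvolve(Jx, kx, mode="same")
              + fftconvolve(Jy, ky, mode="same"))
        return FluxDensityField(grid=grid, Bz=Bz, provenance=provenance)
    Bz = (fftconvolve(Jx, kx, mode="full")[nx - 1:2 * nx, ny - 1:2 * ny]
          + fftconvolve(Jy, ky, mode="full")[nx - 1:2 * nx, ny - 1:2 * ny])
    return FluxDensityField(grid=node_grid(grid), Bz=Bz, provenance=provenance)


def bz_laplacian_consistency(J: CurrentDensityField, Bz: FluxDensityField,
                             grid: VoxelGrid, margin: int = 2,
                             exclude: np.ndarray = None) -> float:
    """Relative L2 mismatch between the in-plane Laplacian of Bz and
    mu0 * (dJx/dy - dJy/dx) on the eroded interior of the mask.

    The identity curl(B) = mu0 J gives lap(Bz) = -mu0 (curl J)_z
    = mu0 (dJx/dy - dJy/dx) inside a z-invariant current distribution; the
    sign convention here was frozen after differencing the Biot-Savart
    kernel numerically.  ``exclude`` masks out voxels (e.g. near a wire)
    before comparison; the denominator is the whole-interior norm of the
    right-hand side.
    """
    ops = _grid_operators(grid)
    dx, dy = ops.dx_m, ops.dy_m
    B = Bz.Bz
    lap = np.zeros_like(B)
    lap[1:-1, 1:-1] = ((B[2:, 1:-1] - 2 * B[1:-1, 1:-1] + B[:-2, 1:-1]) / dx ** 2
                       + (B[1:-1, 2:] - 2 * B[1:-1, 1:-1] + B[1:-1, :-2]) / dy ** 2)
    rhs = np.zeros_like(B)
    rhs[1:-1, 1:-1] = MU0 * ((J.Jx[1:-1, 2:] - J.Jx[1:-1, :-2]) / (2 * dy)
                             - (J.Jy[2:, 1:-1] - J.Jy[:-2, 1:-1]) / (2 * dx))
    interior = ndimage.binary_erosion(grid.domain_mask, iterations=max(margin, 1))
    region = interior if exclude is None else (interior & ~exclude)
    denom = np.linalg.norm(rhs[interior])
    if denom == 0:
        return float(np.linalg.norm(lap[region]) )
    return float(np.linalg.norm((lap - rhs)[region]) / denom)
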