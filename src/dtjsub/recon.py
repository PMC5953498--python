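"""Inverse methods: diffusion-tensor J-substitution and companions.

The conductivity tensor is modelled as C = eta * D with D the water diffusion
tensor and eta a positive scalar field (reflecting, physically, the
extracellular ion concentration).  Given a recovered current density J
(in practice the projected current Jp) and D, eta is reconstructed by
alternating

  (i)  the forward Neumann solve  div(eta^n D grad u^n) = 0  with the
       electrode boundary flux, and
  (ii) the neighborhood-weighted Ohm's-law update

       eta^{n+1}(r) = - <J> . <grad u^n> / ( <D grad u^n> . <grad u^n> )

where <.> is a weighted average over a small search neighborhood with
similarity weights  w_i ∝ exp(-h |S(r_i) - S(r)|)  built from the MR
magnitude image (h tuned to the noise level; the defaults are a 5x5
neighborhood and h = 0.1).  With a singleton neighborhood and the true
potential, eta_true is an exact fixed point of the update.

A single injected current determines eta only up to a global multiplicative
constant (scaling eta scales u inversely, leaving J unchanged), so the
absolute scale is anchored by the initialization; the update is homogeneous
of degree one in that anchor.

Also provided: the two-current direct method, which solves the per-voxel
2x2 system

    grad(ln eta) x (D^-1 Jp) = curl(D^-1 Jp)

for grad(ln eta) from two transversal injected currents and integrates it by
least squares; the isotropic J-substitution baseline (D = I), which cannot
represent anisotropic current paths; and the diagnostic angle map between
the velocity vector D grad u^n and the electric field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import lsqr

from .forward import (CurrentDensityField, PotentialField,
                      compute_current_density, solve_potential)
from .grids import (ETA_D_TO_SI, ConductivityTensorField, DiffusionTensorField,
                    ElectrodeConfiguration, ScaleParameterField, VoxelGrid)

logger = logging.getLogger("dtjsub")

DEFAULT_NEIGHBORHOOD = 5     # 5x5 = 25 in-plane search voxels
DEFAULT_H = 0.1              # similarity decay of the weight kernel
DENOM_FLOOR_REL = 1e-6       # mask voxels with tiny update denominator
CLIP_RANGE = (1e-3, 1e3)     # eta clip bounds relative to the anchor


# ---------------------------------------------------------------------------
# Weight kernel
# ---------------------------------------------------------------------------

@dataclass
class WeightKernel:
    """Normalized exponential-similarity weights over a square neighborhood.

    ``offsets`` lists the in-plane neighborhood offsets; ``weights[k]`` holds
    the per-voxel weight of offset k.  At every voxel the weights are
    non-negative and sum to one; neighborhoods truncated by the mask or the
    grid edge are renormalized over the remaining members.
    """

    grid: VoxelGrid
    offsets: list
    weights: np.ndarray      # (n_offsets, nx, ny)
    h: float
    S: np.ndarray = field(repr=False, default=None)


def _shift(a: np.ndarray, oi: int, oj: int, fill=0.0) -> np.ndarray:
    """a(r + (oi, oj)) with out-of-range entries filled."""
    out = np.full_like(a, fill)
    nx, ny = a.shape[:2]
    si = slice(max(0, -oi), min(nx, nx - oi))
    sj = slice(max(0, -oj), min(ny, ny - oj))
    ti = slice(max(0, oi), min(nx, nx + oi))
    tj = slice(max(0, oj), min(ny, ny + oj))
    out[si, sj] = a[ti, tj]
    return out


def make_weights(S: np.ndarray, grid: VoxelGrid, h: float = DEFAULT_H,
                 neighborhood: int = DEFAULT_NEIGHBORHOOD) -> WeightKernel:
    """Similarity weights w_i ∝ exp(-h |S(r_i) - S(r)|) over an NxN window.

    ``h = 0`` gives uniform averaging; large h concentrates weight on
    neighbors with magnitude close to the center voxel.  ``neighborhood = 1``
    is the singleton (identity) kernel.
    """
    if h < 0:
        raise ValueError("h must be non-negative")
    if neighborhood < 1 or neighborhood % 2 == 0:
        raise ValueError("neighborhood must be a positive odd integer")
    S = np.asarray(S, dtype=float)
    half = neighborhood // 2
    offsets = [(oi, oj) for oi in range(-half, half + 1)
               for oj in range(-half, half + 1)]
    m = grid.domain_mask
    raw = np.zeros((len(offsets),) + grid.shape)
    for k, (oi, oj) in enumerate(offsets):
        Sn = _shift(S, oi, oj, fill=np.nan)
        valid = _shift(m.astype(float), oi, oj, fill=0.0) > 0
        w = np.where(valid, np.exp(-h * np.abs(Sn - S)), 0.0)
        raw[k] = np.where(m, np.nan_to_num(w), 0.0)
    tot = raw.sum(axis=0)
    tot = np.where(tot > 0, tot, 1.0)
    return WeightKernel(grid=grid, offsets=offsets, weights=raw / tot, h=h,
                        S=S)


def _weighted_average(field2d, kernel: WeightKernel):
    """Sum_k w_k * field(r + offset_k), for scalar or stacked fields."""
    out = np.zeros_like(field2d, dtype=float)
    for k, (oi, oj) in enumerate(kernel.offsets):
        w = kernel.weights[k]
        if field2d.ndim == 2:
            out += w * _shift(field2d, oi, oj)
        else:
            sh = np.stack([_shift(field2d[c], oi, oj)
                           for c in range(field2d.shape[0])])
            out += w[None] * sh
    return out


# ---------------------------------------------------------------------------
# DT-J-substitution
# ---------------------------------------------------------------------------

def _velocity(D: DiffusionTensorField, gx, gy):
    """In-plane components of D grad u (D in mm^2/s, grad u in V/m)."""
    c = D.components
    return (c[..., 0] * gx + c[..., 1] * gy,
            c[..., 1] * gx + c[..., 2] * gy)


def _fill_nearest(values: np.ndarray, valid: np.ndarray, mask: np.ndarray):
    """Fill in-mask invalid voxels with the nearest valid value."""
    if valid.all():
        return values
    if not valid.any():
        raise ValueError("no valid voxels to fill from (all-masked slice)")
    missing = mask & ~valid
    if not missing.any():
        return values
    ind = ndimage.distance_transform_edt(~valid, return_distances=False,
                                         return_indices=True)
    out = values.copy()
    out[missing] = values[ind[0][missing], ind[1][missing]]
    return out


def dtj_update(J: CurrentDensityField, D: DiffusionTensorField,
               u: PotentialField, weights: WeightKernel,
               anchor: float = 1.0, center_gradient: bool = False,
               clip_range=CLIP_RANGE) -> ScaleParameterField:
    """One scale-parameter update from Ohm's law on weighted neighborhoods.

    eta^{n+1} = - <J> . <grad u> / ( <D grad u> . <grad u> ), with <.> the
    similarity-weighted neighborhood average.  The units work out to
    S.s/mm^3 after the diffusivity conversion.  Voxels whose denominator
    falls below ``DENOM_FLOOR_REL`` times its in-mask median are masked and
    filled from the nearest valid voxel; the result is clipped to
    ``clip_range`` times the anchor.

    ``center_gradient=True`` uses grad u at the center voxel in the numerator
    (the literal printed form of the update); the default uses the weighted
    average in both numerator and denominator, which makes eta_true an exact
    fixed point.
    """
    grid = u.grid
    m = grid.domain_mask
    gx, gy = u.gradient()
    vx, vy = _velocity(D, gx, gy)            # mm^2/s * V/m
    Javg = _weighted_average(np.stack([J.Jx, J.Jy]), weights)
    Gavg = _weighted_average(np.stack([gx, gy]), weights)
    Vavg = _weighted_average(np.stack([vx, vy]), weights)
    Gnum = np.stack([gx, gy]) if center_gradient else Gavg
    num = -(Javg[0] * Gnum[0] + Javg[1] * Gnum[1])
    den = ETA_D_TO_SI * (Vavg[0] * Gavg[0] + Vavg[1] * Gavg[1])
    med = np.median(np.abs(den[m]))
    valid = m & (np.abs(den) > DENOM_FLOOR_REL * med)
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = np.where(valid, num / np.where(valid, den, 1.0), 0.0)
    eta = _fill_nearest(eta, valid, m)
    eta = np.clip(eta, clip_range[0] * anchor, clip_range[1] * anchor)
    eta = np.where(m, eta, 0.0)
    return ScaleParameterField(grid=grid, eta=np.where(m, eta, 1.0),
                               valid=valid)


def sensitivity(J: CurrentDensityField, u: PotentialField,
                weights: WeightKernel) -> np.ndarray:
    """|<J> . <grad u>| — large where the update is well determined."""
    Javg = _weighted_average(np.stack([J.Jx, J.Jy]), weights)
    Gavg = _weighted_average(np.stack([u.gradient()[0], u.gradient()[1]]),
                             weights)
    return np.abs(Javg[0] * Gavg[0] + Javg[1] * Gavg[1])


@dataclass
class IterationState:
    """Final state and per-iteration history of the substitution loop."""

    eta: ScaleParameterField
    u: PotentialField
    n_iterations: int
    history: list            # dicts: n, rel_change, data_residual
    converged: bool
    eta_iterates: list = field(default_factory=list, repr=False)
    u_iterates: list = field(default_factory=list, repr=False)
    eta0: np.ndarray = field(default=None, repr=False)


def data_residual(eta: np.ndarray, D: DiffusionTensorField,
                  u: PotentialField, J: CurrentDensityField) -> float:
    """|| eta D grad u + J || / ||J|| over the mask (Ohm's-law misfit)."""
    m = u.grid.domain_mask
    gx, gy = u.gradient()
    vx, vy = _velocity(D, gx, gy)
    rx = ETA_D_TO_SI * eta * vx + J.Jx
    ry = ETA_D_TO_SI * eta * vy + J.Jy
    num = np.sqrt((rx[m] ** 2 + ry[m] ** 2).sum())
    den = np.sqrt((J.Jx[m] ** 2 + J.Jy[m] ** 2).sum())
    return float(num / den) if den > 0 else 0.0


def uniform_eta0(D: DiffusionTensorField, sigma0: float) -> float:
    """Anchor: uniform eta0 = sigma0 / mean(trace(D)/3), matching a
    background conductivity sigma0 (S/m) on average."""
    m = D.grid.domain_mask
    c = D.components
    mean_d = ((c[..., 0] + c[..., 2] + c[..., 5]) / 3.0)[m].mean()
    return sigma0 / (ETA_D_TO_SI * mean_d)


def dtj_iterate(J: CurrentDensityField, D: DiffusionTensorField,
                electrodes: ElectrodeConfiguration, grid: VoxelGrid,
                eta0, weights: WeightKernel = None, n_max: int = 10,
                tol: float = 1e-3, center_gradient: bool = False,
                keep_iterates: bool = False) -> IterationState:
    """Alternate the forward solve and the Ohm's-law update.

    ``eta0`` is a positive scalar (uniform start, the scale anchor) or a
    full initial map.  Stops at ``n_max`` iterations or when the mean
    relative change of eta drops below ``tol``.  The history records the
    relative change and the data residual ||eta^n D grad u^n + J||/||J||
    at every iteration.
    """
    if n_max < 1:
        raise ValueError("n_max must be at least 1")
    m = grid.domain_mask
    if np.isscalar(eta0):
        eta = np.where(m, float(eta0), 1.0)
    else:
        eta = np.asarray(eta0, dtype=float).copy()
    if (eta[m] <= 0).any():
        raise ValueError("initial eta must be positive")
    anchor = float(np.mean(eta[m]))
    if weights is None:
        weights = make_weights(np.ones(grid.shape), grid, h=0.0,
                               neighborhood=DEFAULT_NEIGHBORHOOD)
    history = []
    iterates = []
    u_iterates = []
    eta_start = eta.copy()
    u = None
    converged = False
    n_done = 0
    for n in range(n_max):
        C = ConductivityTensorField.from_eta_and_diffusion(
            ScaleParameterField(grid=grid, eta=np.where(m, eta, 1.0)), D)
        try:
            u = solve_potential(C, electrodes, grid)
        except Exception as exc:
            raise RuntimeError(f"forward solve failed at iteration {n}") from exc
        new = dtj_update(J, D, u, weights, anchor=anchor,
                         center_gradient=center_gradient)
        rel_change = float(np.mean(np.abs(new.eta[m] - eta[m])
                                   / np.maximum(np.abs(eta[m]), 1e-30)))
        resid = data_residual(new.eta, D, u, J)
        history.append({"n": n + 1, "rel_change": rel_change,
                        "data_residual": resid})
        logger.info("dtj iteration %d: rel_change=%.3e residual=%.3e",
                    n + 1, rel_change, resid)
        eta = new.eta
        valid = new.valid
        if keep_iterates:
            iterates.append(eta.copy())
            u_iterates.append(u)
        n_done = n + 1
        if rel_change < tol:
            converged = True
            break
    eta_field = ScaleParameterField(grid=grid, eta=np.where(m, eta, 1.0),
                                    valid=valid)
    return IterationState(eta=eta_field, u=u, n_iterations=n_done,
                          history=history, converged=converged,
                          eta_iterates=iterates, u_iterates=u_iterates,
                          eta0=eta_start)


def convergence_identity(J: CurrentDensityField, eta_prev: np.ndarray,
                         u_n: PotentialField, eta_true: np.ndarray,
                         u_true: PotentialField, D: DiffusionTensorField,
                         grid: VoxelGrid) -> dict:
    """Discrete check of the energy identity driving the iteration:

        int (eta^{n+1} - eta) (1 + eta^{n+1}/eta) (D grad u^n) . grad u^n
          = int (eta^n - eta) (D grad u^n) . (grad u^n + grad u)

    where eta, u are the true scale parameter and potential and eta^{n+1}
    enters through the defining relation of the update,
    (eta^{n+1})^2 (D grad u^n).grad u^n = J . D^-1 J, so the left side
    evaluates to  int [ J.D^-1 J / eta - eta (D grad u^n).grad u^n ].
    The equality rests on the divergence-free structure of both the true and
    the iterate's currents (an integration by parts makes the cross term
    vanish); checking it discretely probes the conservation of the forward
    scheme and the quadrature consistency of the gradients.  Returns both
    integrals (voxel sums over the mask) and their relative mismatch.
    """
    m = grid.domain_mask
    gxn, gyn = u_n.gradient()
    vx, vy = _velocity(D, gxn, gyn)
    gx, gy = u_true.gradient()
    quad_nn = ETA_D_TO_SI * (vx * gxn + vy * gyn)
    quad_nt = ETA_D_TO_SI * (vx * gx + vy * gy)
    fx, fy = _dinv_j(D, J)
    jdj = (J.Jx * fx + J.Jy * fy) / ETA_D_TO_SI    # J . D^-1 J, eta units
    lhs = np.sum((jdj / eta_true - eta_true * quad_nn)[m])
    rhs = np.sum(((eta_prev - eta_true) * (quad_nn + quad_nt))[m])
    scale = max(abs(lhs), abs(rhs))
    mism = abs(lhs - rhs) / scale if scale > 0 else 0.0
    return {"lhs": float(lhs), "rhs": float(rhs),
            "rel_mismatch": float(mism)}


# ---------------------------------------------------------------------------
# Isotropic J-substitution baseline
# ---------------------------------------------------------------------------

def isotropic_j_substitution(J: CurrentDensityField,
                             electrodes: ElectrodeConfiguration,
                             grid: VoxelGrid, sigma0: float,
                             weights: WeightKernel = None,
                             n_max: int = 10, tol: float = 1e-3
                             ) -> IterationState:
    """Scalar-conductivity J-substitution (no diffusion information).

    sigma^{n+1} = - <Jp> . <grad u^n> / <grad u^n> . <grad u^n>, iterated
    with isotropic forward solves.  Same masking, filling, and clipping rules
    as the tensor variant; the returned ``eta`` field holds sigma in S/m.
    """
    # reuse the tensor machinery with D = I/ETA_D_TO_SI so eta == sigma (S/m)
    comp = np.zeros(grid.shape + (6,))
    comp[..., 0] = comp[..., 2] = comp[..., 5] = 1.0 / ETA_D_TO_SI
    D_id = DiffusionTensorField(grid=grid, components=comp)
    return dtj_iterate(J, D_id, electrodes, grid, eta0=sigma0,
                       weights=weights, n_max=n_max, tol=tol)


# ---------------------------------------------------------------------------
# Two-current direct method
# ---------------------------------------------------------------------------

def _dinv_j(D: DiffusionTensorField, J: CurrentDensityField):
    """In-plane components of D^-1 J (using the in-plane 2x2 block of D)."""
    c = D.components
    det = c[..., 0] * c[..., 2] - c[..., 1] ** 2
    fx = (c[..., 2] * J.Jx - c[..., 1] * J.Jy) / det
    fy = (-c[..., 1] * J.Jx + c[..., 0] * J.Jy) / det
    return fx, fy


def two_current_direct(Jp: CurrentDensityField, J2p: CurrentDensityField,
                       D: DiffusionTensorField, grid: VoxelGrid,
                       anchor: float = 1.0, det_floor_rel: float = 1e-3,
                       min_valid_fraction: float = 0.5
                       ) -> ScaleParameterField:
    """Direct scale-parameter recovery from two transversal currents.

    For each voxel, the curl-free electric field condition gives the 2x2
    system

        [ (D^-1 Jp)_y   -(D^-1 Jp)_x ] [d ln eta/dx]   [curl_z(D^-1 Jp) ]
        [ (D^-1 J2p)_y  -(D^-1 J2p)_x] [d ln eta/dy] = [curl_z(D^-1 J2p)]

    solved where the determinant (the cross product of the two transformed
    currents) is above ``det_floor_rel`` times its in-mask median magnitude
    scale.  The gradient field is then integrated globally by least squares
    (a Poisson-type problem on the mask) and anchored so mean(ln eta) =
    ln(anchor).  Raises if the currents are (near-)parallel on most of the
    domain — e.g. when the two montages are identical.
    """
    m = grid.domain_mask
    dx = grid.spacing[0] * 1e-3
    dy = grid.spacing[1] * 1e-3
    f1x, f1y = _dinv_j(D, Jp)
    f2x, f2y = _dinv_j(D, J2p)

    def curl_z(fx, fy):
        out = np.zeros(grid.shape)
        out[1:-1, 1:-1] = ((fy[2:, 1:-1] - fy[:-2, 1:-1]) / (2 * dx)
                           - (fx[1:-1, 2:] - fx[1:-1, :-2]) / (2 * dy))
        return out

    # grad(ln eta) x F = curl F  =>  F_y * d/dx - F_x * d/dy = curl_z F
    r1 = curl_z(f1x, f1y)
    r2 = curl_z(f2x, f2y)
    det = f1y * (-f2x) - (-f1x) * f2y      # = f1x*f2y - f1y*f2x (sign folded)
    mag = np.hypot(f1x, f1y) * np.hypot(f2x, f2y)
    med = np.median(mag[m])
    interior = ndimage.binary_erosion(m, iterations=1)
    valid = interior & (np.abs(det) > det_floor_rel * med)
    frac = valid.sum() / max(m.sum(), 1)
    if frac < min_valid_fraction:
        raise ValueError(
            f"injected currents are transversal on only {frac:.1%} of the "
            "domain (determinant below floor): the two-current system is "
            "rank-deficient — use linearly independent montages")
    with np.errstate(divide="ignore", invalid="ignore"):
        px = np.where(valid, (r1 * (-f2x) - (-f1x) * r2) / det, 0.0)
        py = np.where(valid, (f1y * r2 - r1 * f2y) / det, 0.0)

    # least-squares integration: find v with grad v ~ (px, py) on valid voxels
    idx = -np.ones(grid.shape, dtype=int)
    idx[m] = np.arange(m.sum())
    rows, cols, vals, rhs = [], [], [], []
    req = 0
    nx, ny = grid.shape
    for axis, p, h in ((0, px, dx), (1, py, dy)):
        sh = (1, 0) if axis == 0 else (0, 1)
        for i in range(nx - sh[0]):
            for j in range(ny - sh[1]):
                i2, j2 = i + sh[0], j + sh[1]
                if m[i, j] and m[i2, j2]:
                    pv = 0.5 * (p[i, j] + p[i2, j2])
                    ok = valid[i, j] or valid[i2, j2]
                    if not ok:
                        continue
                    rows += [req, req]
                    cols += [idx[i2, j2], idx[i, j]]
                    vals += [1.0 / h, -1.0 / h]
                    rhs.append(pv)
                    req += 1
    G = sparse.csr_matrix((vals, (rows, cols)), shape=(req, m.sum()))
    sol = lsqr(G, np.asarray(rhs), atol=1e-12, btol=1e-12, iter_lim=5000)[0]
    ln_eta = np.zeros(grid.shape)
    ln_eta[m] = sol - sol.mean() + np.log(anchor)
    eta = np.where(m, np.exp(ln_eta), 1.0)
    return ScaleParameterField(grid=grid, eta=eta, valid=valid)


# ---------------------------------------------------------------------------
# Diagnostics and outputs
# ---------------------------------------------------------------------------

@dataclass
class AngleMap:
    """Angle (degrees) between the velocity vector D grad u^n and grad u."""

    grid: VoxelGrid
    alpha: np.ndarray
    valid: np.ndarray


def angle_map(D: DiffusionTensorField, u_n: PotentialField,
              u_ref: PotentialField, floor: float = 1e-30) -> AngleMap:
    """alpha = arccos( (D grad u^n) . grad u / (|D grad u^n| |grad u|) ).

    Masked where either vector is below the norm floor; values in [0, 180].
    """
    if u_n.grid.shape != u_ref.grid.shape:
        raise ValueError("gradient fields on different grids")
    gxn, gyn = u_n.gradient()
    vx, vy = _velocity(D, gxn, gyn)
    gx, gy = u_ref.gradient()
    nv = np.hypot(vx, vy)
    ng = np.hypot(gx, gy)
    valid = u_n.grid.domain_mask & (nv > floor) & (ng > floor)
    cosa = np.where(valid, (vx * gx + vy * gy) / np.where(valid, nv * ng, 1.0),
                    1.0)
    alpha = np.degrees(np.arccos(np.clip(cosa, -1.0, 1.0)))
    return AngleMap(grid=u_n.grid, alpha=np.where(valid, alpha, 0.0),
                    valid=valid)


def assemble_outputs(eta: ScaleParameterField, D: DiffusionTensorField):
    """Conductivity tensor C = eta D (S/m) and mean conductivity
    c_hat = (C11 + C22 + C33)/3."""
    if eta.grid.shape != D.grid.shape:
        raise ValueError("eta and D grids do not match")
    C = ConductivityTensorField.from_eta_and_diffusion(eta, D)
    c = C.components
    mean_c = (c[..., 0] + c[..., 2] + c[..., 5]) / 3.0
    return C, mean_c


def mean_conductivity(C: ConductivityTensorField) -> np.ndarray:
    """c_hat = (C11 + C22 + C33)/3 from an assembled tensor."""
    c = C.components
    return (c[..., 0] + c[..., 2] + c[..., 5]) / 3.0
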