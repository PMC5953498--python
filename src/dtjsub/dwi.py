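"""Diffusion-weighted MR signal model and log-linear tensor estimation.

The mono-exponential signal model at a single b-value is

    rho_j = rho_0 * exp( -b g_j^T D g_j ),   j = 1..N_d,

with unit gradient directions g_j and the diffusion weighting

    b = gamma^2 delta^2 G^2 (Delta - delta/3)

(delta: gradient duration, Delta: separation of the paired gradients, G:
amplitude).  The tensor is fitted per voxel by ordinary least squares on
ln(rho_j/rho_0), the minimal estimator consistent with the model; the result
is projected to SPD by flooring eigenvalues (downstream steps invert D).
The single-b, b <= 1000 s/mm^2 regime is assumed, where the measured ADC is
dominated by the fast (extracellular) diffusion component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import DiffusionTensorField, VoxelGrid, _as_components
from .mrsignal import GAMMA

logger = logging.getLogger("dtjsub")


# ---------------------------------------------------------------------------
# Acquisition
# ---------------------------------------------------------------------------

def compute_b_value(delta: float, Delta: float, G: float,
                    gamma: float = GAMMA) -> float:
    """b = gamma^2 delta^2 G^2 (Delta - delta/3), returned in s/mm^2.

    Inputs in SI (s, T/m); the SI value (s/m^2) is converted by 1e-6.
    """
    if not (Delta >= delta > 0):
        raise ValueError("require Delta >= delta > 0")
    if G < 0:
        raise ValueError("gradient amplitude must be non-negative")
    b_si = gamma ** 2 * delta ** 2 * G ** 2 * (Delta - delta / 3.0)
    return b_si * 1e-6


def dual_axis_directions() -> np.ndarray:
    """Classic 6-direction dual-axis scheme (pairs of axes at 45 degrees)."""
    g = np.array([[1, 1, 0], [1, -1, 0], [1, 0, 1],
                  [1, 0, -1], [0, 1, 1], [0, 1, -1]], dtype=float)
    return g / np.linalg.norm(g, axis=1, keepdims=True)


def repulsion_directions(n: int, seed: int = 0, n_iter: int = 400) -> np.ndarray:
    """N roughly uniformly spread unit directions by electrostatic repulsion.

    Antipodally symmetric energy (directions and their negatives repel), so
    the set is well-spread for tensor estimation.  Deterministic for a seed.
    """
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    step = 0.05
    for _ in range(n_iter):
        force = np.zeros_like(g)
        for sgn in (1.0, -1.0):
            d = g[:, None, :] - sgn * g[None, :, :]
            r2 = (d ** 2).sum(-1)
            np.fill_diagonal(r2, np.inf)
            if sgn < 0:
                r2[r2 < 1e-12] = np.inf  # a direction and its own antipode
            force += (d / (r2 ** 1.5)[..., None]).sum(axis=1)
        # project force onto the tangent plane and take a small step
        force -= (force * g).sum(-1, keepdims=True) * g
        g += step * force / np.maximum(np.linalg.norm(force, axis=1,
                                                      keepdims=True), 1e-9)
        g /= np.linalg.norm(g, axis=1, keepdims=True)
    return g


@dataclass
class DwiAcquisition:
    """Single-shell DWI protocol: b-value (s/mm^2) and unit directions."""

    b: float
    directions: np.ndarray
    rho0: float = 1.0

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float)
        if self.b <= 0:
            raise ValueError("b-value must be positive")
        norms = np.linalg.norm(self.directions, axis=1)
        if np.abs(norms - 1.0).max() > 1e-10:
            raise ValueError("gradient directions must be unit vectors")

    @property
    def n_directions(self) -> int:
        return len(self.directions)

    def design_matrix(self) -> np.ndarray:
        """Rows b*[gx^2, 2gxgy, gy^2, 2gxgz, 2gygz, gz^2] so that
        design @ components = b g^T D g (lower-triangular order)."""
        g = self.directions
        return self.b * np.column_stack([
            g[:, 0] ** 2, 2 * g[:, 0] * g[:, 1], g[:, 1] ** 2,
            2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2], g[:, 2] ** 2])


def default_dwi_acquisition(n_directions: int = 32, b: float = 800.0,
                            seed: int = 0) -> DwiAcquisition:
    """b = 800 s/mm^2 with 32 repulsion-spread directions."""
    return DwiAcquisition(b=b, directions=repulsion_directions(n_directions,
                                                               seed=seed))


@dataclass
class DwiSignalSet:
    """Per-direction diffusion-weighted magnitudes plus the b=0 reference."""

    grid: VoxelGrid
    rho: np.ndarray          # (N_d, nx, ny)
    rho0: np.ndarray         # (nx, ny)
    acq: DwiAcquisition = None


# ---------------------------------------------------------------------------
# Simulation and fitting
# ---------------------------------------------------------------------------

def simulate_dwi(D: DiffusionTensorField, acq: DwiAcquisition,
                 noise_sd: float = 0.0, seed: int = 0) -> DwiSignalSet:
    """Forward-simulate single-shell DWI magnitudes.

    Noise is Rician: independent complex Gaussian with the given channel sd
    added to the noise-free signal before taking the magnitude.  Deterministic
    for a fixed seed.
    """
    X = acq.design_matrix()              # (N_d, 6)
    expo = np.einsum("dk,xyk->dxy", X, D.components)
    rho = acq.rho0 * np.exp(-expo)
    rho0 = np.full(D.grid.shape, float(acq.rho0))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        rho = np.abs(rho + noise_sd * (rng.standard_normal(rho.shape)
                                       + 1j * rng.standard_normal(rho.shape)))
        rho0 = np.abs(rho0 + noise_sd * (rng.standard_normal(rho0.shape)
                                         + 1j * rng.standard_normal(rho0.shape)))
    return DwiSignalSet(grid=D.grid, rho=rho, rho0=rho0, acq=acq)


def fit_diffusion_tensor(signals: DwiSignalSet, acq: DwiAcquisition = None,
                         eigen_floor_rel: float = 1e-6) -> DiffusionTensorField:
    """Per-voxel log-linear least-squares tensor fit, projected to SPD.

    Solves ln(rho_j/rho_0) = -b g_j^T D g_j in the least-squares sense.
    Needs at least 6 directions with a full-rank design; non-positive signals
    are masked out of the fit voxel-wise.  Exact recovery at zero noise.
    """
    acq = acq or signals.acq
    if acq.n_directions < 6:
        raise ValueError("tensor fit needs at least 6 gradient directions")
    X = acq.design_matrix()
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError("rank-deficient gradient direction set")
    nd, nx, ny = signals.rho.shape
    ok = (signals.rho > 0) & (signals.rho0[None] > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = -np.log(signals.rho / signals.rho0[None])   # (N_d, nx, ny)
    y = np.where(ok, y, 0.0)
    yv = y.reshape(nd, -1)
    okv = ok.reshape(nd, -1)
    comp = np.zeros((nx * ny, 6))
    full = okv.all(axis=0)
    if full.any():
        sol, *_ = np.linalg.lstsq(X, yv[:, full], rcond=None)
        comp[full] = sol.T
    # voxels with some masked directions: fit individually
    for v in np.nonzero(~full & okv.any(axis=0))[0]:
        rows = okv[:, v]
        if rows.sum() >= 6 and np.linalg.matrix_rank(X[rows]) == 6:
            comp[v], *_ = np.linalg.lstsq(X[rows], yv[rows, v], rcond=None)
    comp = comp.reshape(nx, ny, 6)
    # SPD projection: floor eigenvalues at eigen_floor_rel * largest
    from .grids import _as_matrices
    lam, vec = np.linalg.eigh(_as_matrices(comp))
    floor = np.maximum(lam[..., -1:], 0.0) * eigen_floor_rel
    floor = np.maximum(floor, 1e-30)
    lam = np.maximum(lam, floor)
    mats = np.einsum("...ik,...k,...jk->...ij", vec, lam, vec)
    return DiffusionTensorField(grid=signals.grid,
                                components=_as_components(mats))


def eigendecompose(D) -> tuple:
    """Eigensystem of a symmetric 3x3 tensor (array or field).

    Returns ``(S, lam)`` with eigenvalues descending and a deterministic
    sign convention: the first nonzero component of each eigenvector is made
    positive, then the third vector is flipped if needed so the basis is
    right-handed.  Reconstruction ``S diag(lam) S^T`` is exact to rounding.
    """
    if isinstance(D, DiffusionTensorField):
        mats = 0.5 * (D.as_matrices() + np.swapaxes(D.as_matrices(), -1, -2))
    else:
        mats = np.asarray(D, dtype=float)
        mats = 0.5 * (mats + np.swapaxes(mats, -1, -2))
    lam, vec = np.linalg.eigh(mats)
    order = np.argsort(lam, axis=-1)[..., ::-1]
    lam = np.take_along_axis(lam, order, axis=-1)
    vec = np.take_along_axis(vec, order[..., None, :], axis=-1)
    # sign convention per eigenvector
    comp = np.moveaxis(vec, -2, 0)        # (3(row), ..., 3(col))
    first_nz = np.where(np.abs(comp[0]) > 1e-12, np.sign(comp[0]),
                        np.where(np.abs(comp[1]) > 1e-12, np.sign(comp[1]),
                                 np.sign(comp[2])))
    first_nz = np.where(first_nz == 0, 1.0, first_nz)
    vec = vec * first_nz[..., None, :]
    det = np.linalg.det(vec)
    vec[..., :, 2] *= np.where(det < 0, -1.0, 1.0)[..., None]
    return vec, lam
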