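"""Voxel grids, electrode montages, and synthetic conductivity/diffusion phantoms.

The reconstruction operates on a regular, voxel-centered 2-D grid representing
one imaging slice of a slab of tissue.  Conventions used throughout the
package:

* 0-based voxel indices, axis order ``(x, y)`` with x fastest-varying;
* voxel centers at ``origin + (index + 0.5) * spacing`` (mm);
* half-open physical extents;
* the slab has a finite thickness in z (``thickness_mm``) over which all
  fields are taken to be z-invariant.

Tensor fields store the six unique components in lower-triangular order
``(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz)``.  Diffusivities are in mm^2/s; the scale
parameter eta linking conductivity to diffusivity is stored in S.s/mm^3 so
that ``sigma[S/m] = 1e3 * eta * D``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger("dtjsub")

#: multiply eta [S.s/mm^3] * D [mm^2/s] by this to obtain conductivity in S/m
ETA_D_TO_SI = 1.0e3

#: smallest admissible diffusion eigenvalue relative to the largest
EIGEN_FLOOR_REL = 1.0e-6

# lower-triangular component order and the (row, col) index of each
TENSOR_COMPONENTS = ("xx", "xy", "yy", "xz", "yz", "zz")
_TRI = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]


# ---------------------------------------------------------------------------
# VoxelGrid
# ---------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    """Regular 2-D voxel grid for one imaging slice of a slab.

    Parameters
    ----------
    shape : tuple of int
        Voxel counts ``(nx, ny)``.
    spacing : tuple of float
        Voxel size per axis in mm.
    origin : tuple of float
        Physical coordinate (mm) of the corner of voxel ``(0, 0)``.
    domain_mask : ndarray of bool
        In-domain voxels (the imaging object Omega); must be one connected
        component.
    thickness_mm : float
        Slab extent along z represented by this slice.
    slice_index : int or None
        Which z-plane this slice is when part of a stack (bookkeeping only).
    """

    shape: tuple
    spacing: tuple
    origin: tuple = (0.0, 0.0)
    domain_mask: np.ndarray = None
    thickness_mm: float = 5.0
    slice_index: int | None = None
    # boundary faces as structured arrays, filled in __post_init__
    boundary_faces: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        if len(self.shape) != 2:
            raise ValueError("only 2-D slice grids are supported")
        if any(n < 3 for n in self.shape):
            raise ValueError(f"grid shape {self.shape} below minimum 3 voxels per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacings must be positive")
        if self.thickness_mm <= 0:
            raise ValueError("slab thickness must be positive")
        if self.domain_mask is None:
            self.domain_mask = np.ones(self.shape, dtype=bool)
        self.domain_mask = np.asarray(self.domain_mask, dtype=bool)
        if self.domain_mask.shape != self.shape:
            raise ValueError("domain_mask shape mismatch")
        if not self.domain_mask.any():
            raise ValueError("empty domain mask")
        _, ncomp = ndimage.label(self.domain_mask)
        if ncomp != 1:
            raise ValueError(
                f"domain mask must be a single connected component, found {ncomp}"
            )
        self.boundary_faces = self._enumerate_boundary_faces()

    # -- geometry helpers ---------------------------------------------------

    @property
    def n_in(self) -> int:
        return int(self.domain_mask.sum())

    def voxel_centers(self):
        """Physical voxel-center coordinates ``(X, Y)`` in mm."""
        nx, ny = self.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.spacing[0]
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.spacing[1]
        return np.meshgrid(x, y, indexing="ij")

    def _enumerate_boundary_faces(self) -> np.ndarray:
        """Boundary faces of the mask, ordered lexicographically by voxel
        index then by face direction (-x, +x, -y, +y)."""
        m = self.domain_mask
        nx, ny = self.shape
        pad = np.zeros((nx + 2, ny + 2), dtype=bool)
        pad[1:-1, 1:-1] = m
        recs = []
        dirs = [(-1, 0, 0), (1, 0, 1), (0, -1, 2), (0, 1, 3)]
        for i in range(nx):
            for j in range(ny):
                if not m[i, j]:
                    continue
                for di, dj, d in dirs:
                    if not pad[1 + i + di, 1 + j + dj]:
                        recs.append((i, j, d))
        return np.array(recs, dtype=[("i", int), ("j", int), ("dir", int)])

    def face_lengths_mm(self) -> np.ndarray:
        """In-plane length of each boundary face (mm)."""
        dx, dy = self.spacing
        # faces normal to x have length dy, faces normal to y length dx
        return np.where(self.boundary_faces["dir"] < 2, dy, dx)

    def face_areas_m2(self) -> np.ndarray:
        """Physical area of each boundary face (m^2), including slab thickness."""
        return self.face_lengths_mm() * 1e-3 * self.thickness_mm * 1e-3

    def face_centers_mm(self):
        """In-plane physical centers of the boundary faces (mm)."""
        bf = self.boundary_faces
        dx, dy = self.spacing
        cx = self.origin[0] + (bf["i"] + 0.5) * dx
        cy = self.origin[1] + (bf["j"] + 0.5) * dy
        off = {0: (-0.5 * dx, 0.0), 1: (0.5 * dx, 0.0),
               2: (0.0, -0.5 * dy), 3: (0.0, 0.5 * dy)}
        ox = np.array([off[d][0] for d in bf["dir"]])
        oy = np.array([off[d][1] for d in bf["dir"]])
        return cx + ox, cy + oy


def node_grid(grid: VoxelGrid) -> VoxelGrid:
    """The dual grid whose voxel centers sit on the corners (nodes) of
    ``grid``.  Used to co-register flux-density samples with the nodes of the
    stream-function discretization."""
    nx, ny = grid.shape
    return VoxelGrid(shape=(nx + 1, ny + 1), spacing=grid.spacing,
                     origin=(grid.origin[0] - 0.5 * grid.spacing[0],
                             grid.origin[1] - 0.5 * grid.spacing[1]),
                     thickness_mm=grid.thickness_mm)


def make_grid(shape, spacing, mask_spec="full", origin=(0.0, 0.0),
              thickness_mm=5.0) -> VoxelGrid:
    """Build a :class:`VoxelGrid` with a named mask.

    ``mask_spec`` is ``"full"`` (whole rectangle), ``("disk", radius_voxels)``,
    ``("ellipse", rx, ry)`` (semi-axes in voxels), or an explicit boolean
    array.  Radii are measured from the grid center in voxel units.
    """
    shape = tuple(int(n) for n in shape)
    spacing = (spacing, spacing) if np.isscalar(spacing) else tuple(spacing)
    nx, ny = shape
    if isinstance(mask_spec, str) and mask_spec == "full":
        mask = np.ones(shape, dtype=bool)
    elif isinstance(mask_spec, np.ndarray):
        mask = mask_spec.astype(bool)
    else:
        kind = mask_spec[0]
        ii, jj = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5,
                             indexing="ij")
        ci, cj = nx / 2.0, ny / 2.0
        if kind == "disk":
            r = float(mask_spec[1])
            mask = (ii - ci) ** 2 + (jj - cj) ** 2 <= r ** 2
        elif kind == "ellipse":
            rx, ry = float(mask_spec[1]), float(mask_spec[2])
            mask = ((ii - ci) / rx) ** 2 + ((jj - cj) / ry) ** 2 <= 1.0
        else:
            raise ValueError(f"unknown mask spec {mask_spec!r}")
    return VoxelGrid(shape=shape, spacing=spacing, origin=origin,
                     domain_mask=mask, thickness_mm=thickness_mm)


# ---------------------------------------------------------------------------
# Electrodes
# ---------------------------------------------------------------------------

@dataclass
class ElectrodeConfiguration:
    """Surface electrode montage with prescribed normal current density.

    ``g`` holds the outward normal current density (A/m^2) for every boundary
    face of the grid; it is uniform over each electrode patch, zero elsewhere,
    and the total signed flux vanishes (current conservation).
    """

    grid: VoxelGrid
    patches: list            # list of index arrays into grid.boundary_faces
    polarities: list         # +1 source / -1 sink per patch
    injected_current: float  # A
    g: np.ndarray = None     # A/m^2 per boundary face

    def __post_init__(self):
        areas = self.grid.face_areas_m2()
        used = np.zeros(len(areas), dtype=bool)
        n_pos = sum(1 for p in self.polarities if p > 0)
        n_neg = sum(1 for p in self.polarities if p < 0)
        if n_pos == 0 or n_neg == 0:
            raise ValueError("montage needs at least one source and one sink patch")
        g = np.zeros(len(areas))
        for idx, pol in zip(self.patches, self.polarities):
            idx = np.asarray(idx, dtype=int)
            if idx.size == 0:
                raise ValueError("zero-area electrode patch")
            if used[idx].any():
                raise ValueError("electrode patches overlap")
            used[idx] = True
            if pol == 0:  # attached but unused pair: no current through it
                continue
            patch_area = areas[idx].sum()
            # uniform normal current density over the patch; per-polarity
            # current split evenly across same-sign patches
            share = self.injected_current / (n_pos if pol > 0 else n_neg)
            g[idx] = pol * share / patch_area
        self.g = g
        net = np.sum(g * areas)
        scale = abs(self.injected_current) if self.injected_current else 1.0
        if abs(net) > 1e-12 * scale:
            raise AssertionError("electrode flux not conserved")

    def total_flux(self) -> float:
        """Net signed boundary flux (A); zero for a conserved montage."""
        return float(np.sum(self.g * self.grid.face_areas_m2()))


def make_electrodes(grid: VoxelGrid, montage_spec, current_mA: float = 2.0
                    ) -> ElectrodeConfiguration:
    """Build an electrode montage.

    ``montage_spec`` is a list of patch specs; each patch is either

    * ``{"kind": "angle", "center_deg": c, "width_deg": w, "polarity": p}`` —
      boundary faces whose center lies within the angular arc (measured from
      the mask centroid, counter-clockwise from +x), or
    * ``{"kind": "edge", "edge": "left"|"right"|"bottom"|"top",
      "lo": i0, "hi": i1, "polarity": p}`` — faces on a rectangle edge with
      transverse index in ``[i0, i1)`` (``lo``/``hi`` optional = whole edge).

    The default injected current is 2 mA, the tDCS level used throughout.
    """
    bf = grid.boundary_faces
    fx, fy = grid.face_centers_mm()
    X, Y = grid.voxel_centers()
    cx = X[grid.domain_mask].mean()
    cy = Y[grid.domain_mask].mean()
    patches, polarities = [], []
    for spec in montage_spec:
        kind = spec.get("kind", "angle")
        pol = int(spec.get("polarity", 1))
        if kind == "angle":
            ang = np.degrees(np.arctan2(fy - cy, fx - cx)) % 360.0
            c = float(spec["center_deg"]) % 360.0
            w = float(spec["width_deg"])
            d = np.abs((ang - c + 180.0) % 360.0 - 180.0)
            idx = np.where(d <= w / 2.0)[0]
        elif kind == "edge":
            edge = spec["edge"]
            dirmap = {"left": 0, "right": 1, "bottom": 2, "top": 3}
            d = dirmap[edge]
            sel = bf["dir"] == d
            t = bf["j"] if d < 2 else bf["i"]
            lo = int(spec.get("lo", 0))
            hi = int(spec.get("hi", max(grid.shape)))
            idx = np.where(sel & (t >= lo) & (t < hi))[0]
        elif kind == "faces":
            idx = np.asarray(spec["indices"], dtype=int)
        else:
            raise ValueError(f"unknown patch kind {kind!r}")
        patches.append(idx)
        polarities.append(pol)
    return ElectrodeConfiguration(grid=grid, patches=patches,
                                  polarities=polarities,
                                  injected_current=current_mA * 1e-3)


# ---------------------------------------------------------------------------
# Tensor and scalar fields
# ---------------------------------------------------------------------------

def _as_matrices(components: np.ndarray) -> np.ndarray:
    """(..., 6) lower-tri components -> (..., 3, 3) symmetric matrices."""
    out = np.zeros(components.shape[:-1] + (3, 3))
    for k, (r, c) in enumerate(_TRI):
        out[..., r, c] = components[..., k]
        out[..., c, r] = components[..., k]
    return out


def _as_components(mats: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrices -> (..., 6) lower-tri components."""
    out = np.zeros(mats.shape[:-2] + (6,))
    for k, (r, c) in enumerate(_TRI):
        out[..., k] = mats[..., r, c]
    return out


@dataclass
class DiffusionTensorField:
    """Per-voxel symmetric positive-definite water diffusion tensor (mm^2/s)."""

    grid: VoxelGrid
    components: np.ndarray  # (nx, ny, 6) lower-tri order
    _eig: tuple = field(default=None, repr=False)

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        if self.components.shape != self.grid.shape + (6,):
            raise ValueError("tensor component array shape mismatch")

    def as_matrices(self) -> np.ndarray:
        return _as_matrices(self.components)

    def eigensystem(self):
        """Eigenvalues (descending) and eigenvectors, computed lazily.

        Returns ``(lam, S)`` with ``lam`` of shape (nx, ny, 3) sorted
        descending and ``S[..., :, k]`` the unit eigenvector of ``lam[..., k]``.
        """
        if self._eig is None:
            lam, vec = np.linalg.eigh(self.as_matrices())
            order = np.argsort(lam, axis=-1)[..., ::-1]
            lam = np.take_along_axis(lam, order, axis=-1)
            vec = np.take_along_axis(vec, order[..., None, :], axis=-1)
            self._eig = (lam, vec)
        return self._eig

    def validate_spd(self, eigen_floor: float = 0.0) -> float:
        """Smallest eigenvalue over the mask; raises if not SPD."""
        lam, _ = self.eigensystem()
        lmin = float(lam[self.grid.domain_mask].min())
        if lmin <= eigen_floor:
            raise ValueError(f"diffusion tensor not SPD: min eigenvalue {lmin}")
        return lmin


@dataclass
class ScaleParameterField:
    """Per-voxel positive scalar eta with C = eta * D (stored S.s/mm^3)."""

    grid: VoxelGrid
    eta: np.ndarray
    valid: np.ndarray = None

    def __post_init__(self):
        self.eta = np.asarray(self.eta, dtype=float)
        if self.valid is None:
            self.valid = self.grid.domain_mask.copy()
        if not np.isfinite(self.eta[self.grid.domain_mask]).all():
            raise ValueError("eta not finite on domain mask")
        if (self.eta[self.valid] <= 0).any():
            raise ValueError("eta must be positive on its validity mask")


@dataclass
class ConductivityTensorField:
    """Per-voxel symmetric conductivity tensor in S/m."""

    grid: VoxelGrid
    components: np.ndarray  # (nx, ny, 6), S/m

    def as_matrices(self) -> np.ndarray:
        return _as_matrices(self.components)

    @classmethod
    def from_eta_and_diffusion(cls, eta: ScaleParameterField,
                               D: DiffusionTensorField
                               ) -> "ConductivityTensorField":
        """C = eta * D, converted from (S.s/mm^3)*(mm^2/s) to S/m."""
        comp = ETA_D_TO_SI * eta.eta[..., None] * D.components
        return cls(grid=D.grid, components=comp)

    @classmethod
    def isotropic(cls, grid: VoxelGrid, sigma) -> "ConductivityTensorField":
        """Scalar conductivity sigma (S/m, scalar or per-voxel) as a tensor."""
        comp = np.zeros(grid.shape + (6,))
        s = np.broadcast_to(np.asarray(sigma, dtype=float), grid.shape)
        comp[..., 0] = s
        comp[..., 2] = s
        comp[..., 5] = s
        return cls(grid=grid, components=comp)


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

def _rotation_from_angle(theta):
    """In-plane rotation matrices sending x to the fiber direction."""
    c, s = np.cos(theta), np.sin(theta)
    R = np.zeros(theta.shape + (3, 3))
    R[..., 0, 0] = c
    R[..., 0, 1] = -s
    R[..., 1, 0] = s
    R[..., 1, 1] = c
    R[..., 2, 2] = 1.0
    return R


def make_phantom(grid: VoxelGrid, fiber_spec, anomaly_spec, seed: int = 0):
    """Seeded synthetic phantom: a diffusion tensor field plus an eta map.

    ``fiber_spec``: ``{"pattern": "isotropic"|"parallel"|"concentric",
    "eigenvalues": (l1, l2, l3) mm^2/s, "angle_deg": ...}``.  ``parallel``
    aligns the principal eigenvector with a fixed in-plane direction
    (mimicking a white-matter bundle); ``concentric`` aligns it tangentially
    around the grid center (mimicking curving fiber arcs).

    ``anomaly_spec``: ``{"background": eta0, "inclusions": [{"center": (cx, cy)
    voxels, "radius": r voxels, "eta": v}, ...]}`` for piecewise-constant eta,
    or ``{"kind": "exponential", "eta0": e, "ax": a, "ay": b}`` for a smooth
    eta = eta0*exp(ax*x + ay*y) with x, y in units of the domain width.
    An optional ``"edge_smooth"`` (Gaussian sd in voxels, default 0) mimics
    the partial-volume blur of MRI-derived parameter maps at inclusion
    boundaries; with 0 the eta map is exactly piecewise constant.

    The generator is deterministic for a fixed seed (the seed feeds the
    optional ``"jitter"`` fraction of the fiber angle, default 0).
    """
    rng = np.random.default_rng(seed)
    nx, ny = grid.shape
    lam = np.asarray(fiber_spec.get("eigenvalues", (1.7e-3, 0.3e-3, 0.3e-3)),
                     dtype=float)
    if (lam <= 0).any():
        raise ValueError("diffusion eigenvalues must be positive")
    pattern = fiber_spec.get("pattern", "parallel")
    ii, jj = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5, indexing="ij")
    if pattern == "isotropic":
        theta = np.zeros((nx, ny))
        lam = np.array([lam.mean()] * 3)
    elif pattern == "parallel":
        theta = np.full((nx, ny), np.radians(fiber_spec.get("angle_deg", 0.0)))
    elif pattern == "concentric":
        ci, cj = nx / 2.0, ny / 2.0
        theta = np.arctan2(jj - cj, ii - ci) + np.pi / 2.0  # tangential
    else:
        raise ValueError(f"unknown fiber pattern {pattern!r}")
    jitter = float(fiber_spec.get("jitter", 0.0))
    if jitter > 0:
        theta = theta + jitter * rng.standard_normal((nx, ny))
    R = _rotation_from_angle(theta)
    Dtilde = np.diag(lam)
    mats = R @ Dtilde @ np.swapaxes(R, -1, -2)
    D = DiffusionTensorField(grid=grid, components=_as_components(mats))

    if anomaly_spec.get("kind") == "exponential":
        eta0 = float(anomaly_spec.get("eta0", 1.0))
        ax = float(anomaly_spec.get("ax", 0.0))
        ay = float(anomaly_spec.get("ay", 0.0))
        eta = eta0 * np.exp(ax * ii / nx + ay * jj / ny)
    else:
        eta = np.full((nx, ny), float(anomaly_spec.get("background", 1.0)))
        for inc in anomaly_spec.get("inclusions", []):
            ci, cj = inc["center"]
            r = float(inc["radius"])
            disk = (ii - ci) ** 2 + (jj - cj) ** 2 <= r ** 2
            if not (disk <= grid.domain_mask).all():
                raise ValueError("anomaly extends outside the domain mask")
            eta[disk] = float(inc["eta"])
        edge_smooth = float(anomaly_spec.get("edge_smooth", 0.0))
        if edge_smooth > 0:
            eta = ndimage.gaussian_filter(eta, edge_smooth)
    eta_field = ScaleParameterField(grid=grid, eta=eta)
    D.validate_spd(eigen_floor=EIGEN_FLOOR_REL * lam.max())
    return D, eta_field


# ---------------------------------------------------------------------------
# Sen-Torquato effective-medium relation
# ---------------------------------------------------------------------------

def sen_torquato_eigenvalues(lam_d, sigma_ext, d_ext, d_int):
    """Conductivity eigenvalues from diffusion eigenvalues under the
    two-phase effective-medium model (small intracellular diffusivity).

    lam_sigma_i = (sigma_ext/d_ext) * [ lam_di*(d_int/(3 d_ext) + 1)
                    + lam_di^2 * d_int/(3 d_ext^2) + (2/3)*d_int ]

    where ``sigma_ext`` is the extracellular conductivity and ``d_ext``,
    ``d_int`` the extra/intracellular diffusion coefficients.  For
    ``d_int = 0`` this reduces to the linear law
    ``lam_sigma = (sigma_ext/d_ext) * lam_d``.
    """
    lam_d = np.asarray(lam_d, dtype=float)
    if sigma_ext <= 0 or d_ext <= 0 or d_int < 0:
        raise ValueError("require sigma_ext > 0, d_ext > 0, d_int >= 0")
    bracket = (lam_d * (d_int / (3.0 * d_ext) + 1.0)
               + lam_d ** 2 * d_int / (3.0 * d_ext ** 2)
               + (2.0 / 3.0) * d_int)
    return (sigma_ext / d_ext) * bracket
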