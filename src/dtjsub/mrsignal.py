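"""MR phase encoding of the current-induced magnetic flux density.

During an injected-current multi-echo acquisition, the current-induced Bz
accumulates as a phase offset of the complex MR signal.  Comparing the l-th
echo with current on, S^l, against the reference without current, S^0, the
flux density is recovered per echo as

    Bz^l = (1 / (gamma * TE_l)) * atan2( Im(S^l conj(S^0)), Re(S^l conj(S^0)) )

with gamma the proton gyromagnetic ratio.  tDCS currents (1-2 mA) induce Bz
of a few nT, so the encoded phase is far below pi at realistic echo times and
no unwrapping is performed — a wrap would indicate a mis-set acquisition and
is treated as a hard error.

Echoes are combined by a convex weighting; per-echo noise of the phase
estimate scales like 1/(TE_l |S^l| |S^0|), so inverse-variance weights
proportional to (TE_l |S^l|)^2 are used.  The noise standard deviation of the
combined Bz follows sd(Bz) ∝ 1/(T_c |S^c|) with T_c the current-injection
width per repetition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .forward import FluxDensityField
from .grids import VoxelGrid

logger = logging.getLogger("dtjsub")

#: gyromagnetic ratio of hydrogen, rad/(T.s)
GAMMA = 26.75e7


@dataclass
class MultiEchoAcquisition:
    """Multi-echo injected-current acquisition parameters.

    ``echo_times`` in seconds, strictly increasing; ``T_c`` is the current
    injection width per TR (s); ``noise_sd`` is the standard deviation of
    each real/imaginary channel of the complex images (same arbitrary units
    as the magnitude).
    """

    echo_times: np.ndarray
    T_c: float = 0.25
    noise_sd: float = 0.0
    seed: int = 0
    gamma: float = GAMMA

    def __post_init__(self):
        self.echo_times = np.atleast_1d(np.asarray(self.echo_times, dtype=float))
        if self.echo_times.size < 1:
            raise ValueError("need at least one echo")
        if (np.diff(self.echo_times) <= 0).any():
            raise ValueError("echo times must be strictly increasing")
        if (self.echo_times <= 0).any():
            raise ValueError("echo times must be positive")

    @property
    def n_echoes(self) -> int:
        return self.echo_times.size


def default_acquisition(n_echoes: int = 13, first_te: float = 2.3e-3,
                        noise_sd: float = 0.0, seed: int = 0
                        ) -> MultiEchoAcquisition:
    """13-echo multi-gradient-echo protocol with 2.3 ms echo spacing."""
    te = first_te * np.arange(1, n_echoes + 1)
    return MultiEchoAcquisition(echo_times=te, noise_sd=noise_sd, seed=seed)


@dataclass
class ComplexImageSet:
    """Reference image S^0 (no current) and per-echo images S^l (current on)."""

    grid: VoxelGrid
    S0: np.ndarray          # (nx, ny) complex
    S: np.ndarray           # (L, nx, ny) complex
    acq: MultiEchoAcquisition = field(repr=False, default=None)


def simulate_signals(Bz: FluxDensityField, acq: MultiEchoAcquisition,
                     magnitude) -> ComplexImageSet:
    """Encode Bz into complex multi-echo images.

    S^l = magnitude * exp(i gamma TE_l Bz) + complex Gaussian noise;
    S^0 = magnitude + noise.  Raises if the encoded phase would wrap.

    ``magnitude`` may be a scalar, a per-voxel image, a per-echo vector of
    length N_E (e.g. a T2* decay), or a full (N_E, nx, ny) stack; the
    reference S^0 uses the first-echo magnitude.
    """
    grid = Bz.grid
    magnitude = np.asarray(magnitude, dtype=float)
    L = acq.n_echoes
    if magnitude.ndim == 1 and magnitude.shape == (L,):
        magnitude = magnitude[:, None, None]
    mag = np.broadcast_to(magnitude, (L,) + grid.shape)
    phase = acq.gamma * acq.echo_times[:, None, None] * Bz.Bz[None, :, :]
    worst = np.unravel_index(np.argmax(np.abs(phase)), phase.shape)
    if np.abs(phase[worst]) >= np.pi:
        raise ValueError(
            f"phase wrap: |gamma*TE*Bz| = {abs(phase[worst]):.3f} rad >= pi at "
            f"echo {worst[0]}, voxel {worst[1:]} — reduce TE or current")
    rng = np.random.default_rng(acq.seed)
    S = mag * np.exp(1j * phase)
    S0 = mag[0].astype(complex)
    if acq.noise_sd > 0:
        sh = S.shape
        S = S + acq.noise_sd * (rng.standard_normal(sh)
                                + 1j * rng.standard_normal(sh))
        S0 = S0 + acq.noise_sd * (rng.standard_normal(grid.shape)
                                  + 1j * rng.standard_normal(grid.shape))
    return ComplexImageSet(grid=grid, S0=S0, S=S, acq=acq)


def measure_bz(images: ComplexImageSet, acq: MultiEchoAcquisition = None):
    """Per-echo Bz from the phase difference of S^l against S^0.

    With P = S^l conj(S^0), alpha = Im(P) and beta = Re(P), the estimate is
    Bz^l = atan2(alpha, beta) / (gamma TE_l).  Voxels with vanishing
    magnitude in either image are masked (set to 0), not propagated.
    Exact inverse of :func:`simulate_signals` at zero noise.
    """
    acq = acq or images.acq
    P = images.S * np.conj(images.S0)[None]
    ok = np.abs(images.S0)[None] * np.abs(images.S) > 0
    bz = np.where(ok, np.arctan2(P.imag, P.real), 0.0)
    bz = bz / (acq.gamma * acq.echo_times[:, None, None])
    return [FluxDensityField(grid=images.grid, Bz=bz[l], provenance="measured")
            for l in range(acq.n_echoes)]


def echo_weights(images: ComplexImageSet, acq: MultiEchoAcquisition = None
                 ) -> np.ndarray:
    """Per-voxel convex combination weights, w_l ∝ (TE_l |S^l|)^2.

    This is the minimum-variance (inverse-variance) weighting under the
    per-echo phase-noise model sd(Bz^l) ∝ 1/(TE_l |S^l|).
    """
    acq = acq or images.acq
    w = (acq.echo_times[:, None, None] * np.abs(images.S)) ** 2
    tot = w.sum(axis=0)
    tot = np.where(tot > 0, tot, 1.0)
    w = np.where(w.sum(axis=0, keepdims=True) > 0, w / tot, 1.0 / acq.n_echoes)
    return w


def combine_echoes(bz_list, images: ComplexImageSet,
                   acq: MultiEchoAcquisition = None) -> FluxDensityField:
    """Weighted combination Bz = sum_l w_l Bz^l with convex per-voxel weights."""
    acq = acq or images.acq
    if len(bz_list) != acq.n_echoes:
        raise ValueError("one Bz field per echo required")
    w = echo_weights(images, acq)
    bz = np.stack([f.Bz for f in bz_list])
    return FluxDensityField(grid=bz_list[0].grid, Bz=(w * bz).sum(axis=0),
                            provenance="recombined")


def noise_sd_model(T_c: float, S_mag, k: float = 1.0):
    """Noise standard deviation of the measured Bz: sd = k / (T_c |S^c|).

    ``k`` is a calibration constant absorbing gamma and sequence details;
    used to choose simulation noise levels consistent with the injection
    width and the signal magnitude.
    """
    S_mag = np.asarray(S_mag, dtype=float)
    if T_c <= 0 or (S_mag <= 0).any():
        raise ValueError("T_c and |S^c| must be positive")
    return k / (T_c * S_mag)
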