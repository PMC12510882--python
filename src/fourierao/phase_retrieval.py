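"""Phase retrieval from a single-bead PSF: the package's verification oracle.

Alternating projections (Gerchberg-Saxton over the z-stack): propagate a
unit-amplitude pupil guess to every plane of the measured widefield PSF,
replace each plane's modulus by the measurement, propagate back, and
average the pupil estimates under the NA support constraint. The
retrieved pupil phase is then projected onto the Zernike basis, with
piston, tip, tilt and defocus removed (they encode only intensity
offsets or bead position, not image quality).

The oracle's contract, exercised in the tests: for a noiseless simulated
PSF with aberrations up to ~0.15 lambda RMS it recovers every
coefficient to better than 0.02 lambda, which makes it an independent
instrument for checking the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import fft as sfft
from skimage.restoration import unwrap_phase

from .optics import OpticalConfig, PSFVolume, _kz_map, make_pupil
from .zernike import (EXCLUDED_MODES, PhaseMap, Wavefront, all_modes,
                      zernike_values)
from .optics import PupilFunction

__all__ = ["RetrievalConfig", "RetrievalResult", "retrieve", "residual_rms"]


@dataclass(frozen=True)
class RetrievalConfig:
    """Iteration budget and convergence tolerance of the retrieval."""

    iterations: int = 200
    tolerance: float = 1e-6      # relative pupil-phase change per sweep
    recenter: bool = True        # shift the brightest voxel to the center

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("need at least one iteration")


@dataclass
class RetrievalResult:
    pupil: PupilFunction
    wavefront: Wavefront          # sensed modes only (n <= 4, 11 modes)
    converged: bool
    iterations_run: int
    final_change: float           # last relative phase update


def retrieve(psf: PSFVolume, cfg: Optional[OpticalConfig] = None,
             rcfg: Optional[RetrievalConfig] = None) -> RetrievalResult:
    """Recover the pupil and Zernike coefficients from a widefield PSF.

    Assumes a single dominant, (near-)centered subdiffractive emitter —
    the classic fiducial-bead measurement. The pupil amplitude is held
    at the uniform NA disk; only the phase is estimated.
    """
    cfg = cfg or psf.config
    rcfg = rcfg or RetrievalConfig()
    intensity = np.asarray(psf.intensity, dtype=float)
    D, H, W = intensity.shape

    if rcfg.recenter:
        peak = np.unravel_index(intensity.argmax(), intensity.shape)
        shift = (D // 2 - peak[0], H // 2 - peak[1], W // 2 - peak[2])
        intensity = np.roll(intensity, shift, axis=(0, 1, 2))

    measured = np.sqrt(np.maximum(intensity, 0.0))

    pupil0 = make_pupil(cfg)
    mask = pupil0.support
    n_mask = mask.sum()
    kz = _kz_map(cfg)
    kz_rel = np.where(mask, kz - kz[H // 2, W // 2], 0.0)
    z = (np.arange(D) - D // 2) * cfg.dz
    defocus = np.exp(1j * kz_rel[None] * z[:, None, None])  # (D, H, W)

    # per-plane energy of a unit-amplitude pupil is conserved; normalize
    # the measurement accordingly so moduli are comparable
    plane_energy = (measured ** 2).sum(axis=(1, 2))
    target = np.sqrt(n_mask / np.maximum(plane_energy, 1e-300))
    measured = measured * target[:, None, None] / np.sqrt(H * W)

    pupil = mask.astype(complex)
    prev_phase = np.zeros((H, W))
    change = np.inf
    it = 0
    for it in range(1, rcfg.iterations + 1):
        planes = pupil[None] * defocus
        fields = sfft.fftshift(
            sfft.ifft2(sfft.ifftshift(planes, axes=(1, 2)), axes=(1, 2)),
            axes=(1, 2))
        mag = np.abs(fields)
        fields = np.where(mag > 0, fields / np.maximum(mag, 1e-300), 1.0)
        fields *= measured
        specs = sfft.fftshift(
            sfft.fft2(sfft.ifftshift(fields, axes=(1, 2)), axes=(1, 2)),
            axes=(1, 2))
        est = (specs * np.conj(defocus)).mean(axis=0)
        phase = np.where(mask, np.angle(est), 0.0)
        pupil = np.where(mask, np.exp(1j * phase), 0.0)
        delta = np.abs(np.angle(np.exp(1j * (phase - prev_phase))))[mask]
        change = float(delta.mean())
        prev_phase = phase
        if change < rcfg.tolerance:
            break
    converged = change < rcfg.tolerance

    wrapped = np.ma.array(phase, mask=~mask)
    try:
        phase_u = np.ma.filled(unwrap_phase(wrapped), 0.0)
    except Exception:
        phase_u = phase

    # fit all first-15 modes, then drop piston/tip/tilt/defocus
    kx, ky = cfg.lateral_k_grids()
    kr = np.hypot(kx, ky)
    rho = np.where(mask, kr / cfg.k_cutoff, 0.0)
    theta = np.arctan2(ky, kx)
    modes15 = all_modes(4)
    design = np.stack([zernike_values(m, rho[mask], theta[mask])
                       for m in modes15], axis=1)
    coeffs, *_ = np.linalg.lstsq(design, phase_u[mask], rcond=None)
    coeffs = coeffs / (2 * np.pi)  # radians -> waves
    excluded = set(EXCLUDED_MODES)
    wf = Wavefront({m: c for m, c in zip(modes15, coeffs)
                    if tuple(m) not in excluded and c != 0.0},
                   cfg.wavelength)

    out_pupil = PupilFunction(mask.astype(float),
                              PhaseMap(phase_u, mask), cfg)
    return RetrievalResult(out_pupil, wf, converged, it, change)


def residual_rms(true: Wavefront, estimated: Wavefront) -> float:
    """Euclidean distance between coefficient vectors, in lambda RMS.

    A metric over wavefronts: symmetric, zero iff the coefficients
    agree, and obeying the triangle inequality.
    """
    keys = sorted(set(true.coefficients) | set(estimated.coefficients))
    diff = np.array([true.amplitude(k) - estimated.amplitude(k)
                     for k in keys])
    return float(np.linalg.norm(diff)) if len(diff) else 0.0
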