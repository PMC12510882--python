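"""Synthetic aberrated puncta volumes with a camera noise model.

A sample is ``J`` subdiffractive fluorescent puncta (Gaussians of FWHM
100-400 nm) placed uniformly at continuous positions inside the volume,
imaged through an aberrated light-sheet PSF, scaled so one unclipped
punctum integrates to ``N_o`` photons, and read out through an sCMOS-like
camera (quantum efficiency, Poisson shot noise, Gaussian read noise,
offset). Ground-truth wavefronts are drawn from a mixture of four
per-mode amplitude distributions (single, bimodal, power-law, Dirichlet)
so that every sensed mode contributes equally across a dataset.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import fft as sfft

from .optics import (OpticalConfig, PSFVolume, detection_psf,
                     make_light_sheet, make_pupil, overall_psf)
from .zernike import Wavefront, ZernikeIndex, eligible_modes

__all__ = [
    "PunctaField",
    "CameraModel",
    "AmplitudeSampler",
    "SampleVolume",
    "SimulationConfig",
    "TRAIN_PRESET",
    "TEST_PRESET",
    "sample_amplitudes",
    "place_puncta",
    "render_volume",
    "apply_camera",
    "simulate_sample",
    "generate_dataset",
]

PUNCTA_WIDTHS_NM = (100.0, 200.0, 300.0, 400.0)


@dataclass
class PunctaField:
    """Continuous puncta positions (nm from the volume corner) and sizes."""

    positions: np.ndarray   # (J, 3) as (z, y, x) nm
    widths: np.ndarray      # (J,) FWHM nm

    @property
    def count(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class CameraModel:
    """sCMOS-like readout: QE, Gaussian read noise (e- RMS) and offset."""

    quantum_efficiency: float = 0.82
    read_noise: float = 1.6
    offset: float = 100.0

    def __post_init__(self):
        if not 0 < self.quantum_efficiency <= 1:
            raise ValueError("quantum efficiency must be in (0, 1]")
        if self.read_noise < 0:
            raise ValueError("read noise must be >= 0")


@dataclass(frozen=True)
class AmplitudeSampler:
    """Per-mode aberration amplitude distributions.

    ``single`` puts the whole amplitude on one mode; the other families
    draw a total ``alpha_t`` uniformly on ``alpha_range`` and split it
    across modes with factors that sum to one: ``bimodal`` between two
    random modes, ``powerlaw`` with Lomax(gamma)-distributed factors
    (heavy-tailed, a few dominant modes), ``dirichlet`` with uniform
    factors (many comparable modes). ``mixed`` picks one of the four per
    draw with equal probability. All per-mode amplitudes are
    non-negative and, for the multi-mode families, sum to ``alpha_t``
    exactly.
    """

    distribution: str = "mixed"
    alpha_range: tuple = (0.0, 0.5)   # lambda RMS
    gamma: float = 0.75               # Lomax shape

    FAMILIES = ("single", "bimodal", "powerlaw", "dirichlet")


def sample_amplitudes(s: AmplitudeSampler, modes: Sequence[ZernikeIndex],
                      rng: np.random.Generator,
                      wavelength: float = 510.0) -> Wavefront:
    """Draw one ground-truth wavefront from the sampler's family."""
    modes = list(modes)
    if not modes:
        raise ValueError("mode list must not be empty")
    family = s.distribution
    if family == "mixed":
        family = s.FAMILIES[rng.integers(len(s.FAMILIES))]
    lo, hi = s.alpha_range
    alpha_t = rng.uniform(lo, hi)
    k = len(modes)
    amps = np.zeros(k)
    if family == "single":
        amps[rng.integers(k)] = alpha_t
    elif family == "bimodal":
        i, j = rng.choice(k, size=2, replace=False)
        eps = rng.uniform()
        amps[i] = eps * alpha_t
        amps[j] = (1 - eps) * alpha_t
    elif family == "powerlaw":
        x = rng.uniform(0.0, 1.0, size=k)
        eps = s.gamma / (x + 1) ** (s.gamma + 1)
        amps = eps / eps.sum() * alpha_t
    elif family == "dirichlet":
        eps = rng.uniform(0.0, 1.0, size=k)
        amps = eps / eps.sum() * alpha_t
    else:
        raise ValueError(f"unknown amplitude family {family!r}")
    return Wavefront.from_vector(amps, modes, wavelength)


def place_puncta(cfg: OpticalConfig, j_range=(1, 5),
                 rng: Optional[np.random.Generator] = None,
                 widths: Sequence[float] = PUNCTA_WIDTHS_NM) -> PunctaField:
    """Uniform puncta positions over the volume; widths i.i.d. from a set.

    Puncta may fall near the border, so their images can be clipped by
    the field of view; the captured-signal bookkeeping accounts for it.
    """
    rng = rng or np.random.default_rng()
    lo, hi = int(j_range[0]), int(j_range[1])
    if lo < 1 or hi < lo:
        raise ValueError("J range must satisfy 1 <= lo <= hi")
    j = int(rng.integers(lo, hi + 1))
    D, H, W = cfg.grid_shape
    extent = np.array([D * cfg.dz, H * cfg.dy, W * cfg.dx])
    positions = rng.uniform(0.0, 1.0, size=(j, 3)) * extent
    w = rng.choice(np.asarray(widths, float), size=j)
    return PunctaField(positions, w)


def _gaussian_1d(coords: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    return np.exp(-4 * np.log(2) * ((coords - center) / fwhm) ** 2)


def _unclipped_sum_1d(center: float, fwhm: float, pitch: float) -> float:
    # discrete sum of the sampled Gaussian over an unbounded axis
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    half = int(np.ceil(6 * sigma / pitch)) + 1
    i0 = int(np.floor(center / pitch))
    idx = np.arange(i0 - half, i0 + half + 1)
    return float(_gaussian_1d(idx * pitch, center, fwhm).sum())


def render_volume(p: PunctaField, psf: PSFVolume, n_photons,
                  cfg: Optional[OpticalConfig] = None, pad: int = 16):
    """Render puncta through a PSF; returns ``(I_photon, scale, S_V)``.

    Each punctum is evaluated analytically on the voxel grid at its
    continuous position (sub-voxel placement preserves the phase ramps
    that encode aberrations), convolved with the PSF in Fourier space on
    a grid padded by ``pad`` voxels so border energy leaves the field of
    view instead of wrapping, and scaled so an unclipped punctum
    integrates to its ``N_o``. The captured signal ``S_V`` (photons
    inside the volume) never exceeds ``J * N_o``.
    """
    cfg = cfg or psf.config
    n_photons = np.broadcast_to(np.asarray(n_photons, float), (p.count,))
    if np.any(n_photons <= 0):
        raise ValueError("integrated photons per punctum must be positive")
    D, H, W = cfg.grid_shape
    if psf.intensity.shape != (D, H, W):
        raise ValueError("PSF grid does not match the optical config")
    pitches = (cfg.dz, cfg.dy, cfg.dx)
    shape_p = (D + 2 * pad, H + 2 * pad, W + 2 * pad)

    psf_sum = psf.intensity.sum()
    buf = np.zeros(shape_p, dtype=np.float32)
    scales = np.empty(p.count)
    for j in range(p.count):
        center = p.positions[j]
        fwhm = p.widths[j]
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        gs, sls = [], []
        unclipped = 1.0
        for ax in range(3):
            pitch = pitches[ax]
            half = int(np.ceil(5 * sigma / pitch)) + 1
            c_idx = int(round(center[ax] / pitch)) + pad
            lo = max(0, c_idx - half)
            hi = min(shape_p[ax], c_idx + half + 1)
            coords = (np.arange(lo, hi) - pad) * pitch
            gs.append(_gaussian_1d(coords, center[ax], fwhm))
            sls.append(slice(lo, hi))
            unclipped *= _unclipped_sum_1d(center[ax], fwhm, pitch)
        # photon scale: N_o over the full (unclipped) integral of
        # PSF (x) Gaussian; separable discrete sums, voxel volume cancels
        scales[j] = n_photons[j] / (psf_sum * unclipped)
        buf[tuple(sls)] += (scales[j] * (gs[0][:, None, None]
                                         * gs[1][None, :, None]
                                         * gs[2][None, None, :])
                            ).astype(np.float32)

    kernel = np.zeros(shape_p, dtype=np.float32)
    kernel[:D, :H, :W] = psf.intensity.astype(np.float32)
    kernel = np.roll(kernel, shift=(-(D // 2), -(H // 2), -(W // 2)),
                     axis=(0, 1, 2))
    conv = sfft.irfftn(sfft.rfftn(buf) * sfft.rfftn(kernel), s=shape_p)
    i_photon = np.maximum(conv[pad:pad + D, pad:pad + H, pad:pad + W], 0.0)
    s_v = float(i_photon.sum())
    return i_photon, scales, s_v


def apply_camera(i_photon: np.ndarray, cam: CameraModel,
                 rng: np.random.Generator) -> np.ndarray:
    """Photon grid to camera counts: QE, shot noise, read noise, offset."""
    if np.any(i_photon < 0):
        raise ValueError("photon intensities must be non-negative")
    electrons = rng.poisson(cam.quantum_efficiency * i_photon).astype(float)
    if cam.read_noise > 0:
        electrons += rng.normal(0.0, cam.read_noise, size=i_photon.shape)
    return electrons + cam.offset


@dataclass
class SampleVolume:
    """One synthetic acquisition with its ground truth."""

    camera_counts: np.ndarray
    i_photon: np.ndarray
    ground_truth: Wavefront
    puncta: PunctaField
    photon_scale: np.ndarray
    n_photons: np.ndarray
    captured_signal: float
    seed: int


@dataclass(frozen=True)
class SimulationConfig:
    """Envelope of one dataset: optics, sheet, aberrations, puncta, SNR."""

    optics: OpticalConfig = field(default_factory=OpticalConfig)
    sheet_family: str = "gaussian"
    sheet_width: float = 1500.0
    sampler: AmplitudeSampler = field(default_factory=AmplitudeSampler)
    j_range: tuple = (1, 5)
    photon_range: tuple = (1.0, 2e5)
    photons_per_punctum: bool = False  # one shared N_o per volume by default
    camera: CameraModel = field(default_factory=CameraModel)
    max_n: int = 4
    modes: Optional[tuple] = None      # restrict sensed modes; None = all 11


TRAIN_PRESET = SimulationConfig()
TEST_PRESET = replace(TRAIN_PRESET,
                      sampler=AmplitudeSampler(alpha_range=(0.0, 1.0)),
                      j_range=(1, 150), photon_range=(1.0, 5e5))

PRESETS = {"train": TRAIN_PRESET, "test": TEST_PRESET}


def simulate_sample(config: SimulationConfig, seed: int,
                    wavefront: Optional[Wavefront] = None) -> SampleVolume:
    """Generate one fully reproducible synthetic volume."""
    rng = np.random.default_rng(seed)
    if config.modes is not None:
        modes = [ZernikeIndex(*m) for m in config.modes]
    else:
        modes = eligible_modes(config.max_n)
    if wavefront is None:
        wavefront = sample_amplitudes(config.sampler, modes, rng,
                                      config.optics.wavelength)
    sheet = make_light_sheet(config.sheet_family, config.sheet_width,
                             config.optics)
    det = detection_psf(make_pupil(config.optics, wavefront))
    psf = overall_psf(det, sheet)
    puncta = place_puncta(config.optics, config.j_range, rng)
    lo, hi = config.photon_range
    if config.photons_per_punctum:
        n_o = rng.uniform(lo, hi, size=puncta.count)
    else:
        n_o = np.full(puncta.count, rng.uniform(lo, hi))
    i_photon, scale, s_v = render_volume(puncta, psf, n_o, config.optics)
    counts = apply_camera(i_photon, config.camera, rng)
    return SampleVolume(counts, i_photon, wavefront, puncta, scale,
                        n_o, s_v, seed)


def generate_dataset(n_samples: int, out_dir, seed: int = 0,
                     config: Optional[SimulationConfig] = None,
                     preset: str = "train") -> pd.DataFrame:
    """Write ``n_samples`` volumes to a zarr store plus a TSV manifest.

    One group per sample holding the camera counts and ground truth;
    the manifest records seed, J, N_o, per-mode amplitudes, RMS and the
    captured signal. Fully reproducible from ``seed``.
    """
    import zarr

    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    config = config or PRESETS[preset]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = zarr.open_group(str(out_dir / "samples.zarr"), mode="w")
    modes = eligible_modes(config.max_n)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_samples)

    rows = []
    for i, s in enumerate(child_seeds):
        s = int(s % (2 ** 31))
        sample = simulate_sample(config, s)
        grp = root.create_group(f"sample_{i:06d}")
        arr = grp.create_array("camera_counts",
                               shape=sample.camera_counts.shape,
                               dtype="float32")
        arr[:] = sample.camera_counts.astype(np.float32)
        grp.attrs["wavefront"] = sample.ground_truth.to_json()
        grp.attrs["seed"] = s
        row = {"sample_id": f"sample_{i:06d}", "seed": s,
               "J": sample.puncta.count,
               "N_o": float(np.mean(sample.n_photons)),
               "rms_lambda": sample.ground_truth.rms(),
               "S_V": sample.captured_signal,
               "checksum": hashlib.sha256(
                   np.ascontiguousarray(
                       sample.camera_counts.astype(np.float32))
                   .tobytes()).hexdigest()[:16]}
        for idx in modes:
            row[f"amp_{idx.n}_{idx.m}"] = sample.ground_truth.amplitude(idx)
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    meta = {"n_samples": n_samples, "seed": seed, "preset": preset,
            "modes": [[i.n, i.m] for i in modes]}
    (out_dir / "metadata.json").write_text(json.dumps(meta, indent=2))
    return manifest
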