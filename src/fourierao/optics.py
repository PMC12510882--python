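"""Pupil-field construction and 3D PSF/OTF synthesis for light-sheet detection.

The detection point spread function of a subdiffractive emitter is the
squared modulus of the angular spectrum of the rear-pupil field
``E = A exp(i phi)``, propagated plane by plane along the detection axis
with ``k_z = sqrt((2 pi eta / lambda)^2 - k_x^2 - k_y^2)`` (the Ewald cap;
scalar diffraction). The overall light-sheet PSF is the detection PSF
multiplied by the axial cross-section of the swept excitation sheet.

Conventions (fixed once, used everywhere):

* volumes are indexed ``(z, y, x)``; the focal plane sits at index
  ``D // 2`` and the unaberrated PSF peaks at the center voxel;
* Fourier grids are centered (zero frequency at ``shape // 2``);
* positive horizontal coma ``Z_3^1`` displaces the PSF centroid toward
  ``+x``;
* coordinates are nm, spatial frequencies rad/nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import fft as sfft

from .zernike import Wavefront, PhaseMap, zernike_values

__all__ = [
    "OpticalConfig",
    "PupilFunction",
    "PSFVolume",
    "LightSheetProfile",
    "OTFVolume",
    "make_pupil",
    "detection_psf",
    "make_light_sheet",
    "overall_psf",
    "compute_otf",
    "ideal_psf",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical and sampling parameters of the detection path.

    Defaults describe a 1.0-NA water-immersion detection objective at
    510 nm emission imaging 64^3-voxel volumes of 125 x 125 x 200 nm^3
    (an 8 x 8 x 12.8 um^3 field of view).
    """

    na_detection: float = 1.0
    wavelength: float = 510.0       # nm
    refractive_index: float = 1.33
    voxel_pitch: tuple = (125.0, 125.0, 200.0)  # (dx, dy, dz) nm
    grid_shape: tuple = (64, 64, 64)            # (D, H, W) = (z, y, x)

    def __post_init__(self):
        if not self.na_detection < self.refractive_index:
            raise ValueError("detection NA must be below the medium index "
                             "(no evanescent collection)")
        if any(p <= 0 for p in self.voxel_pitch):
            raise ValueError("voxel pitches must be positive")

    @property
    def dx(self) -> float:
        return self.voxel_pitch[0]

    @property
    def dy(self) -> float:
        return self.voxel_pitch[1]

    @property
    def dz(self) -> float:
        return self.voxel_pitch[2]

    def lateral_k_grids(self, shape=None):
        """Centered (k_x, k_y) grids in rad/nm for the lateral plane."""
        if shape is None:
            _, H, W = self.grid_shape
        else:
            H, W = shape
        kx = 2 * np.pi * sfft.fftshift(sfft.fftfreq(W, d=self.dx))
        ky = 2 * np.pi * sfft.fftshift(sfft.fftfreq(H, d=self.dy))
        return np.meshgrid(kx, ky, indexing="xy")

    @property
    def k_cutoff(self) -> float:
        """Pupil-edge spatial frequency 2 pi NA / lambda (rad/nm)."""
        return 2 * np.pi * self.na_detection / self.wavelength


@dataclass
class PupilFunction:
    """Rear-pupil field on the centered lateral k-grid."""

    amplitude: np.ndarray       # >= 0, zero outside support
    phase: PhaseMap             # radians, defined on support
    config: OpticalConfig

    @property
    def support(self) -> np.ndarray:
        return self.phase.mask

    def field(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * np.where(self.support,
                                                     self.phase.values, 0.0))


@dataclass
class PSFVolume:
    """3D intensity grid with pitch metadata."""

    intensity: np.ndarray       # (D, H, W), >= 0
    config: OpticalConfig
    kind: str = "detection"     # detection | excitation | overall

    def normalized(self) -> np.ndarray:
        return self.intensity / self.intensity.sum()


@dataclass
class LightSheetProfile:
    """Axial excitation cross-section, peak-normalized to 1 at focus."""

    values: np.ndarray          # one weight per z-plane
    family: str
    width: float                # nm; meaning depends on family


@dataclass
class OTFVolume:
    """Centered 3D Fourier transform of a PSF with a support mask."""

    values: np.ndarray          # complex, zero frequency at shape // 2
    support: np.ndarray         # bool, where |OTF| of the ideal exceeds floor
    config: OpticalConfig


def make_pupil(cfg: OpticalConfig, w: Optional[Wavefront] = None,
               amplitude: Optional[np.ndarray] = None) -> PupilFunction:
    """Build the pupil field for a wavefront (coefficients in lambda RMS).

    The default amplitude is a uniform disk of radius NA/lambda, the
    standard surrogate when no phase-retrieved amplitude map of the real
    pupil is available; a measured 2D map can be passed instead.
    """
    kx, ky = cfg.lateral_k_grids()
    kr = np.hypot(kx, ky)
    support = kr <= cfg.k_cutoff
    if amplitude is None:
        amplitude = support.astype(float)
    else:
        amplitude = np.asarray(amplitude, dtype=float) * support

    phase = np.zeros_like(kr)
    if w is not None and w.coefficients:
        rho = np.where(support, kr / cfg.k_cutoff, 0.0)
        theta = np.arctan2(ky, kx)
        waves = np.zeros_like(kr)
        for idx, a in w.coefficients.items():
            if a != 0.0:
                waves += a * zernike_values(idx, rho, theta)
        phase = np.where(support, 2 * np.pi * waves, 0.0)
    return PupilFunction(amplitude, PhaseMap(phase, support), cfg)


def _kz_map(cfg: OpticalConfig) -> np.ndarray:
    kx, ky = cfg.lateral_k_grids()
    k_med = 2 * np.pi * cfg.refractive_index / cfg.wavelength
    arg = k_med ** 2 - kx ** 2 - ky ** 2
    return np.sqrt(np.maximum(arg, 0.0))


def detection_psf(p: PupilFunction, cfg: Optional[OpticalConfig] = None) -> PSFVolume:
    """Angular-spectrum propagation of the pupil field to a 3D PSF.

    Each z-plane multiplies the pupil by ``exp(i k_z z)`` and transforms
    to real space with the ``exp(+i k.x)`` kernel, so the field is
    ``E(x, y; z)`` and the intensity its squared modulus. Per-plane
    energy is conserved (the defocus factor is phase-only), so a
    phase-only aberration never changes the total PSF intensity.
    """
    cfg = cfg or p.config
    D, H, W = cfg.grid_shape
    if p.amplitude.shape != (H, W):
        raise ValueError("pupil grid does not match the optical config")
    kz = _kz_map(cfg)
    z = (np.arange(D) - D // 2) * cfg.dz
    pupil = p.field()
    # subtract the on-axis k_z so the z phase ramp is relative to focus
    kz_rel = np.where(p.support, kz - kz[H // 2, W // 2], 0.0)
    planes = pupil[None, :, :] * np.exp(1j * kz_rel[None] * z[:, None, None])
    field = sfft.fftshift(sfft.ifft2(sfft.ifftshift(planes, axes=(1, 2)),
                                     axes=(1, 2)), axes=(1, 2))
    intensity = (field.real ** 2 + field.imag ** 2)
    return PSFVolume(intensity, cfg, kind="detection")


_FAMILIES = ("gaussian", "square", "tabulated")


def make_light_sheet(family: str = "gaussian", width: float = 1500.0,
                     cfg: Optional[OpticalConfig] = None,
                     table: Optional[tuple] = None) -> LightSheetProfile:
    """Axial excitation profile sampled on the volume's z planes.

    * ``gaussian``: ``width`` is the FWHM (nm) of the sheet cross-section;
    * ``square``: uniform inside ``|z| <= width / 2``, zero outside;
    * ``tabulated``: linear interpolation of a measured ``(z_nm, value)``
      table (e.g., a lattice sheet cross-section).

    The default 1.5-um-FWHM Gaussian stands in for the swept square
    lattice used in practice; any measured profile can be supplied.
    """
    cfg = cfg or OpticalConfig()
    if width <= 0:
        raise ValueError("light-sheet width must be positive")
    D = cfg.grid_shape[0]
    z = (np.arange(D) - D // 2) * cfg.dz
    if family == "gaussian":
        vals = np.exp(-4 * np.log(2) * (z / width) ** 2)
    elif family == "square":
        vals = (np.abs(z) <= width / 2).astype(float)
    elif family == "tabulated":
        if table is None:
            raise ValueError("tabulated family requires a (z, value) table")
        zt, vt = np.asarray(table[0], float), np.asarray(table[1], float)
        vals = np.interp(z, zt, vt, left=0.0, right=0.0)
    else:
        raise ValueError(f"unknown light-sheet family {family!r}; "
                         f"choose from {_FAMILIES}")
    peak = vals.max()
    if peak <= 0:
        raise ValueError("light-sheet profile has no positive peak in range")
    return LightSheetProfile(vals / peak, family, width)


def overall_psf(det: PSFVolume, sheet: LightSheetProfile) -> PSFVolume:
    """Product of the excitation profile and the detection PSF along z."""
    if sheet.values.shape[0] != det.intensity.shape[0]:
        raise ValueError("light-sheet profile and PSF z-grids do not match")
    out = det.intensity * sheet.values[:, None, None]
    return PSFVolume(out, det.config, kind="overall")


def compute_otf(psf: PSFVolume, floor: float = 1e-3) -> OTFVolume:
    """Centered 3D Fourier transform with an amplitude support mask.

    The mask keeps frequencies where ``|OTF| > floor * max|OTF|`` of the
    transformed PSF; pass the ideal PSF to obtain the ideal support used
    for embedding and Wiener masking.
    """
    values = sfft.fftshift(sfft.fftn(sfft.ifftshift(psf.intensity)))
    mag = np.abs(values)
    support = mag > floor * mag.max()
    return OTFVolume(values, support, psf.config)


def ideal_psf(cfg: Optional[OpticalConfig] = None,
              sheet: Optional[LightSheetProfile] = None) -> PSFVolume:
    """Aberration-free PSF; overall if a light-sheet profile is given."""
    cfg = cfg or OpticalConfig()
    det = detection_psf(make_pupil(cfg))
    if sheet is None:
        return det
    return overall_psf(det, sheet)
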