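"""Tile-based spatially varying OTF-masked Wiener deconvolution.

A large volume rarely shares one aberration: the field of view is cut
into tiles approximating isoplanatic patches, each tile is deconvolved
with its own predicted (or ideal) PSF, and the tile cores are stitched
back together. The Wiener filter is restricted to the ideal OTF support
(OMW), which suppresses the out-of-band high-frequency artifacts that
unmasked inverse filtering amplifies. Tiles are extended by an apron of
half the PSF width on each face before deconvolution; the aprons are
discarded before stitching, so cores concatenate losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Union

import numpy as np
from scipy import fft as sfft

from .optics import (LightSheetProfile, OpticalConfig, PSFVolume,
                     detection_psf, make_pupil)
from .zernike import Wavefront

__all__ = ["TileGrid", "WienerConfig", "plan_tiles", "omw_deconvolve",
           "stitch", "spatially_varying_pipeline"]


@dataclass(frozen=True)
class WienerConfig:
    """OMW deconvolution parameters.

    ``beta`` is the noise-to-signal regularizer as a fraction of the
    peak ``|OTF|^2``; ``support_floor`` defines the ideal-OTF mask
    outside which the filter is zeroed.
    """

    beta: float = 1e-2
    support_floor: float = 1e-3

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass
class TileGrid:
    """Bookkeeping of a tiling: disjoint cores plus overlap aprons."""

    volume_shape: tuple
    tile_shape: tuple            # core size per axis
    overlap: tuple               # apron per face per axis
    origins: list                # core origin (z, y, x) per tile

    @property
    def n_tiles(self) -> int:
        return len(self.origins)

    def core_slices(self, i: int):
        o = self.origins[i]
        return tuple(slice(o[a], min(o[a] + self.tile_shape[a],
                                     self.volume_shape[a]))
                     for a in range(3))

    def extended_slices(self, i: int):
        """Core plus apron, clipped to the volume (padding handled later)."""
        o = self.origins[i]
        return tuple(slice(max(0, o[a] - self.overlap[a]),
                           min(self.volume_shape[a],
                               o[a] + self.tile_shape[a] + self.overlap[a]))
                     for a in range(3))


def plan_tiles(volume_shape, tile_shape, overlap=32) -> TileGrid:
    """Ceiling-division tiling of a volume into overlapping tiles.

    ``overlap`` (scalar or per-axis) is the apron added on each face,
    conventionally half the PSF width. Cores are disjoint and cover the
    volume exactly; edge cores may be smaller.
    """
    volume_shape = tuple(int(s) for s in volume_shape)
    tile_shape = tuple(int(t) for t in np.broadcast_to(tile_shape, (3,)))
    overlap = tuple(int(o) for o in np.broadcast_to(overlap, (3,)))
    for a in range(3):
        if tile_shape[a] < 1 or tile_shape[a] > volume_shape[a]:
            raise ValueError("tile size must be within the volume per axis")
        if overlap[a] < 0 or overlap[a] >= tile_shape[a] + overlap[a] + 1:
            raise ValueError("overlap must be non-negative")
        if overlap[a] >= tile_shape[a] + overlap[a]:
            raise ValueError("overlap must be smaller than the padded tile")
    counts = [int(np.ceil(volume_shape[a] / tile_shape[a])) for a in range(3)]
    origins = [(iz * tile_shape[0], iy * tile_shape[1], ix * tile_shape[2])
               for iz in range(counts[0])
               for iy in range(counts[1])
               for ix in range(counts[2])]
    return TileGrid(volume_shape, tile_shape, overlap, origins)


def _otf_for(psf: np.ndarray, shape) -> np.ndarray:
    """OTF of a center-peaked PSF, resampled to ``shape`` (unshifted)."""
    out = np.zeros(shape)
    src = [min(s, t) for s, t in zip(psf.shape, shape)]
    psl = tuple(slice((s - c) // 2, (s - c) // 2 + c)
                for s, c in zip(psf.shape, src))
    osl = tuple(slice((t - c) // 2, (t - c) // 2 + c)
                for t, c in zip(shape, src))
    out[osl] = psf[psl]
    total = out.sum()
    if total <= 0:
        raise ValueError("PSF has no intensity")
    out /= total
    return sfft.fftn(sfft.ifftshift(out))


def omw_deconvolve(tile: np.ndarray, psf: Union[PSFVolume, np.ndarray],
                   cfg: Optional[WienerConfig] = None,
                   ideal_psf: Optional[Union[PSFVolume, np.ndarray]] = None
                   ) -> np.ndarray:
    """Wiener-deconvolve one tile inside the ideal OTF support.

    The filter is ``conj(OTF) / (|OTF|^2 + beta |OTF|^2_max)``, zeroed
    where the ideal OTF amplitude falls below the support floor. With no
    explicit ideal PSF the support is taken from the supplied PSF.
    """
    cfg = cfg or WienerConfig()
    psf_arr = psf.intensity if isinstance(psf, PSFVolume) else np.asarray(psf)
    if not np.any(psf_arr):
        raise ValueError("all-zero PSF")
    tile = np.asarray(tile, dtype=float)
    otf = _otf_for(psf_arr, tile.shape)
    if ideal_psf is None:
        ideal_otf = otf
    else:
        ideal_arr = (ideal_psf.intensity if isinstance(ideal_psf, PSFVolume)
                     else np.asarray(ideal_psf))
        ideal_otf = _otf_for(ideal_arr, tile.shape)
    mag_ideal = np.abs(ideal_otf)
    support = mag_ideal > cfg.support_floor * mag_ideal.max()
    mag2 = otf.real * otf.real + otf.imag * otf.imag
    filt = np.where(support,
                    np.conj(otf) / (mag2 + cfg.beta * mag2.max()), 0.0)
    return sfft.ifftn(sfft.fftn(tile) * filt).real


def stitch(tiles: Sequence[np.ndarray], grid: TileGrid) -> np.ndarray:
    """Concatenate deconvolved tile cores into the output volume.

    Tiles arrive with their aprons still attached (as produced by the
    pipeline); each core is cut out and placed — no blending, so the
    assembly is lossless by construction.
    """
    if len(tiles) != grid.n_tiles:
        raise ValueError(f"expected {grid.n_tiles} tiles, got {len(tiles)}")
    out = np.zeros(grid.volume_shape)
    filled = np.zeros(grid.volume_shape, dtype=bool)
    for i, tile in enumerate(tiles):
        core = grid.core_slices(i)
        ext = grid.extended_slices(i)
        local = tuple(slice(c.start - e.start, c.stop - e.start)
                      for c, e in zip(core, ext))
        out[core] = tile[local]
        filled[core] = True
    if not filled.all():
        raise ValueError("incomplete assembly: uncovered voxels remain")
    return out


def _tile_psf(wavefront: Optional[Wavefront], shape,
              optics: OpticalConfig,
              sheet: Optional[LightSheetProfile] = None) -> PSFVolume:
    from dataclasses import replace
    cfg = replace(optics, grid_shape=tuple(shape))
    det = detection_psf(make_pupil(cfg, wavefront))
    if sheet is not None:
        prof = np.interp(
            (np.arange(shape[0]) - shape[0] // 2) * cfg.dz,
            (np.arange(len(sheet.values)) - len(sheet.values) // 2)
            * optics.dz,
            sheet.values, left=0.0, right=0.0)
        peak = prof.max()
        det = PSFVolume(det.intensity * (prof / (peak or 1.0))[:, None, None],
                        cfg, kind="overall")
    return det


def spatially_varying_pipeline(volume: np.ndarray,
                               tile_wavefronts: Dict[int, Optional[Wavefront]],
                               optics: Optional[OpticalConfig] = None,
                               wiener: Optional[WienerConfig] = None,
                               tile_shape=(64, 64, 64), overlap=32,
                               sheet: Optional[LightSheetProfile] = None
                               ) -> np.ndarray:
    """Deconvolve a volume with per-tile PSFs and stitch the cores.

    ``tile_wavefronts`` maps tile index to its wavefront; a missing or
    ``None`` entry means the tile had insufficient signal for inference
    and falls back to the ideal PSF. Tile aprons beyond the volume edge
    are filled by reflection.
    """
    optics = optics or OpticalConfig()
    wiener = wiener or WienerConfig()
    volume = np.asarray(volume, dtype=float)
    grid = plan_tiles(volume.shape, tile_shape, overlap)
    pad = [(o, o) for o in grid.overlap]
    padded = np.pad(volume, pad, mode="reflect")

    psf_cache: dict = {}
    out = np.zeros(grid.volume_shape)
    for i in range(grid.n_tiles):
        core = grid.core_slices(i)
        # extended tile in padded coordinates: full aprons on every face
        psl = tuple(slice(core[a].start,
                          core[a].stop + 2 * grid.overlap[a])
                    for a in range(3))
        tile = padded[psl]
        wf = tile_wavefronts.get(i)
        if wf is not None and not wf.coefficients:
            wf = None
        key = (tuple(sorted((tuple(k), v) for k, v in
                            (wf.coefficients.items() if wf else ()))),
               tile.shape)
        if key not in psf_cache:
            psf_cache[key] = _tile_psf(wf, tile.shape, optics, sheet)
        ideal_key = ((), tile.shape)
        if ideal_key not in psf_cache:
            psf_cache[ideal_key] = _tile_psf(None, tile.shape, optics, sheet)
        dec = omw_deconvolve(tile, psf_cache[key], wiener,
                             ideal_psf=psf_cache[ideal_key])
        local = tuple(slice(grid.overlap[a],
                            grid.overlap[a] + (core[a].stop - core[a].start))
                      for a in range(3))
        out[core] = dec[local]
    return out
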