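"""Six-plane Fourier embedding of a puncta volume.

The embedding compresses a 3D volume into six 2D planes near the
``k_z = 0`` principal plane of its Fourier transform: three amplitude
planes (the ratio of the volume's FFT amplitude to that of the ideal
PSF, isolating aberration-induced attenuation from the instrument
envelope) and three unwrapped-phase planes of the interference-free
transfer pattern ``tau``. Because an aberration affects every punctum
in an isoplanatic region identically, the embedding pools signal across
puncta: dim puncta add to the same frequency-domain fingerprint while
their mutual interference fringes are removed by dividing the spectrum
by that of the detected puncta cores.

A parity note that shapes what the phase planes can contain: for an
aberration of even pupil parity (astigmatism, spherical), the axially
projected image is inversion-symmetric, so the principal plane of the
3D transform is real and its phase carries only 0/pi contrast-inversion
patches; smooth phase signatures of even modes appear in the off-
principal planes, while odd modes (coma, trefoil) imprint directly on
the principal plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import fft as sfft
from scipy import ndimage
from scipy.signal.windows import tukey
from skimage.feature import peak_local_max
from skimage.restoration import unwrap_phase

from .optics import OpticalConfig, PSFVolume, ideal_psf as make_ideal_psf
from .zernike import Wavefront, ZernikeIndex, eligible_modes, zernike_values

__all__ = [
    "PreprocessConfig",
    "EmbeddingConfig",
    "FourierEmbedding",
    "InterferenceMask",
    "NoSignalError",
    "preprocess",
    "amplitude_embedding",
    "remove_interference",
    "phase_embedding",
    "build_embedding",
    "fit_plane_wavefront",
    "embedding_support",
    "IdealReference",
]


class NoSignalError(RuntimeError):
    """No punctum peak above threshold was found in the volume."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Filters applied before embedding.

    ``highpass_sigma`` (voxels) sets the Gaussian background-estimation
    scale that is subtracted; the low-pass cutoff sits at the detection
    NA limit of the optical transfer function with a Gaussian rolloff of
    ``lowpass_sigma`` k-space voxels; a lateral Tukey window (cosine
    fraction ``tukey_alpha``) suppresses FFT edge artifacts. No axial
    window is applied: the embedding lives near ``k_z = 0`` where axial
    windowing would cost aberration information.
    """

    highpass_sigma: float = 8.0
    lowpass_sigma: float = 3.0
    tukey_alpha: float = 0.5
    percentile_lo: float = 1.0
    percentile_hi: float = 99.99

    def __post_init__(self):
        if not 0 <= self.tukey_alpha <= 1:
            raise ValueError("Tukey cosine fraction must be in [0, 1]")


@dataclass(frozen=True)
class EmbeddingConfig:
    """Parameters of the embedding itself.

    Amplitude ratios are evaluated where the ideal FFT amplitude exceeds
    ``amplitude_floor`` of its maximum (the ratio is undefined outside
    the ideal support) and are normalized by their zero-frequency value
    so that pooling over many puncta keeps a common scale; a lateral
    normalized-convolution smoothing of ``alpha_smooth_sigma`` pixels
    damps the residual speckle that many randomly placed puncta imprint
    on a single plane. Phase is evaluated on the tighter
    ``phase_floor`` support where the transfer-pattern division is well
    conditioned; beyond it the windowed spectrum undershoots zero and
    the phase degenerates to 0/pi noise. Peak detection retains
    ``mask_halfwidth``-voxel tapered cores around detected puncta; the
    cores must stay well below the PSF extent or the division would
    cancel the aberration signature it is meant to expose.
    """

    d: int = 64
    amplitude_floor: float = 1e-3
    phase_floor: float = 0.08
    alpha_smooth_sigma: float = 1.5
    alpha_max: float = 5.0          # ratios beyond this are rim noise
    phase_detrend: bool = True      # remove per-plane tip/tilt ramps
    phase_clip: float = 2 * np.pi
    min_peak_distance: int = 3
    peak_threshold_rel: float = 0.1
    ncc_kernel_size: int = 16
    ncc_min_score: float = 0.3
    mask_halfwidth: int = 3
    mask_polarity: str = "retain"   # retain cores | remove cores


@dataclass
class FourierEmbedding:
    """The 6-plane model input: (alpha1..3, phi1..3), each d x d."""

    planes: np.ndarray              # (6, d, d) float32
    support: np.ndarray             # (d, d) bool, principal amplitude support
    phase_support: np.ndarray       # (d, d) bool, principal phase support
    quality_ok: bool = True         # False if phase unwrapping was degraded

    @property
    def d(self) -> int:
        return self.planes.shape[-1]


@dataclass
class InterferenceMask:
    """Intermediates of the fringe-removal step."""

    mask: np.ndarray                # tapered weights retaining puncta cores
    masked_volume: np.ndarray       # S = V * M
    tau: np.ndarray                 # interference-free transfer pattern
    reconstructed: np.ndarray       # V' = inverse FFT of tau
    peaks: np.ndarray               # (n, 3) detected peak voxels


_FILTER_CACHE: dict = {}


def _bandpass_filter(cfg: OpticalConfig, shape,
                     pcfg: PreprocessConfig) -> np.ndarray:
    """Combined high-pass x low-pass filter on the unshifted k-grid.

    The Gaussian background subtraction is applied spectrally as
    ``1 - exp(-2 (pi f sigma)^2)`` (identical to subtracting a circular
    Gaussian blur, which keeps the pipeline equivariant to circular
    shifts); the low-pass is a soft mask at the NA-limited OTF extents
    (2 NA / lambda lateral, eta (1 - cos theta) axial) with a Gaussian
    rolloff in k-space voxels.
    """
    key = (shape, cfg.voxel_pitch, cfg.na_detection, cfg.wavelength,
           cfg.refractive_index, pcfg.highpass_sigma, pcfg.lowpass_sigma)
    if key in _FILTER_CACHE:
        return _FILTER_CACHE[key]
    D, H, W = shape
    fz = sfft.fftfreq(D)[:, None, None]   # cycles per voxel
    fy = sfft.fftfreq(H)[None, :, None]
    fx = sfft.fftfreq(W)[None, None, :]
    s = pcfg.highpass_sigma
    highpass = 1.0 - np.exp(-2 * (np.pi * s) ** 2 * (fz * fz + fy * fy
                                                     + fx * fx))

    kx = 2 * np.pi * fx / cfg.dx
    ky = 2 * np.pi * fy / cfg.dy
    kz = 2 * np.pi * fz / cfg.dz
    k_lat = 2 * cfg.k_cutoff
    k_med = 2 * np.pi * cfg.refractive_index / cfg.wavelength
    cos_t = np.sqrt(1 - (cfg.na_detection / cfg.refractive_index) ** 2)
    k_ax = k_med * (1 - cos_t)
    r = np.sqrt((kz / k_ax) ** 2 + (ky / k_lat) ** 2 + (kx / k_lat) ** 2)
    hard = (r <= 1.0).astype(float)
    if pcfg.lowpass_sigma > 0:
        hard = sfft.fftshift(ndimage.gaussian_filter(
            sfft.ifftshift(hard), pcfg.lowpass_sigma))
    filt = (highpass * hard).astype(np.float32)
    _FILTER_CACHE[key] = filt
    return filt


def preprocess(volume: np.ndarray, cfg: Optional[OpticalConfig] = None,
               pcfg: Optional[PreprocessConfig] = None) -> np.ndarray:
    """Normalize, background-subtract, band-limit and window a volume."""
    cfg = cfg or OpticalConfig()
    pcfg = pcfg or PreprocessConfig()
    v = np.asarray(volume, dtype=np.float64)
    if v.ndim != 3:
        raise ValueError("expected a 3D volume")
    if min(v.shape) < 8:
        raise ValueError("volume too small for windowed preprocessing")
    if not np.all(np.isfinite(v)):
        raise ValueError("volume contains non-finite values")

    # normalization in double precision so a globally rescaled volume
    # maps to the bit-identical single-precision array
    lo, hi = np.percentile(v, [pcfg.percentile_lo, pcfg.percentile_hi])
    if hi > lo:
        v = np.clip((v - lo) / (hi - lo), 0.0, 1.0)
    else:
        v = v - lo
    v = v.astype(np.float32)

    filt = _bandpass_filter(cfg, v.shape, pcfg)
    v = sfft.ifftn(sfft.fftn(v) * filt).real

    if pcfg.tukey_alpha > 0:
        wy = tukey(v.shape[1], pcfg.tukey_alpha).astype(np.float32)
        wx = tukey(v.shape[2], pcfg.tukey_alpha).astype(np.float32)
        v = v * wy[None, :, None] * wx[None, None, :]
    return v.astype(np.float32)


def _centered_fft(v: np.ndarray) -> np.ndarray:
    return sfft.fftshift(sfft.fftn(sfft.ifftshift(v)))


def embedding_support(v_ideal: np.ndarray, floor: float = 1e-3) -> np.ndarray:
    """Ideal-OTF support: where the ideal FFT amplitude exceeds a floor."""
    mag = np.abs(_centered_fft(v_ideal))
    return mag > floor * mag.max()


def _center_crop(plane: np.ndarray, d: int) -> np.ndarray:
    H, W = plane.shape
    if (H, W) == (d, d):
        return plane
    if d > min(H, W):
        raise ValueError("embedding size exceeds the volume's lateral size")
    y0, x0 = (H - d) // 2, (W - d) // 2
    return plane[y0:y0 + d, x0:x0 + d]


def _combine_planes(slab: np.ndarray, d: int) -> np.ndarray:
    """Principal plane and two 5-plane means from a 10-plane +k_z slab."""
    p1 = slab[0]
    p2 = slab[0:5].mean(axis=0)
    p3 = slab[5:10].mean(axis=0)
    return np.stack([_center_crop(p, d) for p in (p1, p2, p3)])


def _kz_slab(volume3d: np.ndarray) -> np.ndarray:
    """The ten planes from the principal plane toward +k_z."""
    z0 = volume3d.shape[0] // 2
    return volume3d[z0:z0 + 10]


def amplitude_embedding(v: np.ndarray, v_ideal: np.ndarray, d: int = 64,
                        support: Optional[np.ndarray] = None,
                        floor: float = 1e-3,
                        smooth_sigma: float = 1.5,
                        alpha_max: float = 5.0) -> np.ndarray:
    """Amplitude-ratio planes ``|F(V)| / |F(V_ideal)|`` on the support.

    The ratio is normalized by its zero-frequency value (so it reads as
    attenuation relative to the captured signal, independent of puncta
    count and brightness), laterally smoothed by normalized convolution
    inside the support, and capped at ``alpha_max``: near the support
    rim the ideal amplitude approaches its floor and the ratio of two
    small numbers can spike without carrying aberration information.
    """
    if v.shape != v_ideal.shape:
        raise ValueError("volume and ideal-PSF grids do not match")
    if support is None:
        support = embedding_support(v_ideal, floor)
    num = _kz_slab(np.abs(_centered_fft(v)))
    den = _kz_slab(np.abs(_centered_fft(v_ideal)))
    sup = _kz_slab(support)
    alpha = np.zeros_like(num)
    np.divide(num, den, out=alpha, where=sup & (den > 0))
    dc = alpha[0, alpha.shape[1] // 2, alpha.shape[2] // 2]
    if dc > 0:
        alpha = alpha / dc
    if smooth_sigma > 0:
        sm = ndimage.gaussian_filter(alpha * sup,
                                     (0, smooth_sigma, smooth_sigma))
        wt = ndimage.gaussian_filter(sup.astype(float),
                                     (0, smooth_sigma, smooth_sigma))
        alpha = np.where(sup, sm / np.maximum(wt, 1e-12), 0.0)
    if alpha_max is not None:
        alpha = np.minimum(alpha, alpha_max)
    return _combine_planes(alpha, d)


def _normalized_cross_correlation(v: np.ndarray,
                                  kernel: np.ndarray) -> np.ndarray:
    """Zero-mean NCC of a volume against a template, same-shape output."""
    kz = kernel - kernel.mean()
    norm = np.sqrt((kz ** 2).sum())
    shape = [sfft.next_fast_len(n + k - 1)
             for n, k in zip(v.shape, kernel.shape)]
    corr = sfft.irfftn(sfft.rfftn(v, shape)
                       * sfft.rfftn(kz[::-1, ::-1, ::-1], shape), shape)
    off = [(k - 1) // 2 for k in kernel.shape]
    corr = corr[tuple(slice(o, o + n) for o, n in zip(off, v.shape))]
    n = np.prod(kernel.shape)
    ls = ndimage.uniform_filter(v, kernel.shape, mode="constant") * n
    lss = ndimage.uniform_filter(v * v, kernel.shape, mode="constant") * n
    var = np.maximum(lss - ls * ls / n, 0.0)
    den = norm * np.sqrt(var)
    out = np.zeros_like(corr)
    np.divide(corr, den, out=out,
              where=den > 1e-9 * den.max() if den.max() > 0 else None)
    return out


def _tapered_boxes(shape, peaks, half: int) -> np.ndarray:
    n = 2 * half + 1
    w1 = tukey(n, 0.5)
    box = w1[:, None, None] * w1[None, :, None] * w1[None, None, :]
    m = np.zeros(shape)
    for pk in peaks:
        sl, bl = [], []
        for c, s in zip(pk, shape):
            a, b = c - half, c + half + 1
            sl.append(slice(max(0, a), min(s, b)))
            bl.append(slice(max(0, -a), n - max(0, b - s)))
        m[tuple(sl)] = np.maximum(m[tuple(sl)], box[tuple(bl)])
    return m


def remove_interference(v: np.ndarray,
                        support: Optional[np.ndarray] = None,
                        ecfg: Optional[EmbeddingConfig] = None,
                        reconstruct: bool = True) -> InterferenceMask:
    """Divide out the puncta positions to isolate the transfer pattern.

    Candidate peaks come from local maxima of the preprocessed volume
    and are confirmed by normalized cross-correlation against a kernel
    cropped around the brightest punctum. Small tapered cores around the
    confirmed peaks are retained (the rest of the volume is masked off)
    to form ``S``; the Wiener-regularized ratio ``tau = F(V) / F(S)``
    then cancels the per-punctum position phase ramps and relative
    brightnesses common to both spectra — including their interference
    nulls — while the aberration signature, which lives outside the
    retained cores, survives in ``tau``.
    """
    ecfg = ecfg or EmbeddingConfig()
    peaks0 = peak_local_max(v, min_distance=ecfg.min_peak_distance,
                            threshold_rel=ecfg.peak_threshold_rel)
    if len(peaks0) == 0:
        raise NoSignalError("no punctum peak above threshold")
    brightest = peaks0[np.argmax(v[tuple(peaks0.T)])]
    if len(peaks0) == 1:
        peaks = peaks0  # nothing to confirm against the template
    else:
        half_k = ecfg.ncc_kernel_size // 2
        ksl = tuple(slice(max(0, c - half_k), min(n, c + half_k))
                    for c, n in zip(brightest, v.shape))
        ncc = _normalized_cross_correlation(v, v[ksl])
        confirmed = [pk for pk in peaks0
                     if ncc[tuple(pk)] >= ecfg.ncc_min_score]
        peaks = np.array(confirmed) if confirmed else brightest[None, :]

    weights = _tapered_boxes(v.shape, peaks, ecfg.mask_halfwidth)
    if ecfg.mask_polarity == "remove":
        weights = 1.0 - weights
    elif ecfg.mask_polarity != "retain":
        raise ValueError("mask_polarity must be 'retain' or 'remove'")
    s_vol = v * weights

    fv = _centered_fft(v)
    fs = _centered_fft(s_vol)
    mag2 = fs.real * fs.real + fs.imag * fs.imag
    delta = 1e-6 * mag2.max()
    tau = fv * np.conj(fs) / (mag2 + delta)
    if support is not None:
        tau = np.where(support, tau, 0.0)
    if reconstruct:
        recon = sfft.fftshift(sfft.ifftn(sfft.ifftshift(tau))).real
    else:
        recon = None
    return InterferenceMask(weights, s_vol, tau, recon, peaks)


def phase_embedding(tau: np.ndarray, support: np.ndarray, d: int = 64,
                    detrend: bool = True, clip: float = 2 * np.pi):
    """Per-plane 2D unwrapped phase of ``tau``, combined like amplitudes.

    Each plane is unwrapped on its support, its mean (piston) removed
    and — with ``detrend`` — its best-fit linear ramp subtracted: a
    ramp encodes only residual punctum position offsets (tip/tilt),
    which are excluded from sensing, and uncancelled ramps otherwise
    dominate the plane's dynamic range. Values are finally clipped to
    ``+-clip``. Returns ``(planes, quality_ok)``; a failed unwrap on a
    disconnected support yields the wrapped phase and
    ``quality_ok = False`` rather than an exception. Planes with (near)
    empty support — beyond the axial band limit of the sheet-confined
    OTF — contribute zero.
    """
    tau_slab = _kz_slab(tau)
    sup_slab = _kz_slab(support)
    stack = np.zeros(tau_slab.shape)
    ok = True
    for i in range(tau_slab.shape[0]):
        sup = sup_slab[i]
        if sup.sum() < 20:
            continue
        wrapped = np.ma.array(np.angle(tau_slab[i]), mask=~sup)
        try:
            unwrapped = unwrap_phase(wrapped)
        except Exception:
            unwrapped = wrapped
            ok = False
        vals = np.ma.filled(unwrapped, 0.0)
        ys, xs = np.nonzero(sup)
        if detrend:
            design = np.stack([np.ones_like(ys, dtype=float),
                               ys - ys.mean(), xs - xs.mean()], axis=1)
            coef, *_ = np.linalg.lstsq(design, vals[sup], rcond=None)
            fitted = np.zeros_like(vals)
            fitted[ys, xs] = design @ coef
            vals = vals - fitted
        else:
            vals = vals - vals[sup].mean()  # piston is uninformative
        if clip is not None:
            vals = np.clip(vals, -clip, clip)
        stack[i] = np.where(sup, vals, 0.0)
    return _combine_planes(stack, d), ok


@dataclass
class IdealReference:
    """Preprocessed ideal PSF and its supports, reusable across volumes."""

    v_ideal: np.ndarray
    support: np.ndarray         # amplitude-floor 3D support
    phase_support: np.ndarray   # tighter phase-floor 3D support

    @classmethod
    def build(cls, cfg: Optional[OpticalConfig] = None,
              pcfg: Optional[PreprocessConfig] = None,
              ecfg: Optional[EmbeddingConfig] = None,
              ideal: Optional[PSFVolume] = None) -> "IdealReference":
        cfg = cfg or OpticalConfig()
        ecfg = ecfg or EmbeddingConfig()
        if ideal is None:
            ideal = make_ideal_psf(cfg)
        v_ideal = preprocess(ideal.intensity, cfg, pcfg)
        return cls(v_ideal,
                   embedding_support(v_ideal, ecfg.amplitude_floor),
                   embedding_support(v_ideal, ecfg.phase_floor))


def build_embedding(volume: np.ndarray,
                    ideal: Optional[PSFVolume] = None,
                    cfg: Optional[OpticalConfig] = None,
                    pcfg: Optional[PreprocessConfig] = None,
                    ecfg: Optional[EmbeddingConfig] = None,
                    reference: Optional[IdealReference] = None) -> FourierEmbedding:
    """Full pipeline from a raw volume to the 6-plane embedding.

    Pass a prebuilt :class:`IdealReference` to amortize the ideal-PSF
    preprocessing across many volumes.
    """
    cfg = cfg or OpticalConfig()
    pcfg = pcfg or PreprocessConfig()
    ecfg = ecfg or EmbeddingConfig()
    if reference is None:
        reference = IdealReference.build(cfg, pcfg, ecfg, ideal)

    v = preprocess(volume, cfg, pcfg)
    alphas = amplitude_embedding(v, reference.v_ideal, ecfg.d,
                                 reference.support,
                                 smooth_sigma=ecfg.alpha_smooth_sigma,
                                 alpha_max=ecfg.alpha_max)
    try:
        interference = remove_interference(v, reference.phase_support, ecfg,
                                           reconstruct=False)
        tau = interference.tau
    except NoSignalError:
        tau = np.where(reference.phase_support, _centered_fft(v), 0.0)
    phis, ok = phase_embedding(tau, reference.phase_support, ecfg.d,
                               detrend=ecfg.phase_detrend,
                               clip=ecfg.phase_clip)
    planes = np.concatenate([alphas, phis]).astype(np.float32)
    z0 = reference.support.shape[0] // 2
    return FourierEmbedding(planes,
                            _center_crop(reference.support[z0], ecfg.d),
                            _center_crop(reference.phase_support[z0], ecfg.d),
                            ok)


def fit_plane_wavefront(plane: np.ndarray, support2d: np.ndarray,
                        modes: Optional[Sequence[ZernikeIndex]] = None,
                        wavelength: float = 510.0) -> Wavefront:
    """Project a phase plane (radians) onto Zernike modes over its support.

    The support disk is scaled to the unit pupil; coefficients are
    returned in waves. Used to quantify residual fringes and to compare
    phase patterns between pipelines.
    """
    modes = list(modes) if modes is not None else eligible_modes(4)
    H, W = plane.shape
    ys, xs = np.nonzero(support2d)
    if len(ys) < len(modes):
        raise ValueError("support too small to fit the requested modes")
    r = np.hypot(ys - H // 2, xs - W // 2)
    rmax = r.max() or 1.0
    rho = r / rmax
    theta = np.arctan2(ys - H // 2, xs - W // 2)
    design = np.stack([zernike_values(m, rho, theta) for m in modes], axis=1)
    coeffs, *_ = np.linalg.lstsq(design, plane[ys, xs], rcond=None)
    return Wavefront.from_vector(coeffs / (2 * np.pi), modes, wavelength)
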