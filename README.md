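# fourierao

Fourier-domain aberration sensing and spatially varying deconvolution
for puncta-labeled light-sheet volumes.

## The problem

Imaging deep inside multicellular specimens (zebrafish embryos,
cultured cells) distorts the detection wavefront: refractive-index
heterogeneity imprints a pupil phase error that destroys resolution and
contrast. Hardware adaptive optics measures this error with wavefront
sensors and guide stars; this package instead infers it directly from a
3D image of subdiffractive fluorescent puncta (e.g., AP2-labeled
clathrin-coated pits) and corrects it either prospectively (the
predicted wavefront is what a deformable mirror would be told to undo)
or retrospectively by tile-based deconvolution.

The wavefront is expanded in RMS-normalized Zernike modes
`phi(k) = sum_nm a_nm Z_n^m(k)` over the 11 sensed modes with radial
order `n <= 4` (piston, tip, tilt and defocus are excluded: they shift
or offset the image without degrading it). Coefficients are in units of
the emission wavelength (lambda RMS), so the coefficient-vector norm is
the wavefront RMS and `Strehl ≈ exp(-(2 pi sigma)^2)`; distortion below
0.075 lambda RMS (Strehl 0.8) counts as diffraction-limited.

The pipeline:

1. **simulator** — renders aberrated camera volumes of 1–150 Gaussian
   puncta (FWHM 100–400 nm) through a scalar angular-spectrum PSF model
   of a 1.0-NA detection objective with a swept light-sheet excitation
   profile, Poisson shot noise and sCMOS read noise. This generator is
   the sole source of training and test data.
2. **embedding** — compresses a volume into six 2D Fourier planes near
   `k_z = 0`: three amplitude-ratio planes `|F(V)|/|F(V_ideal)|` (the
   aberration's attenuation fingerprint, instrument envelope divided
   out) and three unwrapped-phase planes of the interference-free
   transfer pattern `tau = F(V)/F(S)`, where `S` retains only the
   detected puncta cores so the division cancels the position phase
   ramps and their interference fringes.
3. **model** — a multistage 3D vision transformer over those planes
   (patch sizes 32 then 16, embedding width tied to the patch pixel
   count, radial positional encoding) regresses the 15 Zernike
   coefficients; exposed as a scikit-learn estimator
   (`WavefrontTransformer`), trained here at desk scale on the
   package's own simulations.
4. **phase_retrieval** — a Gerchberg–Saxton oracle that recovers the
   pupil phase of an isolated bead independently of the model; the
   repository's ground-truth instrument.
5. **deconv** — OTF-masked Wiener deconvolution applied per isoplanatic
   tile with the tile's predicted PSF, cores stitched losslessly.

## Worked example

```python
import numpy as np
from fourierao import (OpticalConfig, Wavefront, make_pupil,
                       detection_psf, make_light_sheet, overall_psf,
                       simulate_sample, build_embedding, retrieve,
                       wavefront_metrics)
from fourierao.simulator import SimulationConfig, AmplitudeSampler

# a 0.2-lambda vertical astigmatism on the detection pupil
truth = Wavefront({(2, 2): 0.2})
print(wavefront_metrics(truth))
# {'rms': 0.2, 'peak_to_valley': 0.9721..., 'strehl': 0.2061...}

# image five puncta through it and embed the volume
cfg = SimulationConfig(photon_range=(1e5, 1e5), j_range=(5, 5))
sample = simulate_sample(cfg, seed=7, wavefront=truth)
emb = build_embedding(sample.camera_counts, cfg=cfg.optics)
print(emb.planes.shape)            # (6, 64, 64)

# independent check: phase-retrieve a noiseless bead image of the
# same aberration and compare coefficients
psf = detection_psf(make_pupil(cfg.optics, truth))
result = retrieve(psf, cfg.optics)
print(round(result.wavefront.amplitude((2, 2)), 3))   # 0.2
```

The Strehl ratio of 0.21 says this aberration is far past the 0.8
diffraction-limit criterion; after a perfect correction the residual
would be 0 lambda with Strehl 1. `retrieve` recovering 0.200 for the
injected mode is the closed-loop consistency check the test suite
leans on throughout.

To train and exercise the full loop from a shell:

```
fourierao simulate --preset train --n 32 --seed 1 --out data/
fourierao train --n 500 --epochs 2 --seed 1 --out ckpt/
fourierao correct --model ckpt/ --iterations 3 --seed 2 --out run/
```

`correct` prints the initial and final residual RMS and writes
per-iteration coefficient files (JSON and `n m amplitude` text, the
shape a deformable-mirror controller would ingest).

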