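# Methods

This note records the models implemented in `fourierao`, their
assumptions, the defaults and why they were chosen, and what the tests
do and do not demonstrate.

## Optical model

The detection-side point spread function is scalar Fourier optics: the
rear-pupil field is `E = A exp(i phi)` on a uniform disk of radius
`NA / lambda` (the standard surrogate when no phase-retrieved amplitude
map exists; a measured 2D map can be supplied), and each z-plane is the
squared modulus of the angular spectrum propagated with
`k_z = sqrt((2 pi eta / lambda)^2 - k_x^2 - k_y^2)` on the Ewald cap,
evanescent components excluded. Defaults describe a water-immersion
1.0-NA objective (`eta = 1.33`) at 510 nm emission sampling
64 x 64 x 64 voxels of 125 x 125 x 200 nm (an 8 x 8 x 12.8 um field of
view). Conventions fixed once: volumes are `(z, y, x)`, Fourier grids
are centered, positive horizontal coma `Z_3^1` moves the PSF centroid
toward `+x`, and the focal plane sits at index `D // 2`.

The light-sheet excitation enters only as an axial profile multiplying
the detection PSF. The default is a Gaussian of 1.5 um FWHM — a
realistic effective thickness for a swept square lattice, and a
conservative stand-in since lattice cross-sections are not reproducible
from published parameters alone; square and tabulated (measured)
profiles are accepted. Polarization/vectorial high-NA effects are out
of scope: the scalar model underestimates the vectorial PSF's lateral
asymmetry at NA 1.0, which is acceptable because every consumer of the
PSF in this package (training data, embedding reference, deconvolution
kernel) uses the same model self-consistently.

Zernike modes are RMS-normalized with ANSI/OSA ordering, so the
coefficient vector's Euclidean norm is the wavefront RMS in waves and
the quoted diffraction-limit correspondence (0.075 lambda RMS <->
Strehl 0.8 through the extended Marechal relation
`exp(-(2 pi sigma)^2)`) holds by construction. The normalization
convention is inferred: per-mode amplitudes quoted in "lambda RMS" only
make sense in an RMS-normalized basis. Both the Marechal Strehl (the
default metric) and the numeric on-axis peak ratio are available; they
agree to 0.1% below 0.1 lambda RMS on this sampling.

## Synthetic data

A sample draws `J` puncta (uniform 1–5 for the training envelope, up
to 150 for the test envelope) at continuous positions uniform over the
volume, each a 3D Gaussian of FWHM drawn from {100, 200, 300, 400} nm.
Puncta are evaluated analytically on the voxel grid at their continuous
positions — sub-voxel placement is what preserves the position phase
ramps the embedding later has to cancel — then convolved with the
overall PSF on a grid padded by 16 voxels so energy leaving the field
of view is lost rather than wrapped. The photon scale normalizes an
unclipped punctum to its integrated photon count `N_o` (uniform over
[1, 2e5] per volume in the training envelope; a per-punctum draw is
available behind a flag since the text description is ambiguous), and
the captured signal `S_V` never exceeds `J N_o`.

Ground-truth wavefronts mix four per-mode amplitude distributions with
equal probability (single mode; bimodal split; Lomax(gamma = 0.75)
power-law factors; uniform "Dirichlet" factors), each distributing a
total amplitude drawn uniformly from [0, 0.5] lambda RMS (training) or
[0, 1.0] (test) so that all 11 sensed modes contribute equally across a
dataset. The per-mode amplitudes of the multi-mode families sum to the
drawn total; amplitudes are non-negative by construction.

Camera model: quantum efficiency 0.82, Gaussian read noise 1.6 e- RMS,
offset 100 counts — typical sCMOS values, configurable, chosen because
no values are printed anywhere authoritative.

What the generator does *not* emulate: sample motion, photobleaching,
scattering background, spatially varying aberrations within one
volume, or vectorial PSF asymmetries. Tests passing on this generator
show the pipeline is self-consistent under the stated image-formation
model, not that the trained toy model transfers to real microscopes.

## Fourier embedding

Preprocessing normalizes a volume to [0, 1] by its 1st–99.99th
percentiles, subtracts a Gaussian background (sigma 8 voxels, applied
spectrally, which keeps the pipeline exactly equivariant to circular
shifts), applies a soft low-pass at the NA-limited OTF extents
(2 NA / lambda lateral, eta (1 - cos theta) axial; Gaussian rolloff of
3 k-voxels) and a lateral Tukey window (cosine fraction 0.5). No axial
window is applied — the embedding lives near `k_z = 0` where axial
windowing would cost aberration information.

Amplitude planes are the ratio of the volume's FFT amplitude to the
identically preprocessed ideal PSF's, evaluated where the ideal
amplitude exceeds 1e-3 of its maximum, normalized by the ratio's
zero-frequency value (so the planes are independent of puncta count
and brightness), laterally smoothed by normalized convolution
(sigma 1.5 px; damps the multiplicative speckle many random puncta
imprint on a single plane) and capped at 5 (larger values occur only
at the support rim where both numerator and denominator sit at the
floor). The planes are the principal `k_z = 0` plane and the means of
planes 0–4 and 5–9 on the `+k_z` side; Hermitian symmetry makes the
side choice information-free for amplitude, and it is fixed for phase.

Phase planes come from the interference-free transfer pattern
`tau = F(V) conj(F(S)) / (|F(S)|^2 + delta)`, where `S` retains
tapered 7-voxel cores around detected puncta (local maxima of the
preprocessed volume, confirmed by normalized cross-correlation >= 0.3
against a 16-voxel kernel cropped at the brightest punctum). Because
`S` is actual data, its spectrum carries the same position ramps,
relative brightnesses and interference nulls as `F(V)`, so the
division cancels fringes without the instability of dividing by a
synthetic position model. The core must stay well below the PSF
extent: retaining a PSF-sized neighborhood reduces `tau` to unity and
destroys the signal. Each `k_z` plane of `tau` is unwrapped in 2D on a
tighter support (floor at 8% of the ideal maximum: beyond it the
windowed spectrum undershoots zero and the phase degenerates to 0/pi
noise), its piston and best-fit linear ramp removed (ramps
encode only residual position offsets — tip/tilt, which are not
sensed — and otherwise dominate the dynamic range), and clipped to
+-2 pi.

A parity fact worth knowing when reading the planes: even-parity
aberrations (astigmatism, spherical) give an inversion-symmetric
projected image, so the principal plane of the 3D transform is real
and its phase holds only 0/pi contrast-inversion patches; smooth phase
signatures of even modes appear in the off-principal planes, while odd
modes (coma, trefoil) imprint directly on the principal plane. The
amplitude planes carry the even-mode information regardless.

## Transformer

Two stages with 32- and 16-pixel patches; the embedding width of a
stage equals its patch pixel count (1024, then 256), so no projection
bottleneck or spatial downsampling occurs between stages — patches are
merged back to plane space and re-tiled. Patches from all six planes
form one token sequence. The positional encoding is radial,
`[r, sin t, cos t, ..., sin 16t, cos 16t]` of the patch center about
the plane center (radius normalized to the outermost center),
concatenated with the patch pixels before one learnable projection
(implemented as the equivalent sum of two linear maps). Layers are
post-norm: `z1 = LN(MHA(z)) + z`, `z2 = LN(MLP(z1)) + z1`, MLP four
times the width, standard scaled dot-product attention, dropout 0.1 on
dense layers, stochastic depth 0.1, plus a stage-level skip. A global
average over the feature axis and a dense layer emit 15 coefficients;
the four unsensed modes are supervised to zero.

Training choices (unstated upstream, fixed here): mean-squared error
on the coefficient vector, Adam with linear warmup (5% of steps),
cosine decay, global gradient-norm clipping at 1.0, batch 32, learning
rate 1e-3, float32 throughout. The network runs on the package's own
reverse-mode autodiff engine (`fourierao.nn`), whose gradients are
finite-difference-checked in the tests; the tape frees intermediate
buffers as the backward sweep consumes them, so peak memory stays near
one set of activations.

Desk-scale sizing: the default test/acceptance runs train on a few
thousand simulated volumes of a deliberately narrow task — single-mode
aberrations on the two astigmatisms, amplitudes <= 0.3 lambda,
>= 1e5 photons — which is enough to demonstrate a learning signal
(median residual after one correction well below the median initial
aberration) and a non-increasing iterative-correction loop. This is a
scaled-down analogue, chosen as the smallest experiment that exercises
every training-path component; it makes no claim about the accuracy
of the full method trained on millions of samples across all modes.

## Phase retrieval

Multi-plane Gerchberg–Saxton: unit pupil amplitude on the NA disk,
forward-propagate to all 64 planes, impose the measured moduli,
back-propagate, average the pupil estimates, repeat (default 200
iterations, mean phase-update tolerance 1e-6). The volume is recentred
on its brightest voxel first (the method assumes an isolated,
near-centered bead and degrades if that fails). The retrieved phase is
unwrapped on the pupil, fitted to the first 15 modes, and
piston/tip/tilt/defocus are dropped. Noiseless contract: coefficients
within 0.02 lambda up to 0.15 lambda RMS total aberration — in
practice recovery is ~1e-3 exact — which qualifies it as the
independent oracle for everything else.

## Spatially varying deconvolution

Volumes are tiled by ceiling division into disjoint cores, each
extended by an apron (default 32 voxels, half the PSF width;
reflective padding at volume edges). Each extended tile is Wiener-
deconvolved with its assigned PSF inside the ideal-OTF support mask:
`conj(OTF) / (|OTF|^2 + beta |OTF|^2_max)`, `beta = 1e-2`, mask floor
1e-3 — the masking is what suppresses out-of-band artifacts when the
assumed PSF is wrong. Tiles with no wavefront assignment (insufficient
signal) fall back to the ideal PSF. Aprons are discarded and cores
concatenated without blending; stitching is lossless by construction
(an identity kernel returns the input bitwise). Because the hard OTF
mask gives the Wiener kernel long oscillatory tails, a tiled result is
not voxelwise identical to whole-volume deconvolution — restoration
quality (correlation with the underlying scene) matches, and seam
discontinuities shrink as the overlap grows. Single-pass Wiener only;
no iterative (Richardson–Lucy-style) refinement.

## Numerical notes and limitations

* Single precision everywhere hot (FFTs, network); normalization is
  done in double so a rescaled volume maps to bit-identical input.
  Scale invariance of the embedding is exact; circular-shift
  invariance holds to ~1e-5 (FFT rounding).
* Array powers (`x ** 3`) on negative operands take a slow scalar path
  in the NumPy build targeted; hot elementwise code uses explicit
  products.
* The interference-removal division is Wiener-regularized
  (`delta = 1e-6 |F(S)|^2_max`); a no-peak volume falls back to the
  raw OTF phase rather than failing.
* Problem sizes in tests and the acceptance script (hundreds to a few
  thousand simulated volumes, 12–50 seeds per Monte-Carlo estimate)
  were chosen as the smallest runs whose pass/fail criteria are stable
  across seeds.
* Known limitations: scalar PSF model; Gaussian surrogate sheet;
  amplitudes non-negative as specified upstream, so the toy model
  never sees negative coefficients during training (the iterative
  loop can still overshoot into them); no background structure in the
  simulator.
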