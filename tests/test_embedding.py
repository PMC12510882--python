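"""Fourier embedding: preprocessing, amplitude ratios, interference
removal and phase planes.

Expected values in these tests were frozen from noiseless or seeded
runs of the simulation oracle (render a known PSF, embed, measure).
"""

import numpy as np
import pytest

from fourierao.embedding import (EmbeddingConfig, IdealReference,
                                 NoSignalError, PreprocessConfig,
                                 build_embedding, fit_plane_wavefront,
                                 phase_embedding, preprocess,
                                 remove_interference, _centered_fft)
from fourierao.simulator import CameraModel, PunctaField, apply_camera, \
    render_volume
from fourierao.zernike import Wavefront, zernike_values


def noisy(volume, seed=0):
    return apply_camera(volume, CameraModel(), np.random.default_rng(seed))


class TestPreprocess:
    def test_constant_volume_maps_to_zero(self, optics):
        out = preprocess(np.full((64, 64, 64), 7.0), optics)
        assert np.abs(out).max() < 1e-6 * 7.0

    def test_axial_tone_above_cutoff_suppressed(self, optics):
        z = np.arange(64)
        tone = np.cos(2 * np.pi * 0.4 * z)[:, None, None] \
            * np.ones((1, 64, 64))
        out = preprocess(tone, optics)
        assert (out ** 2).sum() / (tone ** 2).sum() < 0.05

    def test_lateral_window_tapers_borders_but_not_axial(self, optics,
                                                         ideal):
        out = preprocess(ideal.intensity, optics)
        spine = np.abs(out[:, 32, 32])
        assert spine[0] > 0 or spine[-1] > 0 or spine.max() > 0
        # lateral borders are inside the zeroed quarter of the window
        assert np.abs(out[:, :, 0]).max() == 0
        assert np.abs(out[:, 0, :]).max() == 0

    def test_rejects_bad_input(self, optics):
        with pytest.raises(ValueError):
            preprocess(np.zeros((4, 4)), optics)
        with pytest.raises(ValueError):
            preprocess(np.full((16, 16, 16), np.nan), optics)
        with pytest.raises(ValueError):
            PreprocessConfig(tukey_alpha=1.5)


class TestAmplitudePlanes:
    def test_ideal_self_embedding_is_unity(self, optics, reference, ideal):
        emb = build_embedding(ideal.intensity, cfg=optics,
                              reference=reference)
        assert np.abs(emb.planes[0][emb.support] - 1).max() < 1e-6
        assert emb.planes.shape == (6, 64, 64)

    def test_scale_invariance(self, optics, reference, ideal):
        e1 = build_embedding(ideal.intensity, cfg=optics,
                             reference=reference)
        e2 = build_embedding(3.7 * ideal.intensity, cfg=optics,
                             reference=reference)
        assert np.abs(e1.planes - e2.planes).max() < 1e-6

    def test_astigmatism_attenuates_mean_ratio(self, optics, reference,
                                               aberrated_psf,
                                               centered_punctum):
        psf = aberrated_psf(Wavefront({(2, 2): 0.2}))
        vol, _, _ = render_volume(centered_punctum, psf, 1e5, optics)
        emb = build_embedding(noisy(vol), cfg=optics, reference=reference)
        assert emb.planes[0][emb.support].mean() < 0.95


class TestInterferenceRemoval:
    def test_no_peak_raises(self, reference):
        with pytest.raises(NoSignalError):
            remove_interference(np.zeros((64, 64, 64)),
                                reference.phase_support)

    def test_detects_well_separated_puncta(self, optics, reference,
                                           aberrated_psf):
        psf = aberrated_psf(None)
        pos = np.array([[20 * optics.dz, 16 * optics.dy, 16 * optics.dx],
                        [40 * optics.dz, 44 * optics.dy, 20 * optics.dx],
                        [30 * optics.dz, 20 * optics.dy, 44 * optics.dx],
                        [34 * optics.dz, 46 * optics.dy, 46 * optics.dx]])
        field = PunctaField(pos, np.full(4, 200.0))
        vol, _, _ = render_volume(field, psf, 2e4, optics)
        v = preprocess(noisy(vol), optics)
        im = remove_interference(v, reference.phase_support)
        assert len(im.peaks) == 4

    def test_two_puncta_fringes_removed(self, optics, reference,
                                        aberrated_psf):
        # two puncta 1 um apart produce phase fringes in the raw OTF
        # that the tau division must cancel
        psf = aberrated_psf(None)
        pos = np.array([[32 * optics.dz, 32 * optics.dy, 28 * optics.dx],
                        [32 * optics.dz, 32 * optics.dy, 36 * optics.dx]])
        vol, _, _ = render_volume(PunctaField(pos, np.full(2, 100.0)),
                                  psf, 1e5, optics)
        counts = noisy(vol)
        emb = build_embedding(counts, cfg=optics, reference=reference)
        fitted = fit_plane_wavefront(emb.planes[3], emb.phase_support)
        assert fitted.rms() < 0.02

        v = preprocess(counts, optics)
        tau_raw = np.where(reference.phase_support, _centered_fft(v), 0.0)
        raw_planes, _ = phase_embedding(tau_raw, reference.phase_support)
        raw_fit = fit_plane_wavefront(raw_planes[0], emb.phase_support)
        assert raw_fit.rms() > 0.05

    def test_mask_polarity_switch(self, optics, reference, aberrated_psf,
                                  centered_punctum):
        vol, _, _ = render_volume(centered_punctum, aberrated_psf(None),
                                  1e5, optics)
        v = preprocess(noisy(vol), optics)
        keep = remove_interference(v, reference.phase_support,
                                   EmbeddingConfig(mask_polarity="retain"))
        drop = remove_interference(v, reference.phase_support,
                                   EmbeddingConfig(mask_polarity="remove"))
        assert keep.masked_volume.sum() != drop.masked_volume.sum()
        with pytest.raises(ValueError):
            remove_interference(v, None,
                                EmbeddingConfig(mask_polarity="bogus"))


class TestPhasePlanes:
    def test_ideal_phase_planes_near_zero(self, optics, reference, ideal):
        emb = build_embedding(ideal.intensity, cfg=optics,
                              reference=reference)
        assert np.abs(emb.planes[3:][:, emb.phase_support]).max() < 0.05

    def test_even_aberration_principal_plane_is_flat(self, optics,
                                                     reference,
                                                     aberrated_psf):
        # parity: an even-parity pupil phase yields an inversion-
        # symmetric projected image, so the principal plane is real and
        # carries no smooth phase pattern
        psf = aberrated_psf(Wavefront({(2, 2): 0.05}))
        emb = build_embedding(psf.intensity, cfg=optics, reference=reference)
        assert np.abs(emb.planes[3][emb.phase_support]).max() < 0.05
        # the off-principal plane does carry the even-mode signature
        assert emb.planes[4][emb.phase_support].std() > 0.02

    def test_coma_pattern_reproducible_under_noise(self, optics, reference,
                                                   aberrated_psf,
                                                   centered_punctum):
        psf = aberrated_psf(Wavefront({(3, 1): 0.1}))
        ref_emb = build_embedding(psf.intensity, cfg=optics,
                                  reference=reference)
        vol, _, _ = render_volume(centered_punctum, psf, 1e5, optics)
        emb = build_embedding(noisy(vol), cfg=optics, reference=reference)
        sup = emb.phase_support
        r = np.corrcoef(emb.planes[3][sup], ref_emb.planes[3][sup])[0, 1]
        assert r > 0.9
        assert ref_emb.planes[3][sup].std() > 0.1  # a real pattern

    def test_single_punctum_tau_matches_direct_otf_phase(
            self, optics, reference, aberrated_psf, centered_punctum):
        # noiseless and without ramp detrending, so the comparison
        # isolates the interference-removal division itself
        from fourierao.embedding import remove_interference

        psf = aberrated_psf(Wavefront({(3, 1): 0.1}))
        vol, _, _ = render_volume(centered_punctum, psf, 1e5, optics)
        v = preprocess(vol, optics)
        im = remove_interference(v, reference.phase_support,
                                 reconstruct=False)
        via_tau, _ = phase_embedding(im.tau, reference.phase_support,
                                     detrend=False)
        tau_direct = np.where(reference.phase_support, _centered_fft(v), 0.0)
        direct, _ = phase_embedding(tau_direct, reference.phase_support,
                                    detrend=False)
        sup = reference.phase_support[32]
        f_tau = fit_plane_wavefront(via_tau[0], sup)
        f_dir = fit_plane_wavefront(direct[0], sup)
        modes = list(f_tau.coefficients)
        diff = np.linalg.norm(f_tau.to_vector(modes) - f_dir.to_vector(modes))
        assert diff < 0.01


class TestRobustness:
    def test_whole_voxel_shift_invariance_without_window(self, optics):
        # |F| is exactly invariant to circular shifts once the
        # (position-dependent) lateral window is disabled
        pcfg = PreprocessConfig(tukey_alpha=0.0)
        ref = IdealReference.build(optics, pcfg)
        from fourierao.optics import detection_psf, make_pupil, overall_psf, \
            make_light_sheet
        psf = overall_psf(
            detection_psf(make_pupil(optics,
                                     Wavefront({(3, 1): 0.12, (2, 2): 0.08}))),
            make_light_sheet("gaussian", 1500.0, optics))
        field = PunctaField(np.array([[32 * optics.dz, 32 * optics.dy,
                                       32 * optics.dx]]), np.array([100.0]))
        vol, _, _ = render_volume(field, psf, 1e5, optics)
        e1 = build_embedding(vol, cfg=optics, pcfg=pcfg, reference=ref)
        e2 = build_embedding(np.roll(vol, (0, 5, -7), axis=(0, 1, 2)),
                             cfg=optics, pcfg=pcfg, reference=ref)
        # single-precision FFT roundoff bounds the achievable agreement
        assert np.abs(e1.planes[:3] - e2.planes[:3]).max() < 2e-5

    def test_punctum_position_leaves_fitted_phase_stable(
            self, optics, reference, aberrated_psf):
        psf = aberrated_psf(Wavefront({(3, 1): 0.12, (2, 2): 0.08}))
        f1 = PunctaField(np.array([[32 * optics.dz, 32 * optics.dy,
                                    32 * optics.dx]]), np.array([100.0]))
        f2 = PunctaField(np.array([[32 * optics.dz, 37 * optics.dy,
                                    25 * optics.dx]]), np.array([100.0]))
        fits = []
        for f in (f1, f2):
            vol, _, _ = render_volume(f, psf, 1e5, optics)
            emb = build_embedding(vol, cfg=optics, reference=reference)
            fits.append(fit_plane_wavefront(emb.planes[3],
                                            emb.phase_support))
        modes = list(fits[0].coefficients)
        diff = np.abs(fits[0].to_vector(modes)
                      - fits[1].to_vector(modes)).max()
        assert diff < 0.01

    def test_many_puncta_embedding_consistent_with_single(
            self, optics, reference, aberrated_psf):
        # fifty dim puncta under one aberration carry the same
        # fingerprint as a single bright punctum
        psf = aberrated_psf(Wavefront({(3, 1): 0.12, (3, -3): 0.1,
                                       (2, 2): 0.08}))
        rng = np.random.default_rng(7)
        f1 = PunctaField(np.array([[32 * optics.dz, 32 * optics.dy,
                                    32 * optics.dx]]), np.array([100.0]))
        vol1, _, _ = render_volume(f1, psf, 1e5, optics)
        e1 = build_embedding(apply_camera(vol1, CameraModel(), rng),
                             cfg=optics, reference=reference)
        pos = rng.uniform(0.1, 0.9, (50, 3)) * np.array(
            [64 * optics.dz, 64 * optics.dy, 64 * optics.dx])
        f50 = PunctaField(pos, rng.choice([100.0, 200.0], 50))
        vol50, _, _ = render_volume(f50, psf, 1e5, optics)
        e50 = build_embedding(apply_camera(vol50, CameraModel(), rng),
                              cfg=optics, reference=reference)
        for plane in range(3):
            r = np.corrcoef(e1.planes[plane][e1.support],
                            e50.planes[plane][e1.support])[0, 1]
            assert r > 0.8
        fa = fit_plane_wavefront(e1.planes[3], e1.phase_support)
        fb = fit_plane_wavefront(e50.planes[3], e50.phase_support)
        modes = list(fa.coefficients)
        assert np.linalg.norm(fa.to_vector(modes)
                              - fb.to_vector(modes)) < 0.04

    def test_amplitude_snr_pools_across_puncta(self, optics, reference,
                                               aberrated_psf):
        # at fixed per-punctum photons, more puncta mean more captured
        # signal: the ratio planes get quieter across noise draws
        psf = aberrated_psf(Wavefront({(3, 1): 0.12, (3, -3): 0.1,
                                       (2, 2): 0.08}))
        snrs = []
        for j in (1, 5, 25):
            rng = np.random.default_rng(100)
            pos = rng.uniform(0.15, 0.85, (j, 3)) * np.array(
                [64 * optics.dz, 64 * optics.dy, 64 * optics.dx])
            vol, _, _ = render_volume(PunctaField(pos, np.full(j, 200.0)),
                                      psf, 5e3, optics)
            planes = []
            for k in range(5):
                emb = build_embedding(noisy(vol, seed=200 + k), cfg=optics,
                                      reference=reference)
                planes.append(emb.planes[0])
            planes = np.stack(planes)
            sup = emb.support
            snrs.append(planes.mean(0)[sup].mean()
                        / planes.std(0)[sup].mean())
        assert snrs[0] < snrs[1] < snrs[2]
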