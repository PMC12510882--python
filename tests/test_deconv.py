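"""Tile planning, OTF-masked Wiener deconvolution and stitching."""

import math

import numpy as np
import pytest
from scipy import fft as sfft

from fourierao.deconv import (TileGrid, WienerConfig, omw_deconvolve,
                              plan_tiles, spatially_varying_pipeline,
                              stitch)
from fourierao.optics import detection_psf, make_pupil
from fourierao.simulator import PunctaField, render_volume
from fourierao.zernike import Wavefront


def blur(scene, psf):
    kern = psf.intensity / psf.intensity.sum()
    return sfft.irfftn(sfft.rfftn(scene) * sfft.rfftn(
        sfft.ifftshift(kern)), scene.shape)


class TestPlanTiles:
    def test_fov_tiling_matches_map_of_204_patches(self):
        # 37 x 211 um at 6.3-um pitch: 6 x 34 = 204 isoplanatic tiles
        nx = math.ceil(37 / 6.3)
        ny = math.ceil(211 / 6.3)
        assert nx * ny == 204
        tile_vox = int(6300 / 125)
        grid = plan_tiles((64, nx * tile_vox, ny * tile_vox),
                          (64, tile_vox, tile_vox), 0)
        assert grid.n_tiles == 204

    def test_single_and_eightfold_tilings(self):
        assert plan_tiles((64, 64, 64), (64, 64, 64), 0).n_tiles == 1
        assert plan_tiles((64, 64, 64), (32, 32, 32), 0).n_tiles == 8

    def test_cores_cover_volume_exactly(self):
        grid = plan_tiles((48, 64, 80), (32, 32, 32), 8)
        covered = np.zeros((48, 64, 80), dtype=int)
        for i in range(grid.n_tiles):
            covered[grid.core_slices(i)] += 1
        assert (covered == 1).all()

    def test_oversized_tile_rejected(self):
        with pytest.raises(ValueError):
            plan_tiles((64, 64, 64), (65, 64, 64), 0)


class TestOMW:
    def test_point_restoration_sharpens(self, optics):
        psf = detection_psf(make_pupil(optics))
        scene = np.zeros((64, 64, 64))
        scene[32, 32, 32] = 1.0
        blurred = blur(scene, psf)
        dec = omw_deconvolve(blurred, psf, WienerConfig(beta=1e-4))
        assert np.unravel_index(dec.argmax(), dec.shape) == (32, 32, 32)

        def lateral_width(v):
            line = v[32, 32, :]
            return (line > line.max() / 2).sum()

        assert lateral_width(dec) <= 0.8 * lateral_width(blurred)

    def test_linearity(self, optics):
        psf = detection_psf(make_pupil(optics))
        rng = np.random.default_rng(0)
        a = rng.random((32, 32, 32))
        b = rng.random((32, 32, 32))
        lhs = omw_deconvolve(a + b, psf)
        rhs = omw_deconvolve(a, psf) + omw_deconvolve(b, psf)
        assert np.abs(lhs - rhs).max() < 1e-9 * np.abs(lhs).max()

    def test_matched_psf_beats_ideal_on_aberrated_scene(self, optics):
        # the in-silico analogue of comparing deconvolution with the
        # predicted aberrated PSF against an assumed ideal PSF
        w = Wavefront({(3, 1): 0.15, (2, 2): 0.1})
        psf_ab = detection_psf(make_pupil(optics, w))
        psf_id = detection_psf(make_pupil(optics))
        rng = np.random.default_rng(1)
        pos = rng.uniform(0.2, 0.8, (12, 3)) * np.array(
            [64 * optics.dz, 64 * optics.dy, 64 * optics.dx])
        field = PunctaField(pos, np.full(12, 200.0))
        scene, _, _ = render_volume(field, psf_id, 1e5, optics)
        # re-render the same field through the aberrated optics
        observed, _, _ = render_volume(field, psf_ab, 1e5, optics)
        dec_matched = omw_deconvolve(observed, psf_ab, ideal_psf=psf_id)
        dec_ideal = omw_deconvolve(observed, psf_id, ideal_psf=psf_id)
        r_matched = np.corrcoef(dec_matched.ravel(), scene.ravel())[0, 1]
        r_ideal = np.corrcoef(dec_ideal.ravel(), scene.ravel())[0, 1]
        assert r_matched > r_ideal

    def test_zero_psf_rejected(self):
        with pytest.raises(ValueError):
            omw_deconvolve(np.ones((8, 8, 8)), np.zeros((8, 8, 8)))


class TestStitch:
    def make_tiles(self, vol, grid):
        return [vol[grid.extended_slices(i)] for i in range(grid.n_tiles)]

    def test_core_concatenation_lossless(self):
        rng = np.random.default_rng(2)
        vol = rng.random((64, 64, 64))
        grid = plan_tiles(vol.shape, (32, 32, 32), 8)
        assert np.array_equal(stitch(self.make_tiles(vol, grid), grid), vol)

    def test_missing_tile_detected(self):
        grid = plan_tiles((64, 64, 64), (32, 32, 32), 0)
        with pytest.raises(ValueError):
            stitch([np.zeros((32, 32, 32))] * 7, grid)

    def test_core_voxels_sum_to_volume(self):
        grid = plan_tiles((48, 64, 80), (32, 32, 32), 4)
        total = sum(int(np.prod([s.stop - s.start
                                 for s in grid.core_slices(i)]))
                    for i in range(grid.n_tiles))
        assert total == 48 * 64 * 80


class TestPipeline:
    @pytest.fixture(scope="class")
    def smooth_scene(self):
        rng = np.random.default_rng(3)
        z, y, x = np.mgrid[:64, :64, :64]
        scene = np.zeros((64, 64, 64))
        for _ in range(6):
            c = rng.uniform(16, 48, 3)
            s = rng.uniform(4, 8)
            scene += np.exp(-((z - c[0]) ** 2 + (y - c[1]) ** 2
                              + (x - c[2]) ** 2) / (2 * s * s))
        return scene

    def test_uniform_map_equals_single_psf_tiling(self, optics,
                                                  smooth_scene):
        w = Wavefront({(2, 2): 0.1})
        wf_map_a = {i: w for i in range(8)}
        out_a = spatially_varying_pipeline(smooth_scene, wf_map_a, optics,
                                           tile_shape=(32, 32, 32),
                                           overlap=16)
        out_b = spatially_varying_pipeline(smooth_scene, wf_map_a, optics,
                                           tile_shape=(32, 32, 32),
                                           overlap=16)
        assert np.array_equal(out_a, out_b)

    def test_tiled_restoration_matches_global_quality(self, optics,
                                                      smooth_scene):
        # the hard OTF mask gives the Wiener kernel long tails, so the
        # tiled result is not voxelwise identical to whole-volume
        # deconvolution; restoration quality must match, though
        psf = detection_psf(make_pupil(optics))
        observed = blur(smooth_scene, psf)
        whole = omw_deconvolve(observed, psf)
        tiled = spatially_varying_pipeline(observed, {}, optics,
                                           tile_shape=(32, 32, 32),
                                           overlap=16)
        r_whole = np.corrcoef(whole.ravel(), smooth_scene.ravel())[0, 1]
        r_tiled = np.corrcoef(tiled.ravel(), smooth_scene.ravel())[0, 1]
        assert r_tiled > r_whole - 0.05
        assert r_tiled > 0.8

    def test_identity_kernel_pipeline_is_lossless(self, optics,
                                                  monkeypatch):
        import fourierao.deconv as D

        vol = np.random.default_rng(0).random((64, 64, 64))
        monkeypatch.setattr(
            D, "omw_deconvolve",
            lambda tile, psf, cfg=None, ideal_psf=None: np.asarray(tile,
                                                                   float))
        out = D.spatially_varying_pipeline(vol, {}, optics,
                                           tile_shape=(32, 32, 32),
                                           overlap=16)
        assert np.array_equal(out, vol)

    def test_spatially_varying_map_beats_any_single_psf(self, optics):
        # left half astigmatic, right half comatic: the correct
        # per-tile map must outperform either global choice
        w_l = Wavefront({(2, 2): 0.15})
        w_r = Wavefront({(3, 1): 0.15})
        psf_l = detection_psf(make_pupil(optics, w_l))
        psf_r = detection_psf(make_pupil(optics, w_r))
        rng = np.random.default_rng(4)
        pos = rng.uniform(0.15, 0.85, (16, 3)) * np.array(
            [64 * optics.dz, 64 * optics.dy, 64 * optics.dx])
        field = PunctaField(pos, np.full(16, 200.0))
        truth, _, _ = render_volume(field, detection_psf(make_pupil(optics)),
                                    1e5, optics)
        left, _, _ = render_volume(field, psf_l, 1e5, optics)
        right, _, _ = render_volume(field, psf_r, 1e5, optics)
        observed = np.concatenate([left[:, :, :32], right[:, :, 32:]],
                                  axis=2)
        # tiles (x-major ordering): indices 0..3 left column pairs
        grid = plan_tiles((64, 64, 64), (64, 64, 32), 16)
        assert grid.n_tiles == 2
        correct = spatially_varying_pipeline(
            observed, {0: w_l, 1: w_r}, optics,
            tile_shape=(64, 64, 32), overlap=16)
        global_l = spatially_varying_pipeline(
            observed, {0: w_l, 1: w_l}, optics,
            tile_shape=(64, 64, 32), overlap=16)
        global_r = spatially_varying_pipeline(
            observed, {0: w_r, 1: w_r}, optics,
            tile_shape=(64, 64, 32), overlap=16)

        def score(v):
            return np.corrcoef(v.ravel(), truth.ravel())[0, 1]

        assert score(correct) > score(global_l)
        assert score(correct) > score(global_r)

    def test_larger_overlap_never_increases_seam_discontinuity(
            self, optics, smooth_scene):
        psf = detection_psf(make_pupil(optics))
        observed = blur(smooth_scene, psf)
        seams = []
        for ov in (4, 8, 16):
            out = spatially_varying_pipeline(observed, {}, optics,
                                             tile_shape=(32, 32, 32),
                                             overlap=ov)
            # typical jump across the x = 32 tile seam
            seams.append(np.median(np.abs(np.diff(out, axis=2))[:, :, 31]))
        assert seams[2] <= seams[1] <= seams[0]
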