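"""Non-rigid registration, stable triangulation, deformation mapping."""

import numpy as np
import pytest
from scipy import ndimage

from ringpact import (
    FrameSequence,
    deformation_map,
    estimate_compression_frequency,
    generate_dynamic_frames,
    register_nonrigid,
    stable_triangulation,
)


def textured_base(seed=0, shape=(100, 100)):
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.random(shape), 1.5)
    img = (img - img.min()) / (img.max() - img.min())
    return img


class TestRegisterNonrigid:
    def test_too_few_frames_rejected(self):
        seq = FrameSequence(frames=np.zeros((4, 16, 16)))
        with pytest.raises(ValueError, match="10 frames"):
            register_nonrigid(seq)

    def test_identical_frames_zero_displacement(self):
        base = textured_base()
        seq = FrameSequence(frames=np.repeat(base[None], 12, axis=0))
        disp = register_nonrigid(seq)
        assert np.abs(disp.fields).max() < 0.05
        assert disp.excluded == []

    def test_planted_smooth_warp_recovered(self):
        """A 2-px sinusoidal warp is recovered to < 0.5 px RMS."""
        base = textured_base(1)
        ny, nx = base.shape
        yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
        uy = 2.0 * np.sin(2 * np.pi * xx / nx)
        ux = 2.0 * np.cos(2 * np.pi * yy / ny)
        warped = ndimage.map_coordinates(
            base, [yy + uy, xx + ux], order=1, mode="nearest"
        )
        frames = np.repeat(base[None], 10, axis=0)
        frames[5] = warped
        seq = FrameSequence(frames=frames)
        disp = register_nonrigid(seq)
        # the field that maps the warped frame back onto the reference is
        # −u_true; compare in the interior (demons is unreliable at borders)
        sl = (slice(15, -15), slice(15, -15))
        err = np.sqrt(
            np.mean(
                (disp.fields[5][..., 0][sl] + uy[sl]) ** 2
                + (disp.fields[5][..., 1][sl] + ux[sl]) ** 2
            )
        )
        assert err < 0.5

    def test_noise_frame_warns_and_excluded(self):
        base = textured_base(2)
        frames = np.repeat(base[None], 10, axis=0)
        frames[3] = np.random.default_rng(0).random(base.shape)
        seq = FrameSequence(frames=frames)
        with pytest.warns(UserWarning, match="converge"):
            disp = register_nonrigid(seq)
        assert 3 in disp.excluded


class TestStableTriangulation:
    def test_square_size_in_pixels(self, compression_study):
        """2-mm squares at 0.1-mm pixels are 20×20 px: one candidate list
        per square tile of the 160×160 field."""
        seq, _, disp, grid = compression_study
        assert len(grid.candidates) == (160 // 20) ** 2
        assert len(grid.points) >= 3
        assert grid.areas.shape[0] == seq.n_frames

    def test_rigid_translation_preserves_areas(self):
        base = textured_base(4)
        n = 12
        frames = np.stack(
            [
                ndimage.shift(base, (0.3 * i, -0.2 * i), order=1, mode="nearest")
                for i in range(n)
            ]
        )
        seq = FrameSequence(frames=frames)
        disp = register_nonrigid(seq)
        grid = stable_triangulation(seq, disp, seed=1)
        rel = grid.areas / grid.areas[0]
        # rigid motion: areas constant across frames; tolerate demons noise
        # in sliver/border triangles via robust statistics
        err = np.abs(rel - 1.0)
        assert np.median(err) < 0.02
        assert np.percentile(err, 90) < 0.06

    def test_uniform_dilation_scales_areas_quadratically(self):
        base = textured_base(5)
        eps = 0.01
        ny, nx = base.shape
        yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
        cy, cx = (ny - 1) / 2, (nx - 1) / 2
        dil = ndimage.map_coordinates(
            base,
            [cy + (yy - cy) / (1 + eps), cx + (xx - cx) / (1 + eps)],
            order=1,
            mode="nearest",
        )
        frames = np.repeat(base[None], 10, axis=0)
        frames[4] = dil
        seq = FrameSequence(frames=frames)
        disp = register_nonrigid(seq)
        grid = stable_triangulation(seq, disp, seed=2)
        # keep interior triangles only
        cent = grid.points[grid.simplices].mean(axis=1)
        interior = (
            (cent[:, 0] > 20) & (cent[:, 0] < 80)
            & (cent[:, 1] > 20) & (cent[:, 1] < 80)
        )
        ratio = grid.areas[4][interior] / grid.areas[0][interior]
        assert np.median(ratio) == pytest.approx((1 + eps) ** 2, abs=0.01)

    def test_too_few_points_rejected(self, compression_study):
        seq, _, disp, _ = compression_study
        with pytest.raises(ValueError, match="fewer than 3"):
            stable_triangulation(seq, disp, std_cutoff=-1.0)


class TestDeformationMap:
    def test_static_sequence_zero_map(self):
        base = textured_base(6)
        seq = FrameSequence(frames=np.repeat(base[None], 40, axis=0))
        disp = register_nonrigid(seq)
        grid = stable_triangulation(seq, disp, seed=0)
        dmap = deformation_map(grid, 0.25, n_realizations=3, seed=0)
        assert np.abs(dmap.amplitude).max() < 1e-3

    def test_super_nyquist_rejected(self, compression_study):
        _, _, _, grid = compression_study
        with pytest.raises(ValueError, match="Nyquist"):
            deformation_map(grid, 6.0)

    def test_inclusion_contrast_and_localization(self, compression_study):
        """Planted 0.5-compliance inclusion: amplitude ratio in [0.4, 0.6]
        and the lowest-deformation region overlaps it with IoU ≥ 0.5."""
        seq, incl, disp, grid = compression_study
        dmap = deformation_map(grid, 0.25, n_realizations=20, seed=0)
        yy, xx = np.mgrid[0 : seq.frames.shape[1], 0 : seq.frames.shape[2]]
        core = (yy - 80) ** 2 + (xx - 80) ** 2 <= 18**2
        bg = (
            ~incl
            & ((yy - 80) ** 2 + (xx - 80) ** 2 >= 45**2)
            & (yy > 15) & (yy < 145) & (xx > 15) & (xx < 145)
        )
        a = dmap.amplitude
        inside = a[core & (a > 0)].mean()
        outside = a[bg & (a > 0)].mean()
        assert 0.4 <= inside / outside <= 0.6
        # localization: largest connected low-deformation region vs truth
        valid = a > 0
        thr = np.percentile(a[valid], 30)
        low = valid & (a <= thr)
        lab, n = ndimage.label(low)
        sizes = ndimage.sum(low, lab, range(1, n + 1))
        big = lab == (1 + int(np.argmax(sizes)))
        iou = (big & incl).sum() / (big | incl).sum()
        assert iou >= 0.5

    def test_deterministic_without_noise(self, compression_study):
        """Same seed and realization count give identical maps."""
        _, _, _, grid = compression_study
        m1 = deformation_map(grid, 0.25, n_realizations=2, seed=5)
        m2 = deformation_map(grid, 0.25, n_realizations=2, seed=5)
        assert np.array_equal(m1.amplitude, m2.amplitude)

    def test_compression_frequency_estimated(self, compression_study):
        _, _, _, grid = compression_study
        f = estimate_compression_frequency(grid)
        assert f == pytest.approx(0.25, abs=0.06)
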