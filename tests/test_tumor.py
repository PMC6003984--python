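"""Vessel density, tumor segmentation boundary behavior, ROC statistics."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ringpact import segment_tumors, vessel_density_map
from ringpact.tumor import DensityMap, _trapezoid_auc, density_ratio_and_roc
from ringpact.vessels import SegmentSet, skeleton_segments


def segset_from_mask(mask):
    return skeleton_segments(mask)


def brute_force_density(segments, shape, w, window_mm):
    """Independent oracle: per-pixel loop counting distinct segments whose
    pixels fall in the window [i−w//2, i+w−w//2) per axis."""
    ny, nx = shape
    lab = np.zeros(shape, dtype=int)
    for i, seg in enumerate(segments.segments):
        lab[seg[:, 0], seg[:, 1]] = i + 1
    out = np.zeros(shape)
    lo = w // 2
    hi = w - lo
    for i in range(ny):
        for j in range(nx):
            win = lab[max(i - lo, 0) : i + hi, max(j - lo, 0) : j + hi]
            ids = np.unique(win)
            out[i, j] = (ids > 0).sum()
    return out / window_mm**2


class TestVesselDensityMap:
    def test_window_is_20_pixels_at_default_scales(self):
        """2-mm window at 0.1-mm pixels spans 20 px."""
        m = np.zeros((60, 60), bool)
        m[30, 10:50] = True
        segs = segset_from_mask(m)
        dm = vessel_density_map(segs, m.shape, window_mm=2.0, pixel_size=0.1)
        # a pixel 9 rows away still sees the segment; 11 rows away does not
        assert dm.density[30 - 9, 30] > 0
        assert dm.density[30 - 11, 30] == 0

    def test_empty_segments_zero_map(self):
        segs = SegmentSet(
            skeleton=np.zeros((40, 40), bool), segments=[],
            junctions=np.zeros((0, 2), int),
        )
        dm = vessel_density_map(segs, (40, 40))
        assert np.all(dm.density == 0)
        assert dm.mean == 0.0

    def test_uniform_parallel_lines_density(self):
        """Lines every 1 mm: a 2×2 mm window sees 2 segments on average
        → 0.5 segments/mm² away from borders."""
        m = np.zeros((200, 200), bool)
        for r in range(20, 190, 10):   # 1 mm apart at 0.1 mm pixels
            m[r, 10:190] = True
        segs = segset_from_mask(m)
        dm = vessel_density_map(segs, m.shape, 2.0, 0.1)
        inner = dm.density[60:140, 60:140]
        assert inner.mean() == pytest.approx(0.5, rel=0.15)

    def test_matches_brute_force_window_counting(self):
        """Dilated-count implementation equals the per-pixel loop oracle."""
        rng = np.random.default_rng(1)
        m = np.zeros((80, 80), bool)
        for _ in range(8):
            r, c = rng.integers(10, 70, 2)
            length = rng.integers(8, 25)
            if rng.random() < 0.5:
                m[r, c : min(c + length, 78)] = True
            else:
                m[r : min(r + length, 78), c] = True
        segs = segset_from_mask(m)
        dm = vessel_density_map(segs, m.shape, window_mm=2.0, pixel_size=0.1)
        oracle = brute_force_density(segs, m.shape, 20, 2.0)
        assert np.array_equal(dm.density, oracle)

    def test_planted_cluster_density_contrast(self):
        """A region with 3× the segment count shows ~3× the density."""
        m = np.zeros((300, 300), bool)
        for r in range(20, 290, 30):       # sparse background
            m[r, 20:280] = True
        for r in range(140, 170, 10):      # dense cluster rows (3× locally)
            m[r, 100:200] = True
        segs = segset_from_mask(m)
        dm = vessel_density_map(segs, m.shape, 2.0, 0.1)
        cluster = dm.density[150, 150]
        background = dm.density[80, 150]
        assert cluster / max(background, 1e-9) >= 2.0


def disc_mask(shape, center, n_px):
    """Connected blob of exactly n_px pixels grown from a disc."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    order = np.argsort(d2.ravel(), kind="stable")
    m = np.zeros(shape, bool)
    m.ravel()[order[:n_px]] = True
    return m


class TestSegmentTumors:
    def _dm(self, density, pixel=0.1):
        support = np.ones(density.shape, bool)
        return DensityMap(
            density=density, window_mm=2.0, pixel_size=pixel,
            support_mask=support, mean=float(density.mean()),
            sd=float(density.std()),
        )

    def test_constant_map_warns_no_regions(self):
        dm = self._dm(np.ones((64, 64)))
        with pytest.warns(UserWarning, match="variance"):
            seg = segment_tumors(dm)
        assert seg.regions == []

    def test_1855_pixel_boundary(self):
        """Two supra-threshold blobs of 1854 and 1856 px: only the larger
        one survives the minimum-area filter."""
        density = np.zeros((300, 300))
        small = disc_mask((300, 300), (75, 75), 1854)
        large = disc_mask((300, 300), (220, 220), 1856)
        density[small] = 10.0
        density[large] = 10.0
        dm = self._dm(density)
        seg = segment_tumors(dm, k_sigma=2.0, min_pixels=1855)
        assert len(seg.regions) == 1
        cy, cx = seg.regions[0].centroid
        assert (cy, cx) == pytest.approx((220, 220), abs=2)
        assert seg.regions[0].n_pixels == 1856

    def test_planted_gaussian_bump_localized(self):
        """A mean+4σ bump with a large supra-threshold core yields one
        region centred within 1 mm of the planted centre."""
        yy, xx = np.mgrid[0:400, 0:400]
        rng = np.random.default_rng(0)
        base = rng.normal(1.0, 0.05, (400, 400))
        bump = np.exp(-((yy - 150) ** 2 + (xx - 260) ** 2) / (2 * 30.0**2))
        density = base + 4 * 0.05 * 2.0 * bump
        dm = self._dm(np.clip(density, 0, None))
        seg = segment_tumors(dm, k_sigma=2.0, min_pixels=1855)
        assert len(seg.regions) == 1
        cy, cx = seg.regions[0].centroid
        assert np.hypot(cy - 150, cx - 260) * 0.1 <= 1.0

    def test_monotone_in_k_sigma(self):
        rng = np.random.default_rng(5)
        density = rng.gamma(2.0, 1.0, (300, 300))
        density[100:180, 100:180] += 3.0
        dm = self._dm(density)
        masks = {}
        for k in (1.5, 2.0, 2.5):
            seg = segment_tumors(dm, k_sigma=k, min_pixels=50)
            masks[k] = seg.labels > 0
        assert np.all(masks[2.5] <= masks[2.0])
        assert np.all(masks[2.0] <= masks[1.5])

    def test_longest_dimension(self):
        density = np.zeros((200, 200))
        density[50:60, 20:180] = 5.0   # 10 × 160 px bar
        dm = self._dm(density)
        seg = segment_tumors(dm, min_pixels=100)
        # diagonal of a 10×160 px bar at 0.1 mm/px
        expected = np.hypot(9, 159) * 0.1
        assert seg.regions[0].longest_dimension_mm == pytest.approx(
            expected, abs=0.2
        )


class TestDensityRatioRoc:
    def _maps_from_ratios(self, ratios):
        """Construct density maps whose density_ratio equals ~the given
        value at k=2.0 by planting a high-density plateau."""
        maps = []
        for r in ratios:
            d = np.ones((120, 120))
            d[:40, :40] += np.random.default_rng(0).normal(0, 0.01, (40, 40))
            d[50:80, 50:80] = r  # high region: ratio ≈ r / 1
            maps.append(
                DensityMap(
                    density=d, window_mm=2.0, pixel_size=0.1,
                    support_mask=np.ones_like(d, bool),
                    mean=float(d.mean()), sd=float(d.std()),
                )
            )
        return maps

    def test_perfect_separation_auc_one(self):
        maps = self._maps_from_ratios([4.0, 4.5, 2.0, 2.2])
        labels = [1, 1, 0, 0]
        res = density_ratio_and_roc(maps, labels, k_sigma_options=(2.0,))
        assert res.auc[2.0] == pytest.approx(1.0)

    def test_interleaved_ratios_auc_075(self):
        """Affected {2.5, 3.5} vs contralateral {2.0, 3.0}: 3 of 4
        concordant pairs → AUC = 0.75 by Mann–Whitney counting."""
        ratios = np.array([2.5, 3.5, 2.0, 3.0])
        labels = np.array([1, 1, 0, 0])
        thresholds = np.arange(1.0, 6.005, 0.01)
        auc = _trapezoid_auc(ratios, labels, thresholds)
        assert auc == pytest.approx(0.75, abs=1e-9)

    def test_all_equal_ratios_auc_half(self):
        ratios = np.array([2.0, 2.0, 2.0, 2.0])
        labels = np.array([1, 1, 0, 0])
        thresholds = np.arange(1.0, 6.005, 0.01)
        auc = _trapezoid_auc(ratios, labels, thresholds)
        assert auc == pytest.approx(0.5, abs=1e-9)

    def test_sweep_auc_equals_mann_whitney(self):
        """On tie-free data the sweep AUC equals sklearn's rank AUC."""
        rng = np.random.default_rng(11)
        ratios = np.round(rng.uniform(1.2, 5.8, 16), 3)
        while len(np.unique(ratios)) < 16:
            ratios = np.round(rng.uniform(1.2, 5.8, 16), 3)
        labels = rng.integers(0, 2, 16)
        if labels.sum() in (0, 16):
            labels[0] = 1 - labels[0]
        thresholds = np.arange(1.0, 6.005, 0.01)
        auc = _trapezoid_auc(ratios, labels, thresholds)
        assert auc == pytest.approx(roc_auc_score(labels, ratios), abs=1e-12)

    def test_sensitivity_specificity_monotone(self):
        maps = self._maps_from_ratios([4.0, 3.0, 2.0, 2.6])
        res = density_ratio_and_roc(maps, [1, 1, 0, 0], k_sigma_options=(2.0,))
        assert np.all(np.diff(res.sensitivity[2.0]) <= 0)
        assert np.all(np.diff(res.specificity[2.0]) >= 0)

    def test_needs_both_classes(self):
        maps = self._maps_from_ratios([3.0, 3.0])
        with pytest.raises(ValueError, match="affected"):
            density_ratio_and_roc(maps, [1, 1])
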