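"""Vessel-tree generation (planted diameter law) and phantom rasterization."""

import numpy as np
import pytest

from ringpact import (
    GridSpec,
    TumorSpec,
    generate_vessel_tree,
    junction_metrics,
    rasterize_phantom,
)
from ringpact.phantom import _segments_in_disc
from ringpact.tree import VesselTree


class TestGenerateVesselTree:
    def test_seeded_determinism(self):
        t1 = generate_vessel_tree(seed=1, n_levels=3)
        t2 = generate_vessel_tree(seed=1, n_levels=3)
        assert len(t1.segments) == len(t2.segments)
        for a, b in zip(t1.segments, t2.segments):
            assert np.array_equal(a.polyline, b.polyline)
            assert a.radius == b.radius
        assert t1.bifurcations == t2.bifurcations

    def test_symmetric_murray_daughters(self):
        """X = 3, symmetric: both daughters are 2^(-1/3) of the parent."""
        t = generate_vessel_tree(
            seed=0, n_levels=1, root_diameter=1.0, junction_exponent=3.0,
            asymmetry=1.0,
        )
        (dp, da, db) = t.bifurcation_diameters()[0]
        assert dp == pytest.approx(1.0)
        assert da == pytest.approx(2 ** (-1 / 3), abs=1e-12)
        assert db == pytest.approx(2 ** (-1 / 3), abs=1e-12)

    def test_binary_tree_shape(self):
        t = generate_vessel_tree(seed=5, n_levels=4)
        assert len(t.segments) == 2 ** 5 - 1
        assert len(t.bifurcations) == 2 ** 4 - 1

    @pytest.mark.parametrize("planted_x", [2.0, 2.63, 3.0])
    def test_junction_round_trip(self, planted_x):
        """Every generated bifurcation returns the planted exponent."""
        t = generate_vessel_tree(
            seed=11, n_levels=3, junction_exponent=planted_x, asymmetry=0.75
        )
        for dp, da, db in t.bifurcation_diameters():
            # planted law holds to numerical precision
            assert dp**planted_x == pytest.approx(
                da**planted_x + db**planted_x, abs=1e-9
            )
            b = junction_metrics(dp, da, db)
            assert b.x_b == pytest.approx(planted_x, abs=1e-6)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_levels=0),
            dict(root_diameter=-1.0),
            dict(root_diameter=7.0),
            dict(junction_exponent=1.0),
            dict(asymmetry=0.0),
            dict(asymmetry=1.5),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_vessel_tree(seed=0, **{"n_levels": 2, **kwargs})


class TestRasterizePhantom:
    def test_empty_tree_gives_zero_grid(self):
        empty = VesselTree([], [], 1.0, 1, 3.0, 1.0, 0)
        grid = GridSpec(shape=(1, 64, 64), voxel_xy=0.1)
        ph = rasterize_phantom(empty, grid)
        assert np.all(ph.absorption == 0.0)

    def test_cross_section_width_matches_radius(self):
        """A 0.5-mm-radius straight vessel at 0.1-mm pixels is ~10 px wide."""
        seg = VesselTree(
            segments=[
                __import__("ringpact").VesselSegment(
                    np.array([[-3.0, 0.0], [3.0, 0.0]]), 0.5, 0
                )
            ],
            bifurcations=[],
            root_diameter=1.0,
            n_levels=1,
            junction_exponent=3.0,
            asymmetry=1.0,
            seed=0,
        )
        grid = GridSpec(shape=(1, 101, 101), voxel_xy=0.1)
        ph = rasterize_phantom(seg, grid)
        mid_col = ph.absorption[0][:, 50]
        assert 9 <= int((mid_col > 0).sum()) <= 12

    def test_tree_outside_grid_rejected(self):
        t = generate_vessel_tree(seed=3, n_levels=3, root_diameter=1.5)
        tiny = GridSpec(shape=(1, 21, 21), voxel_xy=0.1)
        with pytest.raises(ValueError, match="outside"):
            rasterize_phantom(t, tiny)

    def test_tumor_density_multiplier(self):
        """Segment count inside the tumor disc is ~3× a background disc."""
        t = generate_vessel_tree(
            seed=2, n_levels=4, root_diameter=1.0,
            root_position=(-12.0, 0.0),
        )
        grid = GridSpec(shape=(1, 321, 321), voxel_xy=0.1)
        tumor = TumorSpec(center=(5.0, -5.0), radius=4.0, density_multiplier=3.0)
        ph = rasterize_phantom(t, grid, tumor, seed=2)
        all_segments = list(t.segments) + list(ph.extra_segments)
        in_tumor = _segments_in_disc(all_segments, (5.0, -5.0), 4.0)
        # brute-force counts in background discs of the same size
        rng = np.random.default_rng(0)
        bg = []
        pts = np.vstack([s.polyline for s in t.segments])
        for _ in range(200):
            p = pts[rng.integers(len(pts))]
            if np.hypot(p[0] - 5.0, p[1] + 5.0) > 8.0:
                bg.append(_segments_in_disc(all_segments, p, 4.0))
        ratio = in_tumor / np.mean(bg)
        assert 2.0 <= ratio <= 4.0

    def test_stiffness_factor_inside_tumor(self):
        t = generate_vessel_tree(seed=2, n_levels=2, root_position=(-8.0, 0.0))
        grid = GridSpec(shape=(1, 401, 401), voxel_xy=0.1)
        tumor = TumorSpec(center=(6.0, 6.0), radius=3.0, stiffness_factor=0.5)
        ph = rasterize_phantom(t, grid, tumor, seed=0)
        yy, xx = np.mgrid[0:401, 0:401]
        xg, yg = grid.index_to_xy(yy, xx)
        inside = (xg - 6.0) ** 2 + (yg - 6.0) ** 2 <= 2.5**2
        outside = (xg - 6.0) ** 2 + (yg - 6.0) ** 2 >= 4.0**2
        assert np.all(ph.stiffness[0][inside] == 0.5)
        assert np.all(ph.stiffness[0][outside] == 1.0)

    def test_to_sources_positions(self):
        t = generate_vessel_tree(seed=4, n_levels=1, root_position=(-5.0, 0.0))
        grid = GridSpec(shape=(1, 321, 321), voxel_xy=0.1)
        ph = rasterize_phantom(t, grid)
        src = ph.to_sources()
        assert src.shape[1] == 5
        assert len(src) == int((ph.absorption > 0).sum())
        assert np.all(src[:, 4] > 0)
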