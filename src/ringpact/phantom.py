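"""Voxel phantoms: rasterized vessel trees, tumor regions, stiffness maps.

The phantom bridges the vector vessel tree to the voxel grid that the
reconstruction operates on (0.1 mm in-plane, 1 mm elevational by default).
A tumor is emulated as a disc with an elevated count of short extra vessel
segments (angiogenesis contrast) and a reduced relative compliance
(stiffness analog of a stiff agar inclusion in a softer base).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .tree import VesselSegment, VesselTree

__all__ = ["GridSpec", "TumorSpec", "Phantom", "rasterize_phantom"]


@dataclass(frozen=True)
class GridSpec:
    """Voxel grid centred on the ring axis. Sizes mm; origin = voxel (0,0,0) centre."""

    shape: Tuple[int, int, int]            # (nz, ny, nx)
    voxel_xy: float = 0.1
    voxel_z: float = 1.0
    origin: Tuple[float, float, float] = None  # (z0, y0, x0); default centres grid

    def __post_init__(self):
        if self.origin is None:
            nz, ny, nx = self.shape
            object.__setattr__(
                self,
                "origin",
                (
                    -self.voxel_z * (nz - 1) / 2.0,
                    -self.voxel_xy * (ny - 1) / 2.0,
                    -self.voxel_xy * (nx - 1) / 2.0,
                ),
            )

    @classmethod
    def planar(cls, extent_mm: float, voxel_xy: float = 0.1) -> "GridSpec":
        n = int(round(extent_mm / voxel_xy)) + 1
        return cls(shape=(1, n, n), voxel_xy=voxel_xy)

    def xy_to_index(self, x, y):
        col = (np.asarray(x) - self.origin[2]) / self.voxel_xy
        row = (np.asarray(y) - self.origin[1]) / self.voxel_xy
        return row, col

    def index_to_xy(self, row, col):
        return (
            self.origin[2] + np.asarray(col) * self.voxel_xy,
            self.origin[1] + np.asarray(row) * self.voxel_xy,
        )


@dataclass(frozen=True)
class TumorSpec:
    center: Tuple[float, float]      # (x, y) mm
    radius: float                    # mm
    density_multiplier: float = 3.0  # ≥ 1
    stiffness_factor: float = 0.5    # ≤ 1 (relative compliance)

    def __post_init__(self):
        if self.density_multiplier < 1:
            raise ValueError("density_multiplier must be ≥ 1")
        if not 0 < self.stiffness_factor <= 1:
            raise ValueError("stiffness_factor must be in (0, 1]")


@dataclass
class Phantom:
    absorption: np.ndarray           # (nz, ny, nx) ≥ 0
    stiffness: np.ndarray            # relative compliance, 1 = background
    labels: np.ndarray               # 0 bg, 1 vessel, 2 tumor region
    grid: GridSpec
    tumor: Optional[TumorSpec] = None
    extra_segments: List[VesselSegment] = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.absorption < 0):
            raise ValueError("absorption must be non-negative")
        if self.absorption.shape != self.labels.shape:
            raise ValueError("labels and absorption must share the grid")

    def to_sources(self, z_plane: Optional[float] = None) -> np.ndarray:
        """Voxelize lit voxels into point sources (x, y, z, radius, amp)."""
        zz, yy, xx = np.nonzero(self.absorption)
        amp = self.absorption[zz, yy, xx]
        x = self.grid.origin[2] + xx * self.grid.voxel_xy
        y = self.grid.origin[1] + yy * self.grid.voxel_xy
        z = (
            np.full_like(x, z_plane)
            if z_plane is not None
            else self.grid.origin[0] + zz * self.grid.voxel_z
        )
        r = np.full_like(x, self.grid.voxel_xy / 2.0)
        return np.stack([x, y, z, r, amp], axis=1)


def _stamp_segment(mask: np.ndarray, seg: VesselSegment, grid: GridSpec):
    """Paint a thick centreline into a 2D boolean mask (one z-slice)."""
    r_px = seg.radius / grid.voxel_xy
    # sample centreline at sub-pixel steps
    pts = []
    for p0, p1 in zip(seg.polyline[:-1], seg.polyline[1:]):
        n = max(2, int(np.ceil(np.linalg.norm(p1 - p0) / (grid.voxel_xy * 0.5))))
        t = np.linspace(0, 1, n)
        pts.append(p0[None] * (1 - t[:, None]) + p1[None] * t[:, None])
    pts = np.vstack(pts)
    rows, cols = grid.xy_to_index(pts[:, 0], pts[:, 1])
    ny, nx = mask.shape
    rad = int(np.ceil(r_px))
    dy, dx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    disc = dy**2 + dx**2 <= r_px**2 + 1e-6  # tolerate radius/pixel rounding
    offs = np.stack([dy[disc], dx[disc]], axis=1)
    rc = np.unique(
        np.stack([np.round(rows).astype(int), np.round(cols).astype(int)], axis=1),
        axis=0,
    )
    all_rc = rc[:, None, :] + offs[None, :, :]
    all_rc = all_rc.reshape(-1, 2)
    ok = (
        (all_rc[:, 0] >= 0)
        & (all_rc[:, 0] < ny)
        & (all_rc[:, 1] >= 0)
        & (all_rc[:, 1] < nx)
    )
    mask[all_rc[ok, 0], all_rc[ok, 1]] = True


def _segments_in_disc(segments, center, radius) -> int:
    """Count segments whose centreline comes within ``radius`` of ``center``."""
    c = np.asarray(center, float)
    n = 0
    for seg in segments:
        d = np.linalg.norm(_densify(seg.polyline) - c[None, :], axis=1)
        if d.min() <= radius:
            n += 1
    return n


def _densify(polyline: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Resample a polyline at ≤ ``step`` mm spacing."""
    pts = [polyline[:1]]
    for p0, p1 in zip(polyline[:-1], polyline[1:]):
        n = max(1, int(np.ceil(np.linalg.norm(p1 - p0) / step)))
        t = np.linspace(0, 1, n + 1)[1:]
        pts.append(p0[None] * (1 - t[:, None]) + p1[None] * t[:, None])
    return np.vstack(pts)


def _skeleton_window_counts(mask2d: np.ndarray, probes_rc, w: int = 20):
    """Distinct skeleton segments per w×w window at given (row, col) probes."""
    from .vessels import skeleton_segments

    segs = skeleton_segments(mask2d)
    lab = segs.label_image(mask2d.shape)
    lo = w // 2
    hi = w - lo
    ny, nx = mask2d.shape
    counts = []
    for r, c in probes_rc:
        win = lab[max(r - lo, 0) : r + hi, max(c - lo, 0) : c + hi]
        ids = np.unique(win)
        counts.append(int((ids > 0).sum()))
    return np.asarray(counts)


def _measured_window_density_at(mask2d, probes_rc, grid, pad: int, w: int = 20):
    """Measured density (segments/mm²) around a probe cluster, cropped."""
    probes = np.asarray(probes_rc)
    r0 = max(int(probes[:, 0].min()) - pad, 0)
    c0 = max(int(probes[:, 1].min()) - pad, 0)
    r1 = min(int(probes[:, 0].max()) + pad + 1, mask2d.shape[0])
    c1 = min(int(probes[:, 1].max()) + pad + 1, mask2d.shape[1])
    crop = mask2d[r0:r1, c0:c1]
    shifted = [(r - r0, c - c0) for r, c in probes_rc]
    counts = _skeleton_window_counts(crop, shifted, w)
    return float(counts.mean()) / (w * grid.voxel_xy) ** 2


def _measured_window_density(mask2d, rng, exclude, grid, n_probes: int = 96,
                             w: int = 20):
    """Measured background density at uniform probes outside the tumor."""
    ny, nx = mask2d.shape
    er, ec, erad = exclude
    probes = []
    for _ in range(20 * n_probes):
        r = int(rng.integers(w, ny - w))
        c = int(rng.integers(w, nx - w))
        if (r - er) ** 2 + (c - ec) ** 2 > erad**2:
            probes.append((r, c))
        if len(probes) >= n_probes:
            break
    counts = _skeleton_window_counts(mask2d, probes, w)
    return float(counts.mean()) / (w * grid.voxel_xy) ** 2


def _window_density(segments, centers: np.ndarray, half_window: float = 1.0):
    """Mean sliding-window vessel density (segments/mm²) at probe centres.

    A segment is counted at a centre when its centreline passes within
    ``half_window`` (the 2-mm window approximated as a disc).
    """
    if not segments or len(centers) == 0:
        return 0.0
    counts = np.zeros(len(centers))
    for seg in segments:
        pts = _densify(seg.polyline)
        d2 = (
            (centers[:, 0, None] - pts[None, :, 0]) ** 2
            + (centers[:, 1, None] - pts[None, :, 1]) ** 2
        )
        counts += (d2.min(axis=1) <= half_window**2).astype(float)
    return float(counts.mean()) / (2 * half_window) ** 2


def rasterize_phantom(
    tree: VesselTree,
    grid: GridSpec,
    tumor: Optional[TumorSpec] = None,
    vessel_absorption: float = 1.0,
    seed: int = 0,
) -> Phantom:
    """Rasterize a vessel tree (and optional tumor) onto a voxel grid.

    The tumor disc receives extra short vessel segments until its segment
    count per area is approximately ``density_multiplier`` times the
    background's, measured with same-size probe discs.
    """
    nz, ny, nx = grid.shape
    if tree.segments:
        (xmin, ymin), (xmax, ymax) = tree.bounding_box()
        x_lo, y_lo = grid.origin[2], grid.origin[1]
        x_hi = x_lo + (nx - 1) * grid.voxel_xy
        y_hi = y_lo + (ny - 1) * grid.voxel_xy
        if xmin < x_lo or ymin < y_lo or xmax > x_hi or ymax > y_hi:
            raise ValueError(
                "vessel tree extends outside the phantom grid "
                f"(tree bbox x [{xmin:.1f},{xmax:.1f}] y [{ymin:.1f},{ymax:.1f}])"
            )

    mask = np.zeros((ny, nx), dtype=bool)
    for seg in tree.segments:
        _stamp_segment(mask, seg, grid)

    rng = np.random.default_rng(seed)
    extra: List[VesselSegment] = []
    labels2d = np.zeros((ny, nx), dtype=np.int16)
    if tumor is not None:
        cx, cy = tumor.center
        # the tumor is planted by adding short segments until the *measured*
        # (rasterized → skeletonized) sliding-window density of the disc
        # reaches multiplier × background; calibrating on the measured
        # metric absorbs the merging losses of crowded vessel rasterization
        r_ct, c_ct = grid.xy_to_index(cx, cy)
        r_ct, c_ct = int(round(float(r_ct))), int(round(float(c_ct)))
        rad_px = int(round(tumor.radius / grid.voxel_xy))
        background = max(
            _measured_window_density(
                mask, rng, exclude=(r_ct, c_ct, 2 * rad_px), grid=grid
            ),
            0.05,
        )
        target = tumor.density_multiplier * background
        core = max(2, int(round(0.8 * rad_px)))
        probes_rc = [
            (r_ct + dr, c_ct + dc)
            for dr in range(-core, core + 1, max(1, core // 2))
            for dc in range(-core, core + 1, max(1, core // 2))
            if dr * dr + dc * dc <= core * core
        ]
        # extras must stay individually resolvable after band-limited
        # reconstruction: ≥ PSF-scale diameter and mutual spacing, else the
        # crowded disc reconstructs as speckle and vesselness filtering
        # cannot recover the planted contrast
        fill = 0.0
        disc_area = np.pi * tumor.radius**2
        midpoints = []
        for _ in range(60):
            current = _measured_window_density_at(
                mask, probes_rc, grid, pad=rad_px + 25
            )
            if current >= target or fill > 0.65:
                break
            added = 0
            for _ in range(40):
                if added >= 4:
                    break
                ang = rng.uniform(0, 2 * np.pi)
                rad = tumor.radius * np.sqrt(rng.uniform(0, 0.95))
                start = np.array(
                    [cx + rad * np.cos(ang), cy + rad * np.sin(ang)]
                )
                heading = rng.uniform(0, 2 * np.pi)
                length = rng.uniform(1.4, 2.4)
                end = start + length * np.array(
                    [np.cos(heading), np.sin(heading)]
                )
                mid = (start + end) / 2.0
                if midpoints and np.min(
                    np.linalg.norm(np.asarray(midpoints) - mid, axis=1)
                ) < 0.7:
                    continue
                seg = VesselSegment(np.array([start, end]), radius=0.15,
                                    level=-1)
                extra.append(seg)
                midpoints.append(mid)
                _stamp_segment(mask, seg, grid)
                fill += length * 2 * seg.radius / disc_area
                added += 1
            if added == 0:
                break
        yy, xx = np.mgrid[0:ny, 0:nx]
        xg, yg = grid.index_to_xy(yy, xx)
        in_tumor = (xg - cx) ** 2 + (yg - cy) ** 2 <= tumor.radius**2
        labels2d[in_tumor] = 2

    labels2d[mask] = 1
    absorption = np.zeros((nz, ny, nx), dtype=float)
    labels = np.zeros((nz, ny, nx), dtype=np.int16)
    stiffness = np.ones((nz, ny, nx), dtype=float)
    mid = nz // 2
    absorption[mid][mask] = vessel_absorption
    labels[mid] = labels2d
    if tumor is not None:
        stiffness[:, labels2d == 2] = tumor.stiffness_factor
        cx, cy = tumor.center
        yy, xx = np.mgrid[0:ny, 0:nx]
        xg, yg = grid.index_to_xy(yy, xx)
        in_tumor = (xg - cx) ** 2 + (yg - cy) ** 2 <= tumor.radius**2
        stiffness[:, in_tumor] = tumor.stiffness_factor
    return Phantom(
        absorption=absorption,
        stiffness=stiffness,
        labels=labels,
        grid=grid,
        tumor=tumor,
        extra_segments=extra,
    )
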