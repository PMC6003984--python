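"""Photoacoustic elastography: breathing-induced relative area changes.

Slow periodic compression deforms soft tissue more than stiff (tumorous)
tissue.  The pipeline: non-rigid (demons) registration of every frame to
the first; selection of stably registered pixels (small intensity STD
across registered frames), one per 2×2 mm square; Delaunay triangulation
over the selected pixels; per-triangle signed areas tracked through the
*original* (unregistered) frames via the displacement fields; per-triangle
spectral amplitude of the relative area change at the compression
frequency, painted into the triangle and averaged over many random
re-selections of the stable pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError
from skimage.draw import polygon

from .frames import FrameSequence

__all__ = [
    "DisplacementResult",
    "TriangleGrid",
    "DeformationMap",
    "register_nonrigid",
    "stable_triangulation",
    "deformation_map",
    "estimate_compression_frequency",
]


@dataclass
class DisplacementResult:
    """Dense per-frame displacement fields u with frame(x + u(x)) ≈ ref(x).

    ``fields[f]`` has shape (ny, nx, 2) ordered (dy, dx) in pixels.
    """

    fields: np.ndarray
    residuals: np.ndarray            # post-registration RMS error per frame
    initial_residuals: np.ndarray
    excluded: List[int]

    @property
    def n_frames(self) -> int:
        return self.fields.shape[0]


def register_nonrigid(
    frames: FrameSequence,
    iterations: int = 60,
    smoothing_sigma: float = 1.5,
) -> DisplacementResult:
    """Demons registration of every frame onto the first frame.

    Frames whose residual intensity error barely improves are flagged with
    a convergence warning and listed in ``excluded``.
    """
    data = frames.frames
    if data.shape[0] < 10:
        raise ValueError("need at least 10 frames for elastography")
    ref = data[0]
    fixed = sitk.GetImageFromArray(ref.astype(np.float64))
    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetNumberOfIterations(iterations)
    demons.SetStandardDeviations(smoothing_sigma)
    nf, ny, nx = data.shape
    fields = np.zeros((nf, ny, nx, 2))
    residuals = np.zeros(nf)
    init_res = np.zeros(nf)
    excluded: List[int] = []
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    for f in range(1, nf):
        moving = sitk.GetImageFromArray(data[f].astype(np.float64))
        disp = demons.Execute(fixed, moving)
        arr = sitk.GetArrayFromImage(disp)      # (ny, nx, 2) as (dx, dy)
        u = arr[..., ::-1]                      # -> (dy, dx)
        fields[f] = u
        warped = ndimage.map_coordinates(
            data[f], [yy + u[..., 0], xx + u[..., 1]], order=1, mode="nearest"
        )
        init_res[f] = float(np.sqrt(np.mean((data[f] - ref) ** 2)))
        residuals[f] = float(np.sqrt(np.mean((warped - ref) ** 2)))
        # a frame is unusable when the registered residual stays large both
        # in absolute terms (vs the reference contrast) and relative to the
        # initial mismatch
        scale = float(ref.std())
        if residuals[f] > 0.2 * scale and residuals[f] > 0.5 * init_res[f]:
            warnings.warn(
                f"demons registration of frame {f} did not converge "
                f"(residual {residuals[f]:.3g} vs initial {init_res[f]:.3g})",
                stacklevel=2,
            )
            excluded.append(f)
    return DisplacementResult(
        fields=fields,
        residuals=residuals,
        initial_residuals=init_res,
        excluded=excluded,
    )


@dataclass
class TriangleGrid:
    points: np.ndarray               # (P, 2) selected stable pixels (row, col)
    simplices: np.ndarray            # (T, 3) indices into points
    areas: np.ndarray                # (n_frames, T) signed areas (px²)
    candidates: List[np.ndarray]     # qualifying pixels per square
    pixel_size: float
    frame_rate: float
    shape: tuple
    displacement: DisplacementResult
    std_map: np.ndarray
    std_cutoff: float


def _vertex_positions(points: np.ndarray, fields: np.ndarray) -> np.ndarray:
    """(n_frames, P, 2) positions of reference points in each original frame."""
    nf = fields.shape[0]
    out = np.empty((nf, len(points), 2))
    r = points[:, 0].astype(int)
    c = points[:, 1].astype(int)
    for f in range(nf):
        out[f, :, 0] = points[:, 0] + fields[f][r, c, 0]
        out[f, :, 1] = points[:, 1] + fields[f][r, c, 1]
    return out


def _signed_areas(pos: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Shoelace signed area per triangle per frame; pos (nf, P, 2)."""
    a = pos[:, simplices[:, 0], :]
    b = pos[:, simplices[:, 1], :]
    c = pos[:, simplices[:, 2], :]
    return 0.5 * (
        (b[..., 1] - a[..., 1]) * (c[..., 0] - a[..., 0])
        - (c[..., 1] - a[..., 1]) * (b[..., 0] - a[..., 0])
    )


def _select_points(candidates: List[np.ndarray], rng) -> np.ndarray:
    pts = [cand[rng.integers(len(cand))] for cand in candidates if len(cand)]
    return np.asarray(pts, dtype=float)


def stable_triangulation(
    frames: FrameSequence,
    displacement: DisplacementResult,
    square_mm: float = 2.0,
    std_cutoff: Optional[float] = None,
    seed: int = 0,
) -> TriangleGrid:
    """Triangulate stably registered pixels, one per 2×2 mm square.

    Stability is judged by the per-pixel standard deviation of the
    registered intensities; the default cutoff is the 20th percentile of
    that distribution.  Squares with no qualifying pixel are skipped.
    """
    data = frames.frames
    nf, ny, nx = data.shape
    valid = [f for f in range(nf) if f not in displacement.excluded]
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    reg = np.empty((len(valid), ny, nx))
    for k, f in enumerate(valid):
        u = displacement.fields[f]
        reg[k] = ndimage.map_coordinates(
            data[f], [yy + u[..., 0], xx + u[..., 1]], order=1, mode="nearest"
        )
    std_map = reg.std(axis=0)
    if std_cutoff is None:
        std_cutoff = float(np.percentile(std_map, 20.0))
    w = max(2, int(round(square_mm / frames.pixel_size)))
    candidates: List[np.ndarray] = []
    for y0 in range(0, ny - w + 1, w):
        for x0 in range(0, nx - w + 1, w):
            block = std_map[y0 : y0 + w, x0 : x0 + w]
            ok = np.argwhere(block <= std_cutoff)
            candidates.append(
                ok + np.array([y0, x0]) if len(ok) else np.zeros((0, 2), int)
            )
    rng = np.random.default_rng(seed)
    points = _select_points(candidates, rng)
    if len(points) < 3:
        raise ValueError(
            "fewer than 3 stably registered pixels were selected; "
            "cannot triangulate"
        )
    tri = Delaunay(points)
    pos = _vertex_positions(points, displacement.fields)
    areas = _signed_areas(pos, tri.simplices)
    return TriangleGrid(
        points=points,
        simplices=tri.simplices,
        areas=areas,
        candidates=candidates,
        pixel_size=frames.pixel_size,
        frame_rate=frames.frame_rate,
        shape=(ny, nx),
        displacement=displacement,
        std_map=std_map,
        std_cutoff=std_cutoff,
    )


@dataclass
class DeformationMap:
    amplitude: np.ndarray            # per-pixel relative-area-change amplitude
    n_realizations: int
    compression_freq: float


def _band_amplitude(series: np.ndarray, frame_rate: float, freq: float):
    """Amplitude of the sinusoidal component at ``freq`` (Hann-windowed)."""
    nf = series.shape[0]
    win = np.hanning(nf)
    detr = (series - series.mean(axis=0)) * win[:, None]
    spec = np.fft.rfft(detr, axis=0)
    freqs = np.fft.rfftfreq(nf, d=1.0 / frame_rate)
    k = int(np.argmin(np.abs(freqs - freq)))
    return 2.0 * np.abs(spec[k]) / win.sum()


def deformation_map(
    grid: TriangleGrid,
    compression_freq: float,
    n_realizations: int = 100,
    seed: int = 0,
) -> DeformationMap:
    """Average deformation map over random stable-pixel re-selections.

    Per triangle the relative area series (area / temporal mean − 1) is
    Fourier-analysed at the compression frequency; the amplitude is
    painted into the triangle's pixels.  ``n_realizations`` independent
    re-draws of the stable pixels are averaged.
    """
    if compression_freq >= grid.frame_rate / 2:
        raise ValueError(
            f"compression frequency {compression_freq} Hz is at or above "
            f"Nyquist ({grid.frame_rate / 2} Hz)"
        )
    nf = grid.areas.shape[0]
    if nf / grid.frame_rate < 4.0 / compression_freq:
        warnings.warn(
            "record shorter than 4 compression periods; amplitude estimates "
            "will be coarse",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    acc = np.zeros(grid.shape)
    cnt = np.zeros(grid.shape)
    fields = grid.displacement.fields
    for _ in range(n_realizations):
        points = _select_points(grid.candidates, rng)
        if len(points) < 3:
            continue
        try:
            tri = Delaunay(points)
        except QhullError:
            continue
        pos = _vertex_positions(points, fields)
        areas = _signed_areas(pos, tri.simplices)
        mean_area = areas.mean(axis=0)
        good = np.abs(mean_area) > 1e-9
        rel = np.zeros_like(areas)
        rel[:, good] = areas[:, good] / mean_area[None, good] - 1.0
        amps = _band_amplitude(rel, grid.frame_rate, compression_freq)
        for t_idx in range(tri.simplices.shape[0]):
            if not good[t_idx]:
                continue
            verts = points[tri.simplices[t_idx]]
            rr, cc = polygon(verts[:, 0], verts[:, 1], shape=grid.shape)
            acc[rr, cc] += amps[t_idx]
            cnt[rr, cc] += 1.0
    out = np.where(cnt > 0, acc / np.maximum(cnt, 1.0), 0.0)
    return DeformationMap(
        amplitude=out,
        n_realizations=n_realizations,
        compression_freq=compression_freq,
    )


def estimate_compression_frequency(
    grid: TriangleGrid, band=(0.1, 0.5)
) -> float:
    """Breathing frequency from the global mean-area spectrum peak."""
    series = grid.areas.mean(axis=1)
    nf = len(series)
    win = np.hanning(nf)
    spec = np.abs(np.fft.rfft((series - series.mean()) * win))
    freqs = np.fft.rfftfreq(nf, d=1.0 / grid.frame_rate)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError("no spectral bins inside the search band")
    return float(freqs[sel][np.argmax(spec[sel])])
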