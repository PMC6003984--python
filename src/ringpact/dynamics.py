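"""Heartbeat-band artery mapping from 2D frame sequences.

Arteries pulsate with the cardiac cycle while veins do not, so per-pixel
spectral power inside the heartbeat band (1.0–1.6 Hz) separates the two.
Frames are first motion-screened (frames poorly correlated with the
reference are dropped), then rigidly registered within 16 slightly
overlapping subdomains, Gaussian-smoothed (0.2 mm radius), Fourier
transformed per pixel, and classified by band power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.registration import phase_cross_correlation

from .frames import FrameSequence

__all__ = [
    "DynamicsConfig",
    "ArteryVeinMap",
    "register_subdomains",
    "spectral_artery_map",
]


@dataclass
class DynamicsConfig:
    n_subdomains: int = 16                  # laid out on a square grid
    overlap: float = 0.25                   # linear subdomain overlap fraction
    smoothing_radius_mm: float = 0.2
    heart_band: Tuple[float, float] = (1.0, 1.6)
    motion_rejection_threshold: float = 0.85
    artery_k: float = 3.0                   # band power > k · median(vessels)
    estimate_rotation: bool = True
    rotation_search_deg: float = 1.0

    def validate(self, frame_rate: float):
        lo, hi = self.heart_band
        if not 0 < lo < hi:
            raise ValueError("heart_band must be an increasing positive interval")
        if hi >= frame_rate / 2:
            raise ValueError(
                f"heart band upper edge {hi} Hz is at or above Nyquist "
                f"({frame_rate / 2} Hz)"
            )


@dataclass
class ArteryVeinMap:
    band_power: np.ndarray
    artery_mask: np.ndarray
    heart_rate_hz: float
    vessel_mask: np.ndarray = None
    spectrum_freqs: np.ndarray = None
    band_spectrum: np.ndarray = None


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / den) if den > 0 else 0.0


def _subdomain_slices(shape, n_grid: int, overlap: float):
    """Overlapping tiles + triangular blending weights covering the frame."""
    ny, nx = shape
    tiles = []
    for gy in range(n_grid):
        for gx in range(n_grid):
            size_y = int(np.ceil(ny / (n_grid - (n_grid - 1) * overlap)))
            size_x = int(np.ceil(nx / (n_grid - (n_grid - 1) * overlap)))
            stride_y = (ny - size_y) / max(n_grid - 1, 1)
            stride_x = (nx - size_x) / max(n_grid - 1, 1)
            y0 = int(round(gy * stride_y))
            x0 = int(round(gx * stride_x))
            y1, x1 = min(y0 + size_y, ny), min(x0 + size_x, nx)
            wy = np.bartlett(y1 - y0 + 2)[1:-1]
            wx = np.bartlett(x1 - x0 + 2)[1:-1]
            tiles.append(((slice(y0, y1), slice(x0, x1)), np.outer(wy, wx)))
    return tiles


def _register_tile(ref_t, frame_t, cfg: DynamicsConfig):
    """Rigid (shift + optional small rotation) alignment of one tile."""
    shift, _, _ = phase_cross_correlation(ref_t, frame_t, upsample_factor=10)
    if np.abs(shift).max() < 0.3:
        # sub-resolution estimates are noise; shifting would only smear
        shift = np.zeros_like(shift)
        moved = frame_t
    else:
        moved = ndimage.shift(frame_t, shift, order=1, mode="nearest")
    best_ang = 0.0
    if cfg.estimate_rotation and _corr(ref_t, moved) < 0.995:
        best_c = _corr(ref_t, moved)
        for ang in np.linspace(
            -cfg.rotation_search_deg, cfg.rotation_search_deg, 5
        ):
            if ang == 0.0:
                continue
            cand = ndimage.rotate(moved, ang, reshape=False, order=1, mode="nearest")
            c = _corr(ref_t, cand)
            if c > best_c:
                best_c, best_ang = c, ang
        if best_ang != 0.0:
            moved = ndimage.rotate(
                moved, best_ang, reshape=False, order=1, mode="nearest"
            )
    return moved, shift, best_ang


def register_subdomains(
    frames: FrameSequence, config: Optional[DynamicsConfig] = None
):
    """Motion-screen and rigidly register a sequence subdomain by subdomain.

    Returns the registered sequence and a log with per-frame global
    correlations, rejected frame indices, and per-tile shifts.
    """
    config = config or DynamicsConfig()
    config.validate(frames.frame_rate)
    data = frames.frames
    if data.shape[0] < 20:
        raise ValueError("need at least 20 frames for dynamic registration")
    ref = data[0]
    corrs = np.array([_corr(ref, f) for f in data])
    keep = corrs >= config.motion_rejection_threshold
    keep[0] = True
    if keep.sum() < 10:
        raise ValueError(
            f"only {int(keep.sum())} frames survive motion rejection; "
            "need at least 10"
        )
    kept = data[keep]
    n_grid = int(round(np.sqrt(config.n_subdomains)))
    tiles = _subdomain_slices(ref.shape, n_grid, config.overlap)
    out = np.empty_like(kept)
    out[0] = kept[0]
    shifts = np.zeros((kept.shape[0], len(tiles), 2))
    angles = np.zeros((kept.shape[0], len(tiles)))
    for fi in range(1, kept.shape[0]):
        acc = np.zeros_like(ref)
        wacc = np.zeros_like(ref)
        for ti, (sl, w) in enumerate(tiles):
            moved, shift, ang = _register_tile(ref[sl], kept[fi][sl], config)
            acc[sl] += w * moved
            wacc[sl] += w
            shifts[fi, ti] = shift
            angles[fi, ti] = ang
        out[fi] = acc / np.maximum(wacc, 1e-12)
    registered = FrameSequence(
        frames=out,
        frame_rate=frames.frame_rate,
        pixel_size=frames.pixel_size,
        ground_truth=frames.ground_truth,
    )
    log = {
        "correlations": corrs,
        "kept": np.nonzero(keep)[0],
        "rejected": np.nonzero(~keep)[0],
        "shifts": shifts,
        "angles": angles,
    }
    return registered, log


def spectral_artery_map(
    frames: FrameSequence,
    config: Optional[DynamicsConfig] = None,
    vessel_mask: Optional[np.ndarray] = None,
) -> ArteryVeinMap:
    """Per-pixel heartbeat-band spectral power and artery classification.

    Each pixel's detrended, Hann-windowed time series is Fourier
    transformed; band power integrates spectral magnitude over the heart
    band.  Arteries are pixels whose band power exceeds ``artery_k`` times
    the median band power over vessel pixels.  The heart rate is the
    band-power-weighted spectral peak inside the band.
    """
    config = config or DynamicsConfig()
    config.validate(frames.frame_rate)
    if frames.duration < 5.0:
        warnings.warn(
            f"sequence of {frames.duration:.1f} s gives spectral resolution "
            f"coarser than 0.2 Hz",
            stacklevel=2,
        )
    data = frames.frames
    sigma_px = config.smoothing_radius_mm / frames.pixel_size
    if sigma_px > 0:
        data = np.stack([ndimage.gaussian_filter(f, sigma_px) for f in data])
    nf = data.shape[0]
    win = np.hanning(nf)
    detrended = (data - data.mean(axis=0)[None]) * win[:, None, None]
    spec = np.abs(np.fft.rfft(detrended, axis=0))
    freqs = np.fft.rfftfreq(nf, d=1.0 / frames.frame_rate)
    lo, hi = config.heart_band
    in_band = (freqs >= lo) & (freqs <= hi)
    band_power = spec[in_band].sum(axis=0)

    if vessel_mask is None:
        mean_img = frames.frames.mean(axis=0)
        try:
            vessel_mask = mean_img > threshold_otsu(mean_img)
        except ValueError:  # constant image
            vessel_mask = np.zeros(mean_img.shape, bool)
    vessel_mask = np.asarray(vessel_mask, bool)

    ref = (
        float(np.median(band_power[vessel_mask])) if vessel_mask.any() else 0.0
    )
    artery = vessel_mask & (band_power > config.artery_k * ref) if ref > 0 else (
        np.zeros_like(vessel_mask)
    )
    band_freqs = freqs[in_band]
    band_spectrum = (spec[in_band] * band_power[None]).sum(axis=(1, 2))
    heart_rate = float(band_freqs[np.argmax(band_spectrum)]) if in_band.any() else np.nan
    return ArteryVeinMap(
        band_power=band_power,
        artery_mask=artery,
        heart_rate_hz=heart_rate,
        vessel_mask=vessel_mask,
        spectrum_freqs=band_freqs,
        band_spectrum=band_spectrum,
    )
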