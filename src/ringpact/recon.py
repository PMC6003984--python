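"""Half-time universal back-projection (UBP) reconstruction in 2D and 3D.

The UBP integrand for each detector is

    b(t̄) = 2 p(t̄) − 2 t̄ · dp/dt(t̄),        t̄ = |r_voxel − r_element| / c,

summed over elements with solid-angle weights.  "Half time" truncates each
record to propagation distances no larger than the ring diameter — the
earliest portion of the data that still covers the imaging field of view —
which suppresses late-arriving reverberation artifacts.

In 3D mode the records of all elevational scan steps are back-projected
simultaneously; each contribution is weighted by the element's elevational
divergence profile evaluated at the voxel's elevational angle, and the
delay uses the full 3D distance.  Optionally the elevational geometry is
referenced to a virtual transducer at the Fresnel–Fraunhofer transition
depth L²/(4λ) in front of the physical element.

A radius-dependent anti-aliasing filter bank implements the spatial
Nyquist criterion of the 512-element ring: pixels at radius r only use
data low-passed to f_cut(r) = N·c/(4π·r), which leaves a ~39-mm-diameter
central zone unfiltered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .forward import Sinogram
from .geometry import ArrayGeometry, TransducerModel
from .phantom import GridSpec

__all__ = [
    "ReconConfig",
    "ImageVolume",
    "AntialiasBank",
    "antialias_lowpass",
    "reconstruct_2d",
    "reconstruct_3d",
    "measure_fwhm",
]


@dataclass
class ReconConfig:
    grid: GridSpec
    speed_of_sound: float = 1.5
    half_time: bool = True
    antialias: bool = False
    elevational_weight_fwhm: float = 9.0     # deg
    elevational_cutoff_factor: float = 2.0   # zero weight beyond factor×FWHM
    virtual_transducer: bool = False


@dataclass
class ImageVolume:
    values: np.ndarray
    grid: GridSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reconstructed volume contains non-finite values")


# ---------------------------------------------------------------------------
# UBP building blocks

def ubp_filtered(
    sino_step: np.ndarray,
    dt: float,
    half_time: bool,
    ring_radius: float,
    c: float,
) -> np.ndarray:
    """Per-channel UBP integrand b(t) = 2p − 2t·dp/dt (optionally half-time)."""
    p = sino_step
    if half_time:
        n_keep = int(np.floor(2.0 * ring_radius / (c * dt)))
        p = p.copy()
        p[:, min(n_keep, p.shape[1]):] = 0.0
    t = np.arange(p.shape[1]) * dt
    dp = np.gradient(p, dt, axis=1)
    return 2.0 * p - 2.0 * t[None, :] * dp


def _interp_channels(b_i: np.ndarray, tt: np.ndarray, dt: float) -> np.ndarray:
    """Linear interpolation of one channel at delays tt (µs); outside → 0."""
    nt = b_i.shape[0]
    s = tt / dt
    i0 = np.floor(s).astype(np.int64)
    frac = s - i0
    ok = (i0 >= 0) & (i0 < nt - 1)
    out = np.zeros(tt.shape)
    idx = i0[ok]
    out[ok] = b_i[idx] * (1.0 - frac[ok]) + b_i[idx + 1] * frac[ok]
    return out


def backproject_2d_points(
    b: np.ndarray,
    elems_xy: np.ndarray,
    pts_xy: np.ndarray,
    c: float,
    dt: float,
    z_offset: float = 0.0,
) -> np.ndarray:
    """Sum the UBP integrand over elements at arbitrary in-plane points.

    ``z_offset`` adds a fixed elevational offset to every element–point
    distance (used by the defocus-compensated sensitivity probe);
    0 gives the standard in-plane 2D reconstruction.

    Weights are the subtended-angle factors cos α / d normalized per pixel
    (uniform at the ring centre).
    """
    img = np.zeros(len(pts_xy))
    wsum = np.zeros(len(pts_xy))
    center = elems_xy.mean(axis=0)
    for i in range(len(elems_xy)):
        ex, ey = elems_xy[i]
        dx = pts_xy[:, 0] - ex
        dy = pts_xy[:, 1] - ey
        d2 = np.hypot(dx, dy)
        d = np.sqrt(d2**2 + z_offset**2)
        # inward normal of the element
        nvec = center - elems_xy[i]
        nvec = nvec / np.linalg.norm(nvec)
        cos_a = np.clip((dx * nvec[0] + dy * nvec[1]) / np.maximum(d2, 1e-9), 0, 1)
        w = cos_a / np.maximum(d2, 1e-9)
        img += w * _interp_channels(b[i], d / c, dt)
        wsum += w
    return img / np.maximum(wsum, 1e-30)


def reconstruct_2d(
    sinogram: Sinogram,
    config: ReconConfig,
    step: int = 0,
) -> ImageVolume:
    """2D half-time UBP of one elevational step onto the config grid."""
    grid = config.grid
    nz, ny, nx = grid.shape
    if nz != 1:
        raise ValueError("reconstruct_2d needs a 2D grid (nz == 1)")
    c = config.speed_of_sound
    dt = sinogram.transducer.dt
    geom = sinogram.geometry
    b = ubp_filtered(
        sinogram.data[step], dt, config.half_time, geom.ring_radius, c
    )
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    xg, yg = grid.index_to_xy(yy.ravel(), xx.ravel())
    pts = np.stack([xg, yg], axis=1)
    elems = geom.element_xy

    if config.antialias:
        bank = antialias_lowpass(sinogram, step=step, b_precomputed=b)
        img = np.zeros(len(pts))
        r = np.hypot(pts[:, 0], pts[:, 1])
        for lo, hi, f_cut, b_f in bank.bands:
            sel = (r >= lo) & (r < hi)
            if np.any(sel):
                img[sel] = backproject_2d_points(b_f, elems, pts[sel], c, dt)
    else:
        img = backproject_2d_points(b, elems, pts, c, dt)
    values = img.reshape(1, ny, nx)
    return ImageVolume(
        values=values,
        grid=grid,
        provenance={
            "mode": "2d",
            "half_time": config.half_time,
            "antialias": config.antialias,
            "speed_of_sound": c,
            "step": step,
        },
    )


def elevational_weight(theta, fwhm_deg: float, cutoff_factor: float):
    """Gaussian divergence weight vs elevational angle, hard cutoff."""
    fwhm = np.radians(fwhm_deg)
    s = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    w = np.exp(-np.asarray(theta) ** 2 / (2 * s**2))
    return np.where(np.abs(theta) > cutoff_factor * fwhm, 0.0, w)


def backproject_3d_points(
    sinogram: Sinogram,
    pts_xyz: np.ndarray,
    config: ReconConfig,
) -> np.ndarray:
    """3D UBP with elevational-divergence weighting at arbitrary voxels."""
    geom = sinogram.geometry
    tr = sinogram.transducer
    c = config.speed_of_sound
    dt = tr.dt
    steps = np.asarray(geom.elevational_positions, float)
    elems = geom.element_xy
    img = np.zeros(len(pts_xyz))
    wsum = np.zeros(len(pts_xyz))
    # virtual transducer: elevational geometry referenced to the
    # Fresnel–Fraunhofer transition depth in front of the element
    d_vt = 0.0
    if config.virtual_transducer:
        lam = c / tr.f_center
        d_vt = geom.element_height**2 / (4.0 * lam)
    for si, zs in enumerate(steps):
        b = ubp_filtered(
            sinogram.data[si], dt, config.half_time, geom.ring_radius, c
        )
        for i in range(geom.n_elements):
            ex, ey = elems[i]
            dx = pts_xyz[:, 0] - ex
            dy = pts_xyz[:, 1] - ey
            dz = pts_xyz[:, 2] - zs
            dxy = np.hypot(dx, dy)
            d = np.sqrt(dxy**2 + dz**2)
            theta = np.arctan2(dz, np.maximum(dxy - d_vt, 1e-6))
            w = elevational_weight(
                theta,
                config.elevational_weight_fwhm,
                config.elevational_cutoff_factor,
            ) / np.maximum(d, 1e-9)
            img += w * _interp_channels(b[i], d / c, dt)
            wsum += w
    return img / np.maximum(wsum, 1e-30)


def reconstruct_3d(sinogram: Sinogram, config: ReconConfig) -> ImageVolume:
    """3D UBP across all elevational steps onto the config grid."""
    if sinogram.n_steps < 2:
        raise ValueError(
            "3D reconstruction needs ≥ 2 elevational steps; "
            "use reconstruct_2d for single-step data"
        )
    grid = config.grid
    nz, ny, nx = grid.shape
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)
    xg, yg = grid.index_to_xy(yy.ravel(), xx.ravel())
    zg = grid.origin[0] + zz.ravel() * grid.voxel_z
    pts = np.stack([xg, yg, zg], axis=1)
    img = backproject_3d_points(sinogram, pts, config)
    return ImageVolume(
        values=img.reshape(nz, ny, nx),
        grid=grid,
        provenance={
            "mode": "3d",
            "half_time": config.half_time,
            "virtual_transducer": config.virtual_transducer,
            "elevational_weight_fwhm": config.elevational_weight_fwhm,
            "speed_of_sound": config.speed_of_sound,
        },
    )


# ---------------------------------------------------------------------------
# Radius-dependent anti-aliasing filter bank

@dataclass
class AntialiasBank:
    """Low-passed copies of the UBP integrand, one per radial zone.

    ``bands`` holds ``(r_lo, r_hi, f_cut, filtered_b)``; cutoffs are
    non-increasing with radius, and the innermost zone (f_cut ≥ band edge)
    keeps the data unfiltered.
    """

    bands: List[Tuple[float, float, float, np.ndarray]]
    sampling_rate: float

    def cutoff_at(self, r: float) -> float:
        for lo, hi, f_cut, _ in self.bands:
            if lo <= r < hi:
                return f_cut
        return self.bands[-1][2]


def nyquist_cutoff(r, n_elements: int, c: float):
    """Spatial-Nyquist cutoff frequency N·c/(4π·r) (MHz) at radius r (mm)."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(r > 0, n_elements * c / (4.0 * np.pi * r), np.inf)


def unaliased_fov_diameter(
    n_elements: int, c: float, band_edge: float
) -> float:
    """Diameter (mm) of the zone fully sampled up to the transducer band edge."""
    return 2.0 * n_elements * c / (4.0 * np.pi * band_edge)


def _lowpass_fft(b: np.ndarray, f_cut: float, fs: float) -> np.ndarray:
    """Zero-phase low-pass with a raised-cosine roll-off above f_cut."""
    nt = b.shape[-1]
    f = np.fft.rfftfreq(nt, d=1.0 / fs)
    roll = 0.15 * f_cut
    h = np.ones_like(f)
    h[f >= f_cut + roll] = 0.0
    mid = (f > f_cut - roll) & (f < f_cut + roll)
    h[mid] = 0.5 * (1 + np.cos(np.pi * (f[mid] - (f_cut - roll)) / (2 * roll)))
    return np.fft.irfft(np.fft.rfft(b, axis=-1) * h[None, :], n=nt, axis=-1)


def antialias_lowpass(
    sinogram: Sinogram,
    step: int = 0,
    n_bands: int = 8,
    r_max: Optional[float] = None,
    b_precomputed: Optional[np.ndarray] = None,
    half_time: bool = True,
) -> AntialiasBank:
    """Build the radius-dependent anti-aliasing filter bank for one step.

    Back-projection at radius r must only use temporal frequencies up to
    f_cut(r) = min(band_edge, N·c/(4π·r)); radii with f_cut at the band
    edge pass through unfiltered.
    """
    geom = sinogram.geometry
    tr = sinogram.transducer
    c = sinogram.speed_of_sound
    if r_max is None:
        r_max = geom.ring_radius
    if r_max < 0:
        raise ValueError("radius must be non-negative")
    band_edge = tr.band_edge
    r_free = unaliased_fov_diameter(geom.n_elements, c, band_edge) / 2.0
    b = (
        b_precomputed
        if b_precomputed is not None
        else ubp_filtered(
            sinogram.data[step], tr.dt, half_time, geom.ring_radius, c
        )
    )
    bands: List[Tuple[float, float, float, np.ndarray]] = []
    bands.append((0.0, min(r_free, r_max), band_edge, b))
    if r_max > r_free:
        edges = np.linspace(r_free, r_max, n_bands + 1)
        for lo, hi in zip(edges[:-1], edges[1:]):
            f_cut = float(nyquist_cutoff(hi, geom.n_elements, c))
            bands.append((lo, hi, f_cut, _lowpass_fft(b, f_cut, tr.sampling_rate)))
    # make the outermost band catch any residual radius
    lo, hi, f_cut, data = bands[-1]
    bands[-1] = (lo, np.inf, f_cut, data)
    return AntialiasBank(bands=bands, sampling_rate=tr.sampling_rate)


# ---------------------------------------------------------------------------

def measure_fwhm(profile, spacing: float) -> float:
    """Full width at half maximum of a 1D peak, linearly interpolated.

    The baseline is the median of the outer 10% of samples (both ends).
    Raises on flat profiles and on peaks touching the profile boundary.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or p.size < 3:
        raise ValueError("profile must be 1D with at least 3 samples")
    n_edge = max(1, int(round(0.05 * p.size)))
    baseline = float(np.median(np.concatenate([p[:n_edge], p[-n_edge:]])))
    q = p - baseline
    imax = int(np.argmax(q))
    peak = q[imax]
    if peak <= 0 or np.allclose(q, q[0]):
        raise ValueError("profile has no peak above the baseline")
    half = peak / 2.0
    i = imax
    while i > 0 and q[i] > half:
        i -= 1
    if q[i] > half:
        raise ValueError("peak touches the left boundary of the profile")
    xl = i + (half - q[i]) / (q[i + 1] - q[i])
    i = imax
    while i < p.size - 1 and q[i] > half:
        i += 1
    if q[i] > half:
        raise ValueError("peak touches the right boundary of the profile")
    xr = i - 1 + (q[i - 1] - half) / (q[i - 1] - q[i])
    return float((xr - xl) * spacing)
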