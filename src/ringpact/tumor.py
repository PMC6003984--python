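"""Vessel-density tumor segmentation and the density-ratio ROC analysis.

Tumors recruit vasculature (angiogenesis), so they appear as regions of
elevated vessel density.  Density is the number of independent vessel
segments intersecting a sliding 2×2 mm window divided by the window area;
whole-breast statistics are taken inside a 10-cm-diameter support circle.
Suspicious regions exceed mean + k·SD (k = 2.0), and contiguous regions
smaller than 1855 pixels (18.55 mm² at 0.1 mm pixels) are rejected.  A
per-breast density ratio (high-density region mean over normal region
mean) feeds a threshold-sweep ROC over affected vs contralateral breasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .vessels import SegmentSet

__all__ = [
    "DensityMap",
    "TumorRegion",
    "TumorSegmentation",
    "RocResult",
    "vessel_density_map",
    "segment_tumors",
    "density_ratio_and_roc",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class DensityMap:
    density: np.ndarray              # segments per mm²
    window_mm: float
    pixel_size: float
    support_mask: np.ndarray
    mean: float
    sd: float


@dataclass
class TumorRegion:
    label: int
    n_pixels: int
    centroid: Tuple[float, float]    # (row, col)
    longest_dimension_mm: float


@dataclass
class TumorSegmentation:
    labels: np.ndarray
    regions: List[TumorRegion]
    threshold: float
    k_sigma: float
    min_pixels: int


def vessel_density_map(
    segments: SegmentSet,
    image_shape: Tuple[int, int],
    window_mm: float = 2.0,
    pixel_size: float = 0.1,
    support_diameter_mm: float = 100.0,
) -> DensityMap:
    """Sliding-window vessel density (segments per mm²).

    A window of ``window_mm`` square is centred on every pixel; the count
    of distinct segments intersecting it is divided by the window area.
    The window of width w px spans offsets [−w//2, w − w//2) around the
    centre pixel.
    """
    ny, nx = image_shape
    w = max(1, int(round(window_mm / pixel_size)))
    counts = np.zeros((ny, nx))
    margin = w + 1
    for seg in segments.segments:
        r0, c0 = seg.min(axis=0) - margin
        r1, c1 = seg.max(axis=0) + margin
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1 + 1, ny), min(c1 + 1, nx)
        sub = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        sub[seg[:, 0] - r0, seg[:, 1] - c0] = True
        hit = ndimage.maximum_filter(sub.astype(np.uint8), size=w) > 0
        counts[r0:r1, c0:c1] += hit
    density = counts / (window_mm**2)
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_px = (support_diameter_mm / 2.0) / pixel_size
    support = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    vals = density[support]
    return DensityMap(
        density=density,
        window_mm=window_mm,
        pixel_size=pixel_size,
        support_mask=support,
        mean=float(vals.mean()) if vals.size else 0.0,
        sd=float(vals.std()) if vals.size else 0.0,
    )


def _longest_dimension(mask: np.ndarray, pixel_size: float) -> float:
    pts = np.argwhere(mask).astype(float)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()) * pixel_size)


def segment_tumors(
    density_map: DensityMap,
    k_sigma: float = 2.0,
    min_pixels: int = 1855,
) -> TumorSegmentation:
    """Threshold the density map at mean + k·SD and reject small regions.

    Regions are 8-connected components; components with fewer than
    ``min_pixels`` pixels are removed.  The longest dimension is the
    maximum pairwise pixel distance × pixel size.
    """
    if density_map.sd == 0.0:
        warnings.warn(
            "density map has zero variance over the support; no regions "
            "can exceed the threshold",
            stacklevel=2,
        )
        return TumorSegmentation(
            labels=np.zeros_like(density_map.density, dtype=np.int32),
            regions=[],
            threshold=density_map.mean,
            k_sigma=k_sigma,
            min_pixels=min_pixels,
        )
    threshold = density_map.mean + k_sigma * density_map.sd
    above = (density_map.density > threshold) & density_map.support_mask
    lab, n = ndimage.label(above, structure=_EIGHT)
    out = np.zeros_like(lab, dtype=np.int32)
    regions: List[TumorRegion] = []
    next_label = 0
    for i in range(1, n + 1):
        m = lab == i
        n_px = int(m.sum())
        if n_px < min_pixels:
            continue
        next_label += 1
        out[m] = next_label
        cy, cx = ndimage.center_of_mass(m)
        regions.append(
            TumorRegion(
                label=next_label,
                n_pixels=n_px,
                centroid=(float(cy), float(cx)),
                longest_dimension_mm=_longest_dimension(
                    m, density_map.pixel_size
                ),
            )
        )
    regions.sort(key=lambda r: -r.n_pixels)
    return TumorSegmentation(
        labels=out,
        regions=regions,
        threshold=float(threshold),
        k_sigma=k_sigma,
        min_pixels=min_pixels,
    )


@dataclass
class RocResult:
    ratios: Dict[float, np.ndarray]      # k_sigma -> per-breast density ratio
    labels: np.ndarray                   # 1 affected, 0 contralateral
    thresholds: np.ndarray
    sensitivity: Dict[float, np.ndarray]
    specificity: Dict[float, np.ndarray]
    auc: Dict[float, float]
    optimal_threshold: Dict[float, Tuple[float, float]]
    excluded: Dict[float, List[int]]


def density_ratio(density_map: DensityMap, k_sigma: float) -> float:
    """High-density-region mean over normal-region mean for one breast."""
    thr = density_map.mean + k_sigma * density_map.sd
    sup = density_map.support_mask
    high = (density_map.density > thr) & sup
    normal = sup & ~high
    if not high.any():
        raise ValueError("high-density region is empty")
    lo = density_map.density[normal].mean()
    if lo <= 0:
        raise ValueError("normal-density region has zero mean density")
    return float(density_map.density[high].mean() / lo)


def _sweep_roc(ratios, labels, thresholds):
    pos = labels == 1
    neg = ~pos
    sens = np.array([(ratios[pos] >= t).mean() for t in thresholds])
    spec = np.array([(ratios[neg] < t).mean() for t in thresholds])
    return sens, spec


def _trapezoid_auc(ratios, labels, thresholds):
    """Trapezoidal AUC over the sweep, refined with midpoints between
    consecutive distinct ratios so that tie-free data reproduce the
    Mann–Whitney statistic exactly."""
    uniq = np.unique(ratios)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    grid = np.unique(
        np.concatenate(
            [thresholds, mids, [uniq.min() - 1.0, uniq.max() + 1.0]]
        )
    )
    # descending threshold order makes both FPR and TPR non-decreasing
    sens, spec = _sweep_roc(ratios, labels, grid[::-1])
    x = np.concatenate([[0.0], 1.0 - spec, [1.0]])
    y = np.concatenate([[0.0], sens, [1.0]])
    return float(np.trapezoid(y, x))


def density_ratio_and_roc(
    density_maps: Sequence[DensityMap],
    labels: Sequence[int],
    k_sigma_options: Sequence[float] = (1.5, 2.0, 2.5),
    threshold_range: Tuple[float, float] = (1.0, 6.0),
    threshold_step: float = 0.01,
) -> RocResult:
    """Density-ratio ROC over affected vs contralateral breasts.

    For each ``k_sigma`` the per-breast ratio is computed, the decision
    threshold is swept over ``threshold_range``, and the AUC is obtained
    by trapezoidal integration of the resulting ROC curve.
    """
    labels = np.asarray(labels, dtype=int)
    if len(density_maps) != len(labels) or len(labels) < 2:
        raise ValueError("need ≥ 2 breasts with matching labels")
    if not (labels == 1).any() or not (labels == 0).any():
        raise ValueError("need at least one affected and one contralateral breast")
    thresholds = np.arange(
        threshold_range[0], threshold_range[1] + threshold_step / 2, threshold_step
    )
    ratios_k, sens_k, spec_k, auc_k, opt_k, exc_k = {}, {}, {}, {}, {}, {}
    for k in k_sigma_options:
        vals, keep = [], []
        for i, dm in enumerate(density_maps):
            try:
                vals.append(density_ratio(dm, k))
                keep.append(i)
            except ValueError as e:
                warnings.warn(
                    f"breast {i} excluded at k={k}: {e}", stacklevel=2
                )
        r = np.asarray(vals)
        lab = labels[keep]
        sens, spec = _sweep_roc(r, lab, thresholds)
        auc = _trapezoid_auc(r, lab, thresholds)
        youden = sens + spec - 1.0
        best = youden == youden.max()
        opt = (float(thresholds[best].min()), float(thresholds[best].max()))
        ratios_k[k] = r
        sens_k[k] = sens
        spec_k[k] = spec
        auc_k[k] = auc
        opt_k[k] = opt
        exc_k[k] = [i for i in range(len(density_maps)) if i not in keep]
    return RocResult(
        ratios=ratios_k,
        labels=labels,
        thresholds=thresholds,
        sensitivity=sens_k,
        specificity=spec_k,
        auc=auc_k,
        optimal_threshold=opt_k,
        excluded=exc_k,
    )
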