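"""Synthetic branching vessel trees with a planted junction exponent.

At every bifurcation the daughter diameters are solved exactly from the
planted diameter law

    D_parent^X = D_daughter_a^X + D_daughter_b^X,

with a fixed asymmetry ratio γ = D_b/D_a, so that downstream morphometry
(junction-exponent recovery) has a known ground truth.  X = 3 is Murray's
law (minimum-work arterial branching); measured human breast vasculature
sits somewhat below 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

__all__ = ["VesselSegment", "VesselTree", "generate_vessel_tree", "fit_to_box"]


@dataclass
class VesselSegment:
    """One junction-free vessel: centreline polyline (K, 2) in mm + radius."""

    polyline: np.ndarray
    radius: float
    level: int


@dataclass
class VesselTree:
    segments: List[VesselSegment]
    bifurcations: List[Tuple[int, int, int]]  # (parent, daughter_a, daughter_b)
    root_diameter: float
    n_levels: int
    junction_exponent: float
    asymmetry: float
    seed: int

    def bounding_box(self):
        """((xmin, ymin), (xmax, ymax)) over all centrelines, radius-padded."""
        if not self.segments:
            return (0.0, 0.0), (0.0, 0.0)
        pts = np.vstack([s.polyline for s in self.segments])
        pad = max(s.radius for s in self.segments)
        return tuple(pts.min(axis=0) - pad), tuple(pts.max(axis=0) + pad)

    def bifurcation_diameters(self):
        """(D_parent, D_a, D_b) in mm for every bifurcation."""
        out = []
        for p, a, b in self.bifurcations:
            out.append(
                (
                    2 * self.segments[p].radius,
                    2 * self.segments[a].radius,
                    2 * self.segments[b].radius,
                )
            )
        return out


def _daughter_diameters(d_parent: float, x: float, gamma: float):
    """Solve D_p^X = D_a^X + D_b^X with D_b = γ·D_a exactly."""
    d_a = d_parent / (1.0 + gamma**x) ** (1.0 / x)
    return d_a, gamma * d_a


def _wiggled_polyline(rng, start, direction, length, n_nodes=4, wiggle_deg=6.0):
    """Gently curved centreline: heading receives small seeded perturbations."""
    pts = [np.asarray(start, dtype=float)]
    heading = np.arctan2(direction[1], direction[0])
    step = length / (n_nodes - 1)
    for _ in range(n_nodes - 1):
        heading += np.radians(rng.normal(0.0, wiggle_deg))
        pts.append(pts[-1] + step * np.array([np.cos(heading), np.sin(heading)]))
    return np.array(pts)


def fit_to_box(tree: VesselTree, lo, hi, margin: float = 0.5) -> VesselTree:
    """Scale and translate a tree's centrelines to fit inside a box.

    Coordinates are scaled uniformly about the tree centre; radii are left
    untouched, so the planted diameter law is preserved exactly.
    """
    if not tree.segments:
        return tree
    (xmin, ymin), (xmax, ymax) = tree.bounding_box()
    lo = np.asarray(lo, float) + margin
    hi = np.asarray(hi, float) - margin
    span = np.array([xmax - xmin, ymax - ymin])
    avail = hi - lo
    s = float(min(1.0, np.min(np.where(span > 0, avail / span, 1.0))))
    center = np.array([(xmin + xmax) / 2.0, (ymin + ymax) / 2.0])
    target = (lo + hi) / 2.0
    segments = [
        VesselSegment((seg.polyline - center) * s + target, seg.radius, seg.level)
        for seg in tree.segments
    ]
    return VesselTree(
        segments=segments,
        bifurcations=list(tree.bifurcations),
        root_diameter=tree.root_diameter,
        n_levels=tree.n_levels,
        junction_exponent=tree.junction_exponent,
        asymmetry=tree.asymmetry,
        seed=tree.seed,
    )


def generate_vessel_tree(
    seed: int,
    n_levels: int = 4,
    root_diameter: float = 1.5,
    junction_exponent: float = 2.63,
    asymmetry: float = 0.8,
    root_position=(0.0, 0.0),
    root_direction=(1.0, 0.0),
    length_factor: float = 7.0,
    branch_angle_deg: Tuple[float, float] = (20.0, 40.0),
) -> VesselTree:
    """Grow a seeded binary vessel tree with ``n_levels`` bifurcation levels.

    Segment lengths scale with diameter (``length_factor`` × D); daughter
    headings deviate from the parent by a seeded angle in ``branch_angle_deg``,
    the slimmer daughter taking the larger deviation.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be ≥ 1")
    if not 0.2 < root_diameter < 5.0:
        raise ValueError("root_diameter must be in (0.2, 5.0) mm")
    if not 1.5 < junction_exponent < 4.0:
        raise ValueError("junction_exponent must be in (1.5, 4.0)")
    if not 0.0 < asymmetry <= 1.0:
        raise ValueError("asymmetry must be in (0, 1]")

    rng = np.random.default_rng(seed)
    segments: List[VesselSegment] = []
    bifurcations: List[Tuple[int, int, int]] = []

    def grow(start, direction, diameter, level):
        poly = _wiggled_polyline(
            rng, start, direction, length_factor * diameter
        )
        idx = len(segments)
        segments.append(VesselSegment(poly, diameter / 2.0, level))
        if level < n_levels:
            d_a, d_b = _daughter_diameters(
                diameter, junction_exponent, asymmetry
            )
            end = poly[-1]
            heading = np.arctan2(
                poly[-1, 1] - poly[-2, 1], poly[-1, 0] - poly[-2, 0]
            )
            ang_a = np.radians(rng.uniform(*branch_angle_deg))
            ang_b = np.radians(rng.uniform(*branch_angle_deg))
            side = rng.choice([-1.0, 1.0])
            ia = grow(
                end,
                (np.cos(heading + side * ang_a), np.sin(heading + side * ang_a)),
                d_a,
                level + 1,
            )
            ib = grow(
                end,
                (np.cos(heading - side * ang_b), np.sin(heading - side * ang_b)),
                d_b,
                level + 1,
            )
            bifurcations.append((idx, ia, ib))
        return idx

    grow(np.asarray(root_position, float), np.asarray(root_direction, float),
         root_diameter, 0)
    return VesselTree(
        segments=segments,
        bifurcations=bifurcations,
        root_diameter=root_diameter,
        n_levels=n_levels,
        junction_exponent=junction_exponent,
        asymmetry=asymmetry,
        seed=seed,
    )
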