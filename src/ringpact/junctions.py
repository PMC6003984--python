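"""Bifurcation morphometry: junction exponent and cube-ratio.

At a vascular bifurcation with parent diameter D_p and daughter diameters
D_a, D_b, the junction exponent X_B is the root of

    D_p^X = D_a^X + D_b^X,

solved here by bisection.  X_B = 3 corresponds to Murray's minimum-work
law, for which the cube-ratio

    R_B = D_p³ / (D_a³ + D_b³)

equals exactly 1.  Ageing and disease shift X_B below 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Bifurcation", "junction_metrics", "JunctionError"]

_X_LO, _X_HI = 0.5, 10.0
_TOL = 1e-9


class JunctionError(ValueError):
    """Raised when the junction equation has no solution for the inputs."""


@dataclass(frozen=True)
class Bifurcation:
    d_parent: float
    d_daughter_a: float
    d_daughter_b: float
    x_b: float
    r_b: float


def _residual(x: float, ra: float, rb: float) -> float:
    """g(X) = (D_a/D_p)^X + (D_b/D_p)^X − 1; strictly decreasing in X."""
    return ra**x + rb**x - 1.0


def junction_metrics(
    d_parent: float, d_daughter_a: float, d_daughter_b: float
) -> Bifurcation:
    """Solve the junction exponent by bisection and compute the cube-ratio.

    Requires strictly positive diameters with the parent larger than both
    daughters; otherwise the junction equation has no positive solution.
    """
    dp, da, db = float(d_parent), float(d_daughter_a), float(d_daughter_b)
    if dp <= 0 or da <= 0 or db <= 0:
        raise JunctionError("diameters must be positive")
    if dp <= max(da, db):
        raise JunctionError(
            "no junction exponent exists: parent diameter must exceed both "
            f"daughters (got parent {dp}, daughters {da}, {db})"
        )
    ra, rb = da / dp, db / dp
    lo, hi = _X_LO, _X_HI
    g_lo, g_hi = _residual(lo, ra, rb), _residual(hi, ra, rb)
    if g_lo < 0 or g_hi > 0:
        raise JunctionError(
            f"junction exponent falls outside the solver range [{_X_LO}, {_X_HI}]"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        g = _residual(mid, ra, rb)
        if abs(g) < _TOL:
            lo = hi = mid
            break
        if g > 0:
            lo = mid
        else:
            hi = mid
    x = 0.5 * (lo + hi)
    r_b = dp**3 / (da**3 + db**3)
    return Bifurcation(dp, da, db, float(x), float(r_b))
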