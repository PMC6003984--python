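"""Ring-array geometry and transducer-element model.

The imaging hardware modelled here is a full-ring ultrasonic transducer
array (512 elements on a 220-mm-diameter circle) of flat-rectangular
elements, 5 mm tall in the elevational direction, with a 2.25 MHz central
frequency and ~95% one-way fractional bandwidth, sampled at 40 MHz for
100 µs per laser pulse.  The ring lies in the horizontal (x, y) plane and
can be stepped along the elevational axis z to scan a volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = ["ArrayGeometry", "TransducerModel"]


@dataclass(frozen=True)
class ArrayGeometry:
    """Full-ring array geometry. Lengths in mm; angles uniform on the ring."""

    ring_radius: float = 110.0
    n_elements: int = 512
    element_height: float = 5.0
    element_pitch: float = 1.35
    elevational_positions: tuple = (0.0,)

    def __post_init__(self):
        if self.ring_radius <= 0 or self.n_elements < 1:
            raise ValueError("ring_radius and n_elements must be positive")
        circumference = 2 * np.pi * self.ring_radius
        # ε absorbs the rounding of the nominal 1.35-mm pitch (512 × 1.35
        # = 691.20 mm vs 2π·110 = 691.15 mm)
        if self.n_elements * self.element_pitch > circumference + 0.5:
            raise ValueError(
                f"{self.n_elements} elements at {self.element_pitch} mm pitch "
                f"exceed the ring circumference {circumference:.1f} mm"
            )
        z = np.asarray(self.elevational_positions, dtype=float)
        if z.ndim != 1 or z.size < 1 or np.any(np.diff(z) <= 0) and z.size > 1:
            raise ValueError("elevational_positions must be strictly increasing")

    @property
    def element_angles(self) -> np.ndarray:
        """Angular position of each element centre (rad)."""
        return 2 * np.pi * np.arange(self.n_elements) / self.n_elements

    @property
    def element_xy(self) -> np.ndarray:
        """(n_elements, 2) element centres in the imaging plane (mm)."""
        a = self.element_angles
        return np.stack(
            [self.ring_radius * np.cos(a), self.ring_radius * np.sin(a)], axis=1
        )

    def with_elevations(self, positions) -> "ArrayGeometry":
        return ArrayGeometry(
            ring_radius=self.ring_radius,
            n_elements=self.n_elements,
            element_height=self.element_height,
            element_pitch=self.element_pitch,
            elevational_positions=tuple(float(p) for p in positions),
        )


@dataclass(frozen=True)
class TransducerModel:
    """Element frequency response and sampling parameters.

    The impulse response is a Gaussian-envelope band-pass at ``f_center``
    whose −6 dB one-way fractional bandwidth is
    ``fractional_bandwidth_oneway``.  The elevational divergence of the
    5-mm-tall element follows the far-field pattern of a uniform line
    aperture; :meth:`divergence_fwhm_deg` solves that pattern for its full
    width at half maximum (≈9.0° for the defaults in water).
    """

    f_center: float = 2.25            # MHz
    fractional_bandwidth_oneway: float = 0.95
    sampling_rate: float = 40.0       # MHz
    record_length: float = 100.0      # µs
    element_height: float = 5.0       # mm (duplicated from geometry for directivity)

    def __post_init__(self):
        if not 0 < self.fractional_bandwidth_oneway < 2:
            raise ValueError("fractional bandwidth must be in (0, 2)")
        if self.f_center <= 0 or self.sampling_rate <= 0 or self.record_length <= 0:
            raise ValueError("frequencies and record length must be positive")

    @property
    def n_samples(self) -> int:
        """Record samples per channel (4000 for the defaults)."""
        return int(round(self.sampling_rate * self.record_length))

    @property
    def dt(self) -> float:
        """Sample interval (µs)."""
        return 1.0 / self.sampling_rate

    @property
    def bandwidth(self) -> float:
        """Absolute −6 dB one-way bandwidth (MHz)."""
        return self.fractional_bandwidth_oneway * self.f_center

    @property
    def sigma_f(self) -> float:
        """Gaussian spectral width (MHz) matching the −6 dB bandwidth."""
        return self.bandwidth / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    @property
    def sigma_t(self) -> float:
        """Gaussian temporal envelope width (µs)."""
        return 1.0 / (2.0 * np.pi * self.sigma_f)

    @property
    def band_edge(self) -> float:
        """Upper edge of the pass band (MHz), f_center + BW/2 (≈3.32 MHz)."""
        return self.f_center + self.bandwidth / 2.0

    def impulse_response(self, t):
        """Band-pass impulse response h(t), t in µs, unit peak."""
        t = np.asarray(t, dtype=float)
        return np.exp(-(t**2) / (2 * self.sigma_t**2)) * np.cos(
            2 * np.pi * self.f_center * t
        )

    def impulse_response_derivative(self, t):
        """dh/dt analytically (µs⁻¹ units)."""
        t = np.asarray(t, dtype=float)
        env = np.exp(-(t**2) / (2 * self.sigma_t**2))
        w0 = 2 * np.pi * self.f_center
        return env * (-(t / self.sigma_t**2) * np.cos(w0 * t) - w0 * np.sin(w0 * t))

    def directivity(self, theta, speed_of_sound: float = 1.5):
        """One-way far-field amplitude of the line aperture at ``f_center``.

        ``theta`` is the elevational angle (rad) off the imaging plane.
        """
        lam = speed_of_sound / self.f_center
        x = self.element_height * np.sin(np.asarray(theta, dtype=float)) / lam
        return np.sinc(x)

    def divergence_fwhm_deg(self, speed_of_sound: float = 1.5) -> float:
        """FWHM (deg) of the elevational far-field directivity pattern."""
        f = lambda th: self.directivity(th, speed_of_sound) - 0.5
        half = brentq(f, 1e-9, np.pi / 2 - 1e-9)
        return float(2 * np.degrees(half))
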