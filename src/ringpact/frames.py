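"""Dynamic 2D frame sequences: cardiac-band pulsation and slow compression.

Two dynamic regimes are emulated at the system's 10-Hz 2D frame rate:

* ``pulsation`` — pixels inside an artery mask oscillate sinusoidally at a
  cardiac frequency (1.0–1.6 Hz band) with a fractional amplitude, the
  contrast used to separate arteries from veins.
* ``compression`` — the whole field dilates in-plane at a slow breathing
  frequency (~0.25 Hz); inside a stiff inclusion the local dilation is
  scaled by its relative compliance, which is what elastography recovers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = ["FrameSequence", "generate_dynamic_frames"]


@dataclass
class FrameSequence:
    frames: np.ndarray          # (n_frames, ny, nx)
    frame_rate: float = 10.0    # Hz
    pixel_size: float = 0.1     # mm
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        f = np.asarray(self.frames, dtype=float)
        if f.ndim != 3:
            raise ValueError("frames must be (n_frames, ny, nx)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        self.frames = f

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


def generate_dynamic_frames(
    base_image: np.ndarray,
    mode: str,
    target_mask: Optional[np.ndarray] = None,
    frequency: float = 1.2,
    amplitude: float = 0.1,
    n_frames: int = 100,
    frame_rate: float = 10.0,
    jitter: float = 0.0,
    noise_sd: float = 0.0,
    stiffness: Optional[np.ndarray] = None,
    pixel_size: float = 0.1,
    seed: Optional[int] = None,
) -> FrameSequence:
    """Generate a seeded dynamic sequence from a static base image.

    Parameters
    ----------
    mode
        ``"pulsation"``: pixels in ``target_mask`` oscillate at ``frequency``
        with fractional ``amplitude``; ``"compression"``: the frame dilates
        in-plane at ``frequency`` with peak relative area change
        ``amplitude``, scaled locally by the ``stiffness`` compliance map
        (1 = background).
    jitter
        Standard deviation (px) of per-frame rigid translations.
    noise_sd
        Additive white Gaussian noise per pixel per frame.
    """
    if frequency >= frame_rate / 2:
        raise ValueError(
            f"frequency {frequency} Hz is at or above Nyquist "
            f"({frame_rate / 2} Hz)"
        )
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    base = np.asarray(base_image, dtype=float)
    ny, nx = base.shape
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / frame_rate
    phase = np.sin(2 * np.pi * frequency * t)

    frames = np.empty((n_frames, ny, nx))
    if mode == "pulsation":
        if target_mask is None:
            raise ValueError("pulsation mode requires a target_mask")
        mask = np.asarray(target_mask, dtype=bool)
        for i in range(n_frames):
            frames[i] = base * (1.0 + amplitude * phase[i] * mask)
    elif mode == "compression":
        s = (
            np.ones_like(base)
            if stiffness is None
            else np.asarray(stiffness, dtype=float)
        )
        # displacement with local divergence = amplitude·phase·s(x, y):
        # separable half-strain integrals from the image centre
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        ix = np.cumsum(s, axis=1)
        ix = 0.5 * (ix - ix[:, int(round(cx))][:, None])
        iy = np.cumsum(s, axis=0)
        iy = 0.5 * (iy - iy[int(round(cy))][None, :])
        yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
        for i in range(n_frames):
            a = amplitude * phase[i]
            coords = np.stack([yy - a * iy, xx - a * ix])
            frames[i] = ndimage.map_coordinates(
                base, coords, order=1, mode="nearest"
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if jitter > 0:
        for i in range(n_frames):
            dy, dx = rng.normal(0.0, jitter, size=2)
            frames[i] = ndimage.shift(frames[i], (dy, dx), order=1, mode="nearest")
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)

    gt = {
        "mode": mode,
        "frequency": frequency,
        "amplitude": amplitude,
    }
    if target_mask is not None:
        gt["target_mask"] = np.asarray(target_mask, dtype=bool)
    if stiffness is not None:
        gt["stiffness"] = np.asarray(stiffness, dtype=float)
    return FrameSequence(
        frames=frames,
        frame_rate=frame_rate,
        pixel_size=pixel_size,
        ground_truth=gt,
    )
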