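"""File formats: HDF5 sinograms, TIFF+JSON frame sequences, NIfTI volumes.

Sinograms are stored as HDF5 with dataset ``/data`` shaped
``[steps, elements, samples]`` (float32) plus scalar attributes carrying
geometry and sampling metadata.  Image volumes go to NIfTI (voxel sizes in
the header) and/or float32 multi-page TIFF; frame sequences to multi-page
TIFF with a JSON sidecar; tables to CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .forward import Sinogram
from .frames import FrameSequence
from .geometry import ArrayGeometry, TransducerModel
from .phantom import GridSpec
from .recon import ImageVolume

__all__ = [
    "FormatError",
    "write_sinogram",
    "read_sinogram",
    "write_frames",
    "read_frames",
    "write_volume_nifti",
    "write_volume_tiff",
    "write_mask_tiff",
    "write_float_tiff",
    "segments_to_csv",
    "bifurcations_to_csv",
]

_REQUIRED_ATTRS = (
    "sampling_rate_mhz",
    "speed_of_sound_mm_per_us",
    "ring_radius_mm",
    "n_elements",
    "element_height_mm",
    "elevational_positions_mm",
)


class FormatError(ValueError):
    """A file does not conform to the expected container layout."""


def write_sinogram(path: Union[str, Path], sino: Sinogram) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=sino.data.astype(np.float32))
        f.attrs["sampling_rate_mhz"] = sino.transducer.sampling_rate
        f.attrs["speed_of_sound_mm_per_us"] = sino.speed_of_sound
        f.attrs["ring_radius_mm"] = sino.geometry.ring_radius
        f.attrs["n_elements"] = sino.geometry.n_elements
        f.attrs["element_height_mm"] = sino.geometry.element_height
        f.attrs["elevational_positions_mm"] = np.asarray(
            sino.geometry.elevational_positions, dtype=float
        )
        f.attrs["f_center_mhz"] = sino.transducer.f_center
        f.attrs["fractional_bandwidth_oneway"] = (
            sino.transducer.fractional_bandwidth_oneway
        )
        f.attrs["record_length_us"] = sino.transducer.record_length
        f.attrs["directivity_model"] = sino.directivity_model
        if sino.noise_seed is not None:
            f.attrs["seed"] = sino.noise_seed


def read_sinogram(path: Union[str, Path]) -> Sinogram:
    """Load and validate an HDF5 sinogram container."""
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise FormatError("missing dataset '/data'")
        missing = [k for k in _REQUIRED_ATTRS if k not in f.attrs]
        if missing:
            raise FormatError(
                "sinogram file is missing required attributes: "
                + ", ".join(missing)
            )
        data = np.asarray(f["data"], dtype=np.float64)
        if data.ndim != 3:
            raise FormatError(
                f"dataset '/data' must be 3D [steps, elements, samples], "
                f"got shape {data.shape}"
            )
        if not np.all(np.isfinite(data)):
            raise FormatError("sinogram data contain non-finite values")
        attrs = dict(f.attrs)
    geom = ArrayGeometry(
        ring_radius=float(attrs["ring_radius_mm"]),
        n_elements=int(attrs["n_elements"]),
        element_height=float(attrs["element_height_mm"]),
        elevational_positions=tuple(
            np.atleast_1d(attrs["elevational_positions_mm"]).astype(float)
        ),
    )
    record_length = float(
        attrs.get(
            "record_length_us",
            data.shape[2] / float(attrs["sampling_rate_mhz"]),
        )
    )
    tr = TransducerModel(
        f_center=float(attrs.get("f_center_mhz", 2.25)),
        fractional_bandwidth_oneway=float(
            attrs.get("fractional_bandwidth_oneway", 0.95)
        ),
        sampling_rate=float(attrs["sampling_rate_mhz"]),
        record_length=record_length,
        element_height=float(attrs["element_height_mm"]),
    )
    if data.shape[1] != geom.n_elements:
        raise FormatError(
            f"element axis {data.shape[1]} does not match n_elements attribute "
            f"{geom.n_elements}"
        )
    seed = int(attrs["seed"]) if "seed" in attrs else None
    return Sinogram(
        data,
        geom,
        tr,
        float(attrs["speed_of_sound_mm_per_us"]),
        noise_seed=seed,
        directivity_model=str(attrs.get("directivity_model", "aperture")),
    )


def write_frames(path: Union[str, Path], seq: FrameSequence) -> None:
    """Multi-page float32 TIFF + JSON sidecar (same stem, .json)."""
    path = Path(path)
    tifffile.imwrite(path, seq.frames.astype(np.float32))
    meta = {
        "frame_rate_hz": seq.frame_rate,
        "pixel_size_mm": seq.pixel_size,
        "n_frames": int(seq.n_frames),
        "ground_truth": {
            k: v for k, v in seq.ground_truth.items() if np.isscalar(v) or isinstance(v, str)
        },
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_frames(path: Union[str, Path]) -> FrameSequence:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())
    return FrameSequence(
        frames=frames,
        frame_rate=float(meta["frame_rate_hz"]),
        pixel_size=float(meta["pixel_size_mm"]),
        ground_truth=meta.get("ground_truth", {}),
    )


def write_volume_nifti(path: Union[str, Path], vol: ImageVolume) -> None:
    """NIfTI with (x, y, z) voxel sizes in mm recorded in the header.

    The elevational coordinate convention is z = 0 at the shallowest
    (nipple-most) scan position, increasing toward the chest wall.
    """
    g = vol.grid
    arr = np.transpose(vol.values, (2, 1, 0)).astype(np.float32)  # x, y, z
    affine = np.diag([g.voxel_xy, g.voxel_xy, g.voxel_z, 1.0])
    affine[:3, 3] = (g.origin[2], g.origin[1], g.origin[0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def write_volume_tiff(path: Union[str, Path], vol: ImageVolume) -> None:
    tifffile.imwrite(path, vol.values.astype(np.float32))


def write_mask_tiff(path: Union[str, Path], mask: np.ndarray) -> None:
    tifffile.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))


def write_float_tiff(path: Union[str, Path], image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def segments_to_csv(path: Union[str, Path], segments) -> None:
    rows = []
    for i, seg in enumerate(segments.segments):
        rows.append(
            {
                "segment": i,
                "n_pixels": len(seg),
                "row_start": int(seg[0, 0]),
                "col_start": int(seg[0, 1]),
                "row_end": int(seg[-1, 0]),
                "col_end": int(seg[-1, 1]),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def bifurcations_to_csv(path: Union[str, Path], bifurcations) -> None:
    rows = [
        {
            "d_parent_mm": b.d_parent,
            "d_daughter_a_mm": b.d_daughter_a,
            "d_daughter_b_mm": b.d_daughter_b,
            "x_b": b.x_b,
            "r_b": b.r_b,
        }
        for b in bifurcations
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
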