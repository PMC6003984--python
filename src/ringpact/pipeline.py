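"""End-to-end pipeline driver: simulate → reconstruct → analyse.

All stage parameters default to the system's processing constants
(2 mm density window, k = 2.0 segmentation threshold, 1855-px region
filter, 1.0–1.6 Hz heart band, 16 subdomains, 0.2 mm smoothing,
100 elastography realizations, Frangi scales spanning 3–12 px vessels,
0.5–2.0 mm template bank).  Every source of randomness derives from the
single global seed, so identical configurations produce identical output
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import tifffile
import yaml

from . import io as rio
from .forward import simulate_sinogram
from .geometry import ArrayGeometry, TransducerModel
from .phantom import GridSpec, TumorSpec, rasterize_phantom
from .recon import ReconConfig, reconstruct_2d
from .tree import fit_to_box, generate_vessel_tree
from .tumor import segment_tumors, vessel_density_map
from .vessels import enhance_and_segment, skeleton_segments

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "ringpact_run"
    # phantom
    grid_extent_mm: float = 25.6
    pixel_mm: float = 0.1
    n_levels: int = 4
    root_diameter_mm: float = 1.2
    junction_exponent: float = 2.63
    asymmetry: float = 0.8
    tumor_center_mm: Optional[Tuple[float, float]] = (5.0, -4.0)
    tumor_radius_mm: float = 5.0
    tumor_multiplier: float = 3.0
    tumor_stiffness: float = 0.5
    # acquisition / reconstruction
    speed_of_sound: float = 1.5
    noise_sd: float = 0.0
    half_time: bool = True
    antialias: bool = False
    # vessel analysis
    frangi_sigmas: Tuple[float, ...] = (1.5, 2.5, 3.5, 4.5, 6.0)
    # density / tumor
    density_window_mm: float = 2.0
    k_sigma: float = 2.0
    min_region_pixels: int = 1855
    support_diameter_mm: float = 100.0
    # dynamics
    heart_band: Tuple[float, float] = (1.0, 1.6)
    n_subdomains: int = 16
    smoothing_radius_mm: float = 0.2
    frame_rate_hz: float = 10.0
    # elastography
    compression_freq_hz: float = 0.25
    n_realizations: int = 100
    # optional stages
    run_dynamics: bool = False
    run_elastography: bool = False

    def validate(self):
        if self.heart_band[1] >= self.frame_rate_hz / 2:
            raise ValueError(
                f"heart band {self.heart_band} exceeds the Nyquist limit of "
                f"the {self.frame_rate_hz} Hz frame rate"
            )
        if self.compression_freq_hz >= self.frame_rate_hz / 2:
            raise ValueError("compression frequency exceeds Nyquist")
        if not 1.4 < self.speed_of_sound < 1.6:
            raise ValueError("speed of sound must be in (1.4, 1.6) mm/µs")


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("tumor_center_mm", "heart_band", "frangi_sigmas"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate → recon → vessels → density → tumor; write a manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }

    def record(stage, path: Path):
        manifest["outputs"][stage] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    try:
        stage = "simulate"
        tree = generate_vessel_tree(
            seed=config.seed,
            n_levels=config.n_levels,
            root_diameter=config.root_diameter_mm,
            junction_exponent=config.junction_exponent,
            asymmetry=config.asymmetry,
            root_position=(-config.grid_extent_mm / 2 + 2.0, 0.0),
        )
        half = config.grid_extent_mm / 2.0
        tree = fit_to_box(tree, (-half, -half), (half, half))
        n = int(round(config.grid_extent_mm / config.pixel_mm)) + 1
        grid = GridSpec(shape=(1, n, n), voxel_xy=config.pixel_mm)
        tumor = (
            TumorSpec(
                center=tuple(config.tumor_center_mm),
                radius=config.tumor_radius_mm,
                density_multiplier=config.tumor_multiplier,
                stiffness_factor=config.tumor_stiffness,
            )
            if config.tumor_center_mm is not None
            else None
        )
        phantom = rasterize_phantom(tree, grid, tumor, seed=config.seed)
        geometry = ArrayGeometry()
        transducer = TransducerModel()
        sino = simulate_sinogram(
            phantom,
            geometry,
            transducer,
            config.speed_of_sound,
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
        sino_path = out / "sinogram.h5"
        rio.write_sinogram(sino_path, sino)
        record(stage, sino_path)
        manifest["stages"][stage] = "ok"

        stage = "recon"
        recon = reconstruct_2d(
            sino,
            ReconConfig(
                grid=grid,
                speed_of_sound=config.speed_of_sound,
                half_time=config.half_time,
                antialias=config.antialias,
            ),
        )
        img_path = out / "recon.tiff"
        rio.write_volume_tiff(img_path, recon)
        rio.write_volume_nifti(out / "recon.nii.gz", recon)
        record(stage, img_path)
        manifest["stages"][stage] = "ok"

        stage = "vessels"
        vm = enhance_and_segment(recon.values[0], sigmas=config.frangi_sigmas)
        mask_path = out / "vessel_mask.tiff"
        rio.write_mask_tiff(mask_path, vm.mask)
        segs = skeleton_segments(vm.mask)
        seg_path = out / "segments.csv"
        rio.segments_to_csv(seg_path, segs)
        record(stage, mask_path)
        manifest["stages"][stage] = "ok"

        stage = "density"
        dm = vessel_density_map(
            segs,
            recon.values[0].shape,
            window_mm=config.density_window_mm,
            pixel_size=config.pixel_mm,
            support_diameter_mm=config.support_diameter_mm,
        )
        dens_path = out / "density.tiff"
        rio.write_float_tiff(dens_path, dm.density)
        record(stage, dens_path)
        manifest["stages"][stage] = "ok"

        stage = "tumor"
        min_px = int(
            round(
                config.min_region_pixels * (0.1 / config.pixel_mm) ** 2
            )
        )
        seg_result = segment_tumors(
            dm, k_sigma=config.k_sigma, min_pixels=min_px
        )
        lab_path = out / "tumor_labels.tiff"
        tifffile.imwrite(lab_path, seg_result.labels.astype(np.uint16))
        record(stage, lab_path)
        manifest["stages"][stage] = "ok"
        manifest["tumor_regions"] = [
            {
                "label": r.label,
                "n_pixels": r.n_pixels,
                "centroid_px": list(r.centroid),
                "longest_dimension_mm": r.longest_dimension_mm,
            }
            for r in seg_result.regions
        ]
    except Exception as e:
        manifest["stages"][stage] = f"failed: {e}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
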