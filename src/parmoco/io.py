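"""File formats and run configuration.

Scans (fan sinogram + timeline + ECG + config echo) and motion fields
are stored in HDF5; reconstructions and ground truths as NIfTI-1 with
values in HU and the pixel size in the header.  Run configuration is a
YAML document with blocks ``phantom / geometry / scan / recon / motion /
metrics`` plus a ``seed``; every omitted key falls back to the package
default, every unknown key is an error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .core import ReconGrid, ReconImage, hu_to_mu, mu_to_hu
from .motion_estimation import (BandPassSpec, MotionVectorField,
                                RegistrationConfig)
from .phantom import DynamicPhantom, ECGModel, preset
from .projector import FanSinogram, ScanTimeline, SystemGeometry

FORMAT_VERSION = "1"


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

_DEFAULTS: dict = {
    "phantom": {"preset": "xcat_like", "heart_rate": 80.0, "t0_rpeak": 0.0,
                "options": {}},
    "geometry": {f.name: f.default for f in dataclasses.fields(SystemGeometry)},
    "scan": {"n_rotations": None, "start_angle": 0.0, "start_time": 0.0,
             "photons_per_ray": None},
    "recon": {"n": 256, "fov": 250.0, "phases": [0.3, 0.7], "method": "sculli",
              "cycle_index": None, "apodize": False, "supersample_truth": 4},
    "motion": {"f_lo": 0.1, "f_hi": 0.3, "levels": 3, "finest_spacing": 3.6,
               "bending_weight": 0.01, "max_iter": 50,
               "displacement_cap": 14.3},
    "metrics": {"roi_half_extent": 10.0},
    "seed": 0,
}


def _merged(block: str, user: dict | None) -> dict:
    base = dict(_DEFAULTS[block])
    user = user or {}
    unknown = set(user) - set(base)
    if unknown:
        raise ConfigError(f"unknown keys in {block!r} block: {sorted(unknown)}")
    base.update(user)
    return base


@dataclass
class RunConfig:
    """Validated run configuration with paper-default parameters."""

    phantom: dict = dc_field(default_factory=lambda: dict(_DEFAULTS["phantom"]))
    geometry: SystemGeometry = dc_field(default_factory=SystemGeometry)
    scan: dict = dc_field(default_factory=lambda: dict(_DEFAULTS["scan"]))
    recon: dict = dc_field(default_factory=lambda: dict(_DEFAULTS["recon"]))
    motion: dict = dc_field(default_factory=lambda: dict(_DEFAULTS["motion"]))
    metrics: dict = dc_field(default_factory=lambda: dict(_DEFAULTS["metrics"]))
    seed: int = 0

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = d or {}
        unknown = set(d) - {"phantom", "geometry", "scan", "recon", "motion",
                            "metrics", "seed"}
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        geo = SystemGeometry(**_merged("geometry", d.get("geometry")))
        return RunConfig(
            phantom=_merged("phantom", d.get("phantom")),
            geometry=geo,
            scan=_merged("scan", d.get("scan")),
            recon=_merged("recon", d.get("recon")),
            motion=_merged("motion", d.get("motion")),
            metrics=_merged("metrics", d.get("metrics")),
            seed=int(d.get("seed", 0)),
        )

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return RunConfig.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "phantom": dict(self.phantom),
            "geometry": dataclasses.asdict(self.geometry),
            "scan": dict(self.scan),
            "recon": dict(self.recon),
            "motion": dict(self.motion),
            "metrics": dict(self.metrics),
            "seed": self.seed,
        }

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    # -- derived objects ----------------------------------------------------
    def build_phantom(self) -> DynamicPhantom:
        p = self.phantom
        return preset(p["preset"], heart_rate=p["heart_rate"],
                      t0_rpeak=p["t0_rpeak"], **(p.get("options") or {}))

    def build_grid(self) -> ReconGrid:
        n = int(self.recon["n"])
        return ReconGrid(n=n, pixel_size=float(self.recon["fov"]) / n)

    def build_timeline(self, ecg: ECGModel) -> ScanTimeline:
        n_rot = self.scan["n_rotations"]
        if n_rot is None:
            # cover two full cardiac cycles plus one gating window
            window_t = (np.pi + 2 * self.geometry.fan_rad) / (2 * np.pi) \
                * self.geometry.rotation_time
            n_rot = np.ceil((2.0 * ecg.period + window_t)
                            / self.geometry.rotation_time) + 1
        return ScanTimeline.for_scan(self.geometry, n_rotations=float(n_rot),
                                     start_angle=float(self.scan["start_angle"]),
                                     start_time=float(self.scan["start_time"]))

    def band_spec(self) -> BandPassSpec:
        return BandPassSpec(f_lo=self.motion["f_lo"], f_hi=self.motion["f_hi"])

    def reg_config(self) -> RegistrationConfig:
        m = self.motion
        return RegistrationConfig(
            levels=int(m["levels"]), finest_spacing=float(m["finest_spacing"]),
            bending_weight=float(m["bending_weight"]),
            max_iter=int(m["max_iter"]),
            displacement_cap=float(m["displacement_cap"]))


# --------------------------------------------------------------------------
# HDF5 scan / MVF
# --------------------------------------------------------------------------

def write_scan_h5(path: str | Path, sino: FanSinogram, ecg: ECGModel,
                  config: RunConfig | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("values", data=sino.values)
        f.create_dataset("view_angles", data=sino.timeline.view_angles)
        f.create_dataset("view_times", data=sino.timeline.view_times)
        for k, v in dataclasses.asdict(sino.geometry).items():
            f.attrs[f"geometry/{k}"] = v
        f.attrs["ecg/heart_rate"] = ecg.heart_rate
        f.attrs["ecg/t0_rpeak"] = ecg.t0_rpeak
        if config is not None:
            f.attrs["config_yaml"] = config.canonical_yaml()


def read_scan_h5(path: str | Path
                 ) -> tuple[FanSinogram, ECGModel, RunConfig | None]:
    with h5py.File(path, "r") as f:
        geo_kwargs = {
            f_.name: type(f_.default)(f.attrs[f"geometry/{f_.name}"])
            for f_ in dataclasses.fields(SystemGeometry)
        }
        geometry = SystemGeometry(**geo_kwargs)
        timeline = ScanTimeline(view_angles=f["view_angles"][()],
                                view_times=f["view_times"][()])
        sino = FanSinogram(values=f["values"][()], geometry=geometry,
                           timeline=timeline)
        ecg = ECGModel(heart_rate=float(f.attrs["ecg/heart_rate"]),
                       t0_rpeak=float(f.attrs["ecg/t0_rpeak"]))
        cfg = None
        if "config_yaml" in f.attrs:
            cfg = RunConfig.from_dict(yaml.safe_load(f.attrs["config_yaml"]))
    return sino, ecg, cfg


def write_mvf_h5(path: str | Path, mvf: MotionVectorField) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.create_dataset("controls", data=mvf.controls)
        f.attrs["spacing_mm"] = mvf.spacing
        f.attrs["origin_mm"] = mvf.origin
        f.attrs["extent_mm"] = mvf.extent
        f.attrs["t_start"] = mvf.t_start
        f.attrs["t_end"] = mvf.t_end
        f.attrs["displacement_cap"] = mvf.displacement_cap
        for k in ("final_ssd", "converged"):
            if k in mvf.meta and mvf.meta[k] is not None:
                f.attrs[f"diag/{k}"] = mvf.meta[k]


def read_mvf_h5(path: str | Path) -> MotionVectorField:
    with h5py.File(path, "r") as f:
        mvf = MotionVectorField(
            controls=f["controls"][()],
            spacing=float(f.attrs["spacing_mm"]),
            origin=float(f.attrs["origin_mm"]),
            extent=float(f.attrs["extent_mm"]),
            t_start=float(f.attrs["t_start"]),
            t_end=float(f.attrs["t_end"]),
            displacement_cap=float(f.attrs["displacement_cap"]))
    return mvf


# --------------------------------------------------------------------------
# NIfTI images
# --------------------------------------------------------------------------

def write_nifti(path: str | Path, image: ReconImage) -> None:
    """Write the image in HU as single-slice NIfTI-1 (pixel size in header)."""
    data = image.hu()[:, :, None].astype(np.float32)
    affine = np.diag([image.grid.pixel_size, image.grid.pixel_size, 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((image.grid.pixel_size, image.grid.pixel_size, 1.0))
    nib.save(img, str(path))


def read_nifti(path: str | Path) -> ReconImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[:, :, 0]
    px = float(img.header.get_zooms()[0])
    grid = ReconGrid(n=data.shape[0], pixel_size=px)
    return ReconImage(values=hu_to_mu(data), grid=grid)
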