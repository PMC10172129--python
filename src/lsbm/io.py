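"""File formats and run configuration.

On-disk layout (see also docs/FORMATS.md):

* Frame stacks: multi-page TIFF (one page per frame) or HDF5 with
  ``/frames`` of shape (n, rows, cols); ground truth from the simulator is
  stored under ``/truth/*`` so synthetic datasets carry their answers.
* Calibration models: JSON (see :class:`~lsbm.calibration.CalibrationModel`).
* Shift volumes: HDF5 with ``/maps/{shift,linewidth,snr,valid}`` datasets
  and ``voxel_size_um``, ``geometry``, ``timepoints_min`` attributes.
* ROI summaries: CSV with columns timepoint_min, stat_GHz, dispersion_GHz,
  n_voxels.
* Run configuration: YAML, schema-validated (unknown keys rejected).

Counts and GHz fields are stored as 64-bit floats so every round trip is
lossless.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .calibration import CalibrationModel
from .errors import FormatError
from .mapping import RegistrationTransform, ROITimeSeries, ShiftVolume
from .reconstruction import FitConfig
from .simulator import SpectralFrame
from .spectral_model import (
    CameraConfig,
    GeometryConfig,
    InstrumentKernel,
    NotchConfig,
    SpectrometerConfig,
)

__all__ = [
    "write_frames",
    "read_frames",
    "write_volume",
    "read_volume",
    "write_calibration",
    "read_calibration",
    "write_timeseries_csv",
    "write_measurements_csv",
    "read_mask",
    "RunConfig",
]


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

def write_frames(path, frames, truth: dict | None = None) -> None:
    """Write a frame stack as multi-page TIFF or HDF5 (by extension).

    ``truth`` (simulator ground truth; HDF5 only) is stored under ``/truth``.
    """
    path = Path(path)
    frames = list(frames)
    stack = np.stack([f.counts for f in frames]).astype(np.float64)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, stack)
        return
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as h5:
            ds = h5.create_dataset("frames", data=stack)
            ds.attrs["exposure_s"] = frames[0].exposure
            if truth:
                grp = h5.create_group("truth")
                for key, val in truth.items():
                    grp.create_dataset(key, data=np.asarray(val))
        return
    raise FormatError(f"unsupported frame format: {path.suffix!r}")


class FrameStack:
    """Lazy per-frame access to an HDF5 frame stack."""

    def __init__(self, path):
        self._path = Path(path)
        with h5py.File(self._path, "r") as h5:
            if "frames" not in h5:
                raise FormatError(f"{path}: missing /frames dataset")
            self._n = h5["frames"].shape[0]
            self._exposure = float(h5["frames"].attrs.get("exposure_s", 0.1))

    def __len__(self) -> int:
        return self._n

    def __getitem__(self, i: int) -> SpectralFrame:
        with h5py.File(self._path, "r") as h5:
            counts = h5["frames"][i][...]
        return SpectralFrame(counts=counts, exposure=self._exposure,
                             metadata={"index": i, "path": str(self._path)})

    @property
    def truth(self) -> dict:
        with h5py.File(self._path, "r") as h5:
            if "truth" not in h5:
                return {}
            return {k: h5["truth"][k][...] for k in h5["truth"]}


def read_frames(path, lazy: bool = False):
    """Read a frame stack (TIFF or HDF5); returns a list of frames or a
    lazy :class:`FrameStack` for HDF5 with ``lazy=True``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            stack = tifffile.imread(path)
        except Exception as exc:
            raise FormatError(f"{path}: malformed TIFF ({exc})") from exc
        if stack.ndim == 2:
            stack = stack[None]
        return [SpectralFrame(counts=page, metadata={"index": i, "path": str(path)})
                for i, page in enumerate(stack)]
    if path.suffix.lower() in (".h5", ".hdf5"):
        try:
            stack = FrameStack(path)
        except FormatError:
            raise
        except Exception as exc:
            raise FormatError(f"{path}: malformed HDF5 ({exc})") from exc
        if lazy:
            return stack
        frames = [stack[i] for i in range(len(stack))]
        truth = stack.truth
        if truth:
            for f in frames:
                f.metadata["truth"] = truth
        return frames
    raise FormatError(f"unsupported frame format: {path.suffix!r}")


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def write_volume(path, volume: ShiftVolume, calibration: CalibrationModel | None = None
                 ) -> None:
    with h5py.File(Path(path), "w") as h5:
        maps = h5.create_group("maps")
        maps.create_dataset("shift", data=volume.shift.astype(np.float64))
        maps.create_dataset("linewidth", data=volume.linewidth.astype(np.float64))
        maps.create_dataset("snr", data=volume.snr.astype(np.float64))
        maps.create_dataset("valid", data=volume.valid.astype(np.uint8))
        h5.attrs["voxel_size_um"] = volume.voxel_size_um
        h5.attrs["geometry"] = volume.geometry
        if volume.timepoints_min is not None:
            h5.attrs["timepoints_min"] = volume.timepoints_min
        if calibration is not None:
            h5.attrs["calibration_json"] = calibration.to_json()


def read_volume(path) -> ShiftVolume:
    path = Path(path)
    try:
        with h5py.File(path, "r") as h5:
            if "maps" not in h5:
                raise FormatError(f"{path}: missing /maps group")
            maps = h5["maps"]
            timepoints = h5.attrs.get("timepoints_min")
            return ShiftVolume(
                shift=maps["shift"][...],
                linewidth=maps["linewidth"][...],
                snr=maps["snr"][...],
                valid=maps["valid"][...].astype(bool),
                voxel_size_um=tuple(h5.attrs["voxel_size_um"]),
                geometry=str(h5.attrs.get("geometry", "E-LSBM")),
                timepoints_min=None if timepoints is None else np.asarray(timepoints),
            )
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"{path}: malformed volume file ({exc})") from exc


# ---------------------------------------------------------------------------
# calibration, tables, masks
# ---------------------------------------------------------------------------

def write_calibration(path, model: CalibrationModel) -> None:
    Path(path).write_text(model.to_json())


def read_calibration(path) -> CalibrationModel:
    try:
        return CalibrationModel.from_json(Path(path).read_text())
    except Exception as exc:
        raise FormatError(f"{path}: malformed calibration JSON ({exc})") from exc


def write_timeseries_csv(path, series: ROITimeSeries) -> None:
    disp = series.dispersion
    if disp.ndim == 2:  # IQR bounds -> half-width for the summary column
        disp = 0.5 * (disp[1] - disp[0])
    pd.DataFrame(
        {
            "timepoint_min": series.timepoints_min,
            "stat_GHz": series.central,
            "dispersion_GHz": disp,
            "n_voxels": series.n_voxels,
        }
    ).to_csv(path, index=False)


def write_measurements_csv(path, measurements) -> None:
    pd.DataFrame(
        [
            {
                "row": m.row,
                "shift_GHz": m.shift,
                "linewidth_GHz": m.linewidth,
                "amplitude_counts": m.amplitude,
                "snr_dB": m.snr_db,
                "r_squared": m.goodness_r2,
                "n_iterations": m.n_iterations,
                "valid": m.valid,
            }
            for m in measurements
        ]
    ).to_csv(path, index=False)


def read_mask(path) -> np.ndarray:
    """Read a label/ROI mask TIFF as a boolean array (non-zero = inside)."""
    try:
        return tifffile.imread(Path(path)) != 0
    except Exception as exc:
        raise FormatError(f"{path}: malformed mask TIFF ({exc})") from exc


# ---------------------------------------------------------------------------
# run configuration (YAML, schema-validated)
# ---------------------------------------------------------------------------

class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KernelSection(_Section):
    kind: str = "gaussian"
    sigma: float = 0.297


class NotchSection(_Section):
    line_centers: list[float] = [0.0]
    optical_depth: float = float(np.log(1e8))
    doppler_fwhm: float = 0.55


class CameraSection(_Section):
    read_noise: float = 2.0
    gain: float = 1.0
    full_well: float = 65535.0
    exposure: float = 0.1


class SpectrometerSection(_Section):
    fsr: float = 15.15
    n_orders_visible: int = 3
    spectral_sampling: float = 0.35
    spatial_sampling: float = 0.7
    dispersion_nonlinearity: float = 0.0
    instrument_kernel: KernelSection = KernelSection()
    notch: NotchSection = NotchSection()
    camera: CameraSection = CameraSection()

    def build(self) -> SpectrometerConfig:
        return SpectrometerConfig(
            fsr=self.fsr,
            n_orders_visible=self.n_orders_visible,
            spectral_sampling=self.spectral_sampling,
            spatial_sampling=self.spatial_sampling,
            dispersion_nonlinearity=self.dispersion_nonlinearity,
            instrument_kernel=InstrumentKernel(**self.instrument_kernel.model_dump()),
            notch=NotchConfig(
                line_centers=tuple(self.notch.line_centers),
                optical_depth=self.notch.optical_depth,
                doppler_fwhm=self.notch.doppler_fwhm,
            ),
            camera=CameraConfig(**self.camera.model_dump()),
        )


class GeometrySection(_Section):
    scattering_angle: float = 180.0
    wavelength_nm: float = 780.24
    refractive_index: float = 1.33
    sound_velocity: float = 1490.0

    def build(self) -> GeometryConfig:
        return GeometryConfig(**self.model_dump())


class FitSection(_Section):
    model_kind: str = "broadened_brillouin"
    fit_range_lo: float = 2.0
    fit_range_hi: float | None = None
    target_df: float = 0.1
    min_orders: int = 3
    instrument_sigma: float = 0.297
    r2_threshold: float = 0.5
    shot_noise_weights: bool = False

    def build(self) -> FitConfig:
        return FitConfig(
            model_kind=self.model_kind,
            fit_range=(self.fit_range_lo, self.fit_range_hi),
            target_df=self.target_df,
            min_orders=self.min_orders,
            instrument_sigma=self.instrument_sigma,
            r2_threshold=self.r2_threshold,
            shot_noise_weights=self.shot_noise_weights,
        )


class RegistrationSection(_Section):
    xy_scale: float = 2.5138
    y_offset: int = 450
    x_offset: int = 0

    def build(self) -> RegistrationTransform:
        return RegistrationTransform(**self.model_dump())


class RunConfig(_Section):
    """Full run configuration; validated before any stage runs."""

    spectrometer: SpectrometerSection = SpectrometerSection()
    geometry: GeometrySection = GeometrySection()
    fit: FitSection = FitSection()
    registration: RegistrationSection = RegistrationSection()
    paths: dict[str, str] = {}
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
            return cls(**data)
        except ValidationError:
            raise
        except Exception as exc:
            raise FormatError(f"{path}: malformed YAML config ({exc})") from exc

    def config_hash(self) -> str:
        """Stable hash identifying the configuration (logged with each run)."""
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
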