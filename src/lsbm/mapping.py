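"""Shift-map assembly and fluorescence-guided quantification.

Per-line measurements are stacked into 3D/4D shift volumes; the
quantification mirrors the image-guided analysis used on embryo data:
bilinear rescaling of the Brillouin maps onto the fluorescence pixel grid,
offset-based overlay registration (the landmark offset is user input),
re-slicing with per-slab median projections, mask statistics (mean +/- sd or
median + IQR), time series relative to a reference timepoint, and the
Gaussian bead-scan PSF analysis.

Conventions: 0-based indices; x is along the illumination line, y the
light-sheet scan axis, z depth; rescaled output sizes use
``floor(input * scale)``; invalid voxels are excluded from (never zero-
filled into) every statistic; the median of an even count is the mean of
the central pair and the IQR uses linear-interpolation quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from skimage.transform import resize

from .errors import InvalidParameterError, RangeError
from .spectral_model import GAUSSIAN_FWHM_PER_SIGMA

__all__ = [
    "ShiftVolume",
    "RegistrationTransform",
    "ROITimeSeries",
    "assemble_volume",
    "rescale_to_fluorescence",
    "register_overlay",
    "reslice_and_median_project",
    "roi_quantify",
    "relative_timeseries",
    "bead_psf_fwhm",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ShiftVolume:
    """3D/4D grid of Brillouin measurements with voxel geometry.

    Grids are (x, y[, z]) or (t, x, y, z); all share one shape.  ``valid``
    marks voxels whose fit succeeded; invalid voxels hold NaN in ``shift``.
    """

    shift: np.ndarray  # GHz
    linewidth: np.ndarray  # GHz
    snr: np.ndarray  # dB
    valid: np.ndarray  # bool
    voxel_size_um: tuple[float, float, float] = (0.7, 1.5, 1.5)
    geometry: str = "E-LSBM"
    timepoints_min: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=float)
        self.linewidth = np.asarray(self.linewidth, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        shapes = {a.shape for a in (self.shift, self.linewidth, self.snr, self.valid)}
        if len(shapes) != 1:
            raise InvalidParameterError("all volume grids must be congruent")
        if any(v <= 0 for v in self.voxel_size_um):
            raise InvalidParameterError("voxel_size must be positive")
        if self.timepoints_min is not None:
            self.timepoints_min = np.asarray(self.timepoints_min, dtype=float)

    def masked_shift(self) -> np.ndarray:
        """Shift grid with invalid voxels as NaN."""
        return np.where(self.valid, self.shift, np.nan)


@dataclass(frozen=True)
class RegistrationTransform:
    """Brillouin -> fluorescence frame registration.

    ``xy_scale`` is the linear magnification between the Brillouin map and
    the fluorescence image; ``y_offset`` is half the fluorescence image
    diameter (aligning field centers) and ``x_offset`` is the user-supplied
    landmark offset (e.g. furrow co-localization), both in fluorescence
    pixels.
    """

    xy_scale: float = 2.5138
    y_offset: int = 450
    x_offset: int = 0

    def __post_init__(self) -> None:
        if self.xy_scale <= 0:
            raise InvalidParameterError("xy_scale must be positive")


@dataclass
class ROITimeSeries:
    """Per-timepoint central statistic and dispersion over an ROI."""

    timepoints_min: np.ndarray
    central: np.ndarray  # GHz (mean or median)
    dispersion: np.ndarray  # GHz (sd, or (2, n) low/high IQR bounds distance)
    n_voxels: np.ndarray
    statistic: str = "mean"  # 'mean' (+/- sd) or 'median' (+ IQR)
    reference_index: int | None = None

    def __post_init__(self) -> None:
        self.timepoints_min = np.asarray(self.timepoints_min, dtype=float)
        self.central = np.asarray(self.central, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        self.n_voxels = np.asarray(self.n_voxels, dtype=int)
        n = self.timepoints_min.size
        if not (self.central.size == n and self.n_voxels.size == n
                and self.dispersion.shape[-1] == n):
            raise InvalidParameterError("time-series fields must have equal length")


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_volume(
    measurement_lines,
    scan_positions_um,
    spatial_sampling_um: float = 0.7,
    depth_step_um: float | None = None,
    geometry: str = "E-LSBM",
) -> ShiftVolume:
    """Stack per-line measurements into an (x, y) map / (x, y, 1) volume.

    ``measurement_lines`` is one list of :class:`BrillouinMeasurement` per
    scan position; lines are sorted by their scan position, so shuffled
    acquisition order yields the identical volume.
    """
    lines = list(measurement_lines)
    pos = np.asarray(scan_positions_um, dtype=float)
    if len(lines) != pos.size or not lines:
        raise InvalidParameterError("need one measurement line per scan position")
    lengths = {len(line) for line in lines}
    if len(lengths) != 1:
        raise InvalidParameterError(f"inconsistent line lengths: {sorted(lengths)}")
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    lines = [lines[i] for i in order]

    def grid(attr):
        return np.array([[getattr(m, attr) for m in line] for line in lines]).T

    shift = grid("shift")
    valid = np.array([[m.valid for m in line] for line in lines]).T
    vol_shift = np.where(valid, shift, np.nan)
    steps = np.diff(pos)
    scan_step = float(np.median(steps)) if steps.size else spatial_sampling_um
    voxel = (
        spatial_sampling_um,
        abs(scan_step) if scan_step != 0 else spatial_sampling_um,
        depth_step_um if depth_step_um is not None else abs(scan_step) or 1.0,
    )
    return ShiftVolume(
        shift=vol_shift,
        linewidth=grid("linewidth"),
        snr=grid("snr_db"),
        valid=valid,
        voxel_size_um=voxel,
        geometry=geometry,
    )


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def rescale_to_fluorescence(
    map2d: np.ndarray,
    transform: RegistrationTransform,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Bilinear rescale of a 2D map by ``xy_scale`` in both directions.

    Output dimensions are ``floor(input * scale)``; the validity mask is
    resampled nearest-neighbor so no voxel becomes fractionally valid.
    """
    arr = np.asarray(map2d, dtype=float)
    if arr.ndim != 2:
        raise InvalidParameterError("rescale expects a 2D map")
    s = transform.xy_scale
    out_shape = (int(np.floor(arr.shape[0] * s)), int(np.floor(arr.shape[1] * s)))
    if s == 1.0:
        return arr.copy(), None if valid is None else np.asarray(valid, bool).copy()
    out = resize(arr, out_shape, order=1, mode="edge", anti_aliasing=False)
    out_valid = None
    if valid is not None:
        out_valid = resize(
            np.asarray(valid, dtype=float), out_shape, order=0, mode="edge",
            anti_aliasing=False,
        ).astype(bool)
    return out, out_valid


def register_overlay(
    fluo_stack: np.ndarray,
    brillouin_stack: np.ndarray,
    transform: RegistrationTransform,
) -> tuple[np.ndarray, np.ndarray]:
    """Crop the fluorescence stack onto the (rescaled) Brillouin frame.

    Both stacks are (..., x, y) with the Brillouin stack already rescaled to
    fluorescence pixel size.  The fluorescence is cropped starting at
    ``(x_offset, y_offset - x_size/2 ...)``: ``y_offset`` aligns the
    fluorescence field center (half its diameter) with the Brillouin field
    center, ``x_offset`` is the landmark shift.  Returns the aligned
    (fluorescence, Brillouin) pair on one coordinate frame.
    """
    fluo = np.asarray(fluo_stack, dtype=float)
    bri = np.asarray(brillouin_stack, dtype=float)
    bx, by = bri.shape[-2], bri.shape[-1]
    x0 = transform.x_offset
    y0 = transform.y_offset - by // 2
    if x0 < 0 or y0 < 0 or x0 + bx > fluo.shape[-2] or y0 + by > fluo.shape[-1]:
        raise RangeError(
            f"offsets place the {bx}x{by} crop outside the fluorescence frame "
            f"{fluo.shape[-2]}x{fluo.shape[-1]}"
        )
    cropped = fluo[..., x0 : x0 + bx, y0 : y0 + by]
    return cropped, bri


# ---------------------------------------------------------------------------
# projections and ROI statistics
# ---------------------------------------------------------------------------

def reslice_and_median_project(
    volume: ShiftVolume | np.ndarray,
    axis: int,
    slabs,
) -> list[np.ndarray]:
    """Voxel-wise median over each slab of slices along ``axis``.

    Invalid (NaN) voxels are ignored; a pixel whose slab is fully invalid is
    NaN in the output.  ``slabs`` is a list of slice-index groups, e.g.
    ``[(0, 1), (2, 3), (4, 5)]`` for three projections of two slices each.
    """
    arr = volume.masked_shift() if isinstance(volume, ShiftVolume) else np.asarray(
        volume, dtype=float
    )
    out = []
    for slab in slabs:
        idx = np.asarray(list(slab), dtype=int)
        if np.any(idx < 0) or np.any(idx >= arr.shape[axis]):
            raise RangeError(f"slab indices {idx.tolist()} out of range on axis {axis}")
        taken = np.take(arr, idx, axis=axis)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slabs
            out.append(np.nanmedian(taken, axis=axis))
    return out


def roi_quantify(
    map_or_volume: np.ndarray | ShiftVolume,
    mask: np.ndarray,
    statistic: str = "mean",
) -> dict:
    """Central statistic and dispersion of the valid masked voxels.

    ``statistic='mean'`` reports mean and sd; ``'median'`` reports the median
    and the interquartile range bounds (25th/75th percentiles, linear
    interpolation).  Returns ``{'central', 'dispersion', 'n'}`` with
    ``dispersion`` the sd or the ``(q25, q75)`` pair.
    """
    arr = (
        map_or_volume.masked_shift()
        if isinstance(map_or_volume, ShiftVolume)
        else np.asarray(map_or_volume, dtype=float)
    )
    m = np.asarray(mask, dtype=bool)
    if m.shape != arr.shape:
        raise InvalidParameterError(
            f"mask shape {m.shape} does not match map shape {arr.shape}"
        )
    vals = arr[m]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InvalidParameterError("empty mask (or no valid voxels under it)")
    if statistic == "mean":
        disp = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        return {"central": float(np.mean(vals)), "dispersion": disp, "n": int(vals.size)}
    if statistic == "median":
        q25, q75 = np.percentile(vals, [25.0, 75.0], method="linear")
        return {
            "central": float(np.median(vals)),
            "dispersion": (float(q25), float(q75)),
            "n": int(vals.size),
        }
    raise InvalidParameterError(f"unknown statistic {statistic!r}")


def relative_timeseries(series: ROITimeSeries, t0_index: int = 0) -> ROITimeSeries:
    """Express the central statistic relative to its value at ``t0_index``.

    Dispersions are left untouched (they describe scatter, not offset).
    """
    if not 0 <= t0_index < series.timepoints_min.size:
        raise RangeError(f"t0 index {t0_index} out of range")
    ref = series.central[t0_index]
    central = series.central - ref
    dispersion = series.dispersion.copy()
    if dispersion.ndim == 2:  # IQR bounds shift with the central value
        dispersion = dispersion - ref
    return ROITimeSeries(
        timepoints_min=series.timepoints_min.copy(),
        central=central,
        dispersion=dispersion,
        n_voxels=series.n_voxels.copy(),
        statistic=series.statistic,
        reference_index=t0_index,
    )


# ---------------------------------------------------------------------------
# bead-scan PSF
# ---------------------------------------------------------------------------

def bead_psf_fwhm(scan_positions_um, rayleigh_amplitudes) -> float:
    """Spatial resolution from a bead scan: Gaussian FWHM in um.

    The Rayleigh-peak amplitude recorded at each scan position traces the
    system PSF across a sub-resolution bead; a Gaussian least-squares fit
    gives FWHM = 2 sqrt(2 ln 2) sigma.
    """
    x = np.asarray(scan_positions_um, dtype=float)
    y = np.asarray(rayleigh_amplitudes, dtype=float)
    if x.size != y.size or x.size < 7:
        raise InvalidParameterError("need >= 7 samples spanning the bead peak")
    span = float(y.max() - y.min())
    if span <= 0:
        raise InvalidParameterError("flat profile: no bead peak")
    imax = int(np.argmax(y))
    if imax in (0, y.size - 1):
        raise InvalidParameterError("profile is monotone: peak not spanned by the scan")

    def gaussian(xx, amp, mu, sigma, off):
        return amp * np.exp(-0.5 * ((xx - mu) / sigma) ** 2) + off

    sigma0 = max((x.max() - x.min()) / 6.0, 1e-6)
    p0 = [span, float(x[imax]), sigma0, float(y.min())]
    popt, _ = curve_fit(
        gaussian, x, y, p0=p0,
        bounds=([0, x.min(), 1e-6, -np.inf], [np.inf, x.max(), np.inf, np.inf]),
        maxfev=10000,
    )
    return float(GAUSSIAN_FWHM_PER_SIGMA * popt[2])
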