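"""Forward model of the line-scan VIPA spectrometer.

Produces synthetic camera frames with exactly known ground truth, standing in
for the instrument: multi-order VIPA spectra (Rayleigh + Stokes/anti-Stokes
peaks replicated with an inter-order pitch of one FSR), the rubidium notch
suppressing the elastic line, Poisson photon statistics with camera gain and
read noise, calibration frames carrying Rb D2 reference lines, and 3D/4D
embryo-like phantoms with a locally elevated shift (a "folding domain").

The spectral model per VIPA order, in the order's own signed frequency
coordinate ``nu`` (zero at the order's Rayleigh anchor), is

    I(nu) = sum_m S(nu + m * FSR),   m in {-1, 0, +1}

where ``S`` is the instrument-broadened, notch-filtered source spectrum on
the true-frequency axis.  The elastic (Rayleigh) line is spectrally narrow
compared with the notch, so its notch attenuation is evaluated at its line
center before instrument broadening; the Brillouin peaks sit several GHz
outside the notch and are attenuated at the detected frequency, which only
affects their far tails near 0 GHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .errors import (
    CalibrationInsufficiencyError,
    ConfigurationError,
    InvalidParameterError,
)
from .spectral_model import (
    CameraConfig,
    NotchConfig,
    SpectrometerConfig,
    voigt_peak,
)

__all__ = [
    "Material",
    "SpectralFrame",
    "Phantom",
    "WATER",
    "notch_transmission",
    "apply_rb_notch",
    "apply_camera_noise",
    "frequency_to_pixel_offset",
    "pixel_offset_to_frequency",
    "simulate_row_spectrum",
    "simulate_frame",
    "simulate_calibration_frame",
    "uniform_phantom",
    "simulate_timelapse_phantom",
    "phantom_line_materials",
]


# ---------------------------------------------------------------------------
# materials and containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Material:
    """Local sample properties seen by one point on the illumination line."""

    shift: float  # GHz, Brillouin shift nu_B > 0
    linewidth: float  # GHz, intrinsic FWHM Gamma_B
    reflectivity: float = 1e6  # Rayleigh peak height relative to Brillouin

    def __post_init__(self) -> None:
        if self.shift <= 0:
            raise InvalidParameterError("shift must be positive")
        if self.linewidth <= 0:
            raise InvalidParameterError("linewidth must be positive")
        if self.reflectivity < 0:
            raise InvalidParameterError("reflectivity must be non-negative")


#: Water at 780 nm in the epi-line (backscattering) geometry.
WATER = Material(shift=5.05, linewidth=0.4)


@dataclass
class SpectralFrame:
    """One raw spectrometer image: spatial row x spectral pixel, in counts."""

    counts: np.ndarray
    exposure: float = 0.1
    metadata: dict = field(default_factory=dict)
    noiseless: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise InvalidParameterError("frame counts must be 2D (row x pixel)")

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]


@dataclass
class Phantom:
    """Voxel grid of ground-truth sample properties.

    Spatial axes are (x, y, z): x along the illumination line, y the
    light-sheet scan axis, z depth.  With a time axis the grids are
    (t, x, y, z).  An optional fluorescence channel lives on its own, finer,
    xy pixel grid (as a SPIM camera would deliver it).
    """

    shift_ghz: np.ndarray
    linewidth_ghz: np.ndarray
    rayleigh_reflectivity: np.ndarray
    voxel_size_um: tuple[float, float, float] = (0.7, 1.5, 1.5)
    timepoints_min: np.ndarray | None = None
    fluorescence: np.ndarray | None = None
    fluorescence_pixel_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.shift_ghz = np.asarray(self.shift_ghz, dtype=float)
        self.linewidth_ghz = np.asarray(self.linewidth_ghz, dtype=float)
        self.rayleigh_reflectivity = np.asarray(self.rayleigh_reflectivity, dtype=float)
        if not (
            self.shift_ghz.shape
            == self.linewidth_ghz.shape
            == self.rayleigh_reflectivity.shape
        ):
            raise InvalidParameterError("phantom fields must share one grid shape")
        if self.timepoints_min is not None:
            self.timepoints_min = np.asarray(self.timepoints_min, dtype=float)
            if self.shift_ghz.shape[0] != self.timepoints_min.size:
                raise InvalidParameterError(
                    "leading axis of phantom fields must match timepoints"
                )
        if np.any(self.shift_ghz <= 0):
            raise InvalidParameterError("shift_field must be positive everywhere")

    @property
    def has_time(self) -> bool:
        return self.timepoints_min is not None

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.shift_ghz.shape


# ---------------------------------------------------------------------------
# notch and camera
# ---------------------------------------------------------------------------

def notch_transmission(freq_ghz, notch: NotchConfig) -> np.ndarray:
    """Intensity transmission of the Rb-vapor notch at signed GHz ``freq``.

    ``T = exp(-OD * g(nu))`` with ``g`` a unit-peak Gaussian (Doppler)
    absorption profile summed over the configured line centers.
    """
    nu = np.asarray(freq_ghz, dtype=float)
    if notch.optical_depth == 0.0:
        return np.ones_like(nu)
    four_ln2 = 4.0 * np.log(2.0)
    absorption = np.zeros_like(nu)
    for center in notch.line_centers:
        absorption += np.exp(-four_ln2 * (nu - center) ** 2 / notch.doppler_fwhm**2)
    return np.exp(-notch.optical_depth * absorption)


def apply_rb_notch(freq_ghz, spectrum, notch: NotchConfig) -> np.ndarray:
    """Multiply a spectrum on a GHz grid by the notch transmission."""
    return np.asarray(spectrum, dtype=float) * notch_transmission(freq_ghz, notch)


def apply_camera_noise(noiseless, camera: CameraConfig, rng) -> np.ndarray:
    """Poisson photon statistics x gain plus Gaussian read noise.

    ``noiseless`` is the expected photon count per pixel; the returned array
    is in camera counts, clipped at the full-well capacity (negative
    excursions of the read noise are kept, as on a baseline-subtracted
    camera).  ``rng`` may be a seed or a ``numpy.random.Generator``.
    """
    noiseless = np.asarray(noiseless, dtype=float)
    if np.any(noiseless < 0):
        raise InvalidParameterError("noiseless photon counts must be non-negative")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    counts = camera.gain * gen.poisson(noiseless).astype(float)
    if camera.read_noise > 0:
        counts = counts + gen.normal(0.0, camera.read_noise, size=noiseless.shape)
    return np.minimum(counts, camera.full_well)


# ---------------------------------------------------------------------------
# dispersion law (frequency <-> pixel offset within one order)
# ---------------------------------------------------------------------------

def frequency_to_pixel_offset(freq_ghz, config: SpectrometerConfig) -> np.ndarray:
    """Pixel offset from the order's Rayleigh anchor for signed GHz ``freq``.

    ``dp = (nu/s) * (1 + b * nu / FSR)`` with ``s`` the nominal sampling in
    GHz/px and ``b`` the dimensionless quadratic nonlinearity.
    """
    nu = np.asarray(freq_ghz, dtype=float)
    s = config.spectral_sampling
    b = config.dispersion_nonlinearity
    return (nu / s) * (1.0 + b * nu / config.fsr)


def pixel_offset_to_frequency(pixel_offset, config: SpectrometerConfig) -> np.ndarray:
    """Inverse of :func:`frequency_to_pixel_offset` (branch continuous in b)."""
    dp = np.asarray(pixel_offset, dtype=float)
    s = config.spectral_sampling
    b = config.dispersion_nonlinearity
    if b == 0.0:
        return dp * s
    a = 1.0 / s
    c2 = b / (s * config.fsr)
    disc = a * a + 4.0 * c2 * dp
    if np.any(disc <= 0):
        raise ConfigurationError("pixel offset outside the invertible dispersion branch")
    return 2.0 * dp / (a + np.sqrt(disc))


# ---------------------------------------------------------------------------
# row-spectrum forward model
# ---------------------------------------------------------------------------

def _pixel_frequencies(config: SpectrometerConfig) -> tuple[np.ndarray, np.ndarray]:
    """Order index and order-relative frequency (GHz) for every camera pixel."""
    pixels = np.arange(config.n_pixels, dtype=float)
    anchors = config.anchor_positions_px
    order = np.clip(
        np.rint((pixels - anchors[0]) / config.order_pitch_px).astype(int),
        0,
        config.n_orders_visible - 1,
    )
    nu = pixel_offset_to_frequency(pixels - anchors[order], config)
    return order, nu


def _source_spectrum(
    true_freq: np.ndarray, material: Material, config: SpectrometerConfig,
    photon_budget: float,
) -> np.ndarray:
    """Notched, instrument-broadened source spectrum on the true-frequency axis."""
    sigma = config.instrument_kernel.effective_sigma
    notch = config.notch
    # elastic line: narrow vs notch -> attenuate at its center, then broaden
    t_elastic = float(notch_transmission(np.array([0.0]), notch)[0])
    out = (
        material.reflectivity
        * photon_budget
        * t_elastic
        * voigt_peak(true_freq, 1.0, 0.0, config.rayleigh_intrinsic_fwhm, sigma)
    )
    # Brillouin doublet: far from the notch; attenuate at detected frequency
    t_inelastic = notch_transmission(true_freq, notch)
    for center in (-material.shift, material.shift):
        out += t_inelastic * voigt_peak(
            true_freq, photon_budget, center, material.linewidth, sigma
        )
    return out


def simulate_row_spectrum(
    material: Material,
    config: SpectrometerConfig,
    photon_budget: float,
    rng_seed=None,
) -> dict:
    """Simulate one spectral row (one point on the illumination line).

    ``photon_budget`` is the expected peak photon count of each Brillouin
    peak per order before notch/noise; it is the energy knob behind the
    shot-noise precision scaling.  Returns a dict with ``noiseless`` (expected
    photons per pixel), ``noisy`` (camera counts; equals ``noiseless`` when
    ``rng_seed`` is None) and the ground-truth pixel positions of every peak.
    """
    if photon_budget <= 0:
        raise InvalidParameterError("photon_budget must be positive")
    max_offset = frequency_to_pixel_offset(
        np.array([material.shift]), config
    )[0]
    if max_offset >= 0.5 * config.order_pitch_px + 4.0:
        raise ConfigurationError(
            "Brillouin peaks fall outside the simulated pixel range for this "
            "FSR/sampling configuration"
        )
    order, nu = _pixel_frequencies(config)
    noiseless = np.zeros_like(nu)
    for m in (-1, 0, 1):
        noiseless += _source_spectrum(nu + m * config.fsr, material, config, photon_budget)
    if rng_seed is None:
        noisy = noiseless.copy()
    else:
        noisy = apply_camera_noise(noiseless, config.camera, rng_seed)
    anchors = config.anchor_positions_px
    truth = {
        "anchor_px": anchors.copy(),
        "stokes_px": anchors + frequency_to_pixel_offset(-material.shift, config),
        "antistokes_px": anchors + frequency_to_pixel_offset(material.shift, config),
        "shift_ghz": material.shift,
        "linewidth_ghz": material.linewidth,
    }
    return {"noiseless": noiseless, "noisy": noisy, "truth": truth}


def simulate_frame(
    materials,
    config: SpectrometerConfig,
    photon_budget: float,
    rng_seed=None,
) -> SpectralFrame:
    """Simulate a full frame: one independent row spectrum per material.

    Rows are statistically independent; each draws its noise from a child
    stream of ``rng_seed``, so a frame is bit-reproducible from its seed and
    unchanged rows do not perturb each other.
    """
    materials = list(materials)
    if not materials:
        raise InvalidParameterError("need at least one material (row)")
    if rng_seed is None:
        row_rngs = [None] * len(materials)
    elif isinstance(rng_seed, np.random.Generator):
        row_rngs = rng_seed.spawn(len(materials))
    else:
        seq = (
            rng_seed
            if isinstance(rng_seed, np.random.SeedSequence)
            else np.random.SeedSequence(rng_seed)
        )
        row_rngs = [np.random.default_rng(s) for s in seq.spawn(len(materials))]
    noiseless_rows, noisy_rows = [], []
    for mat, rng in zip(materials, row_rngs):
        row = simulate_row_spectrum(mat, config, photon_budget, rng)
        noiseless_rows.append(row["noiseless"])
        noisy_rows.append(row["noisy"])
    truth = {
        "shift_ghz": np.array([m.shift for m in materials]),
        "linewidth_ghz": np.array([m.linewidth for m in materials]),
        "anchor_px": config.anchor_positions_px,
    }
    return SpectralFrame(
        counts=np.vstack(noisy_rows),
        exposure=config.camera.exposure,
        metadata={"truth": truth, "photon_budget": photon_budget, "seed": rng_seed},
        noiseless=np.vstack(noiseless_rows),
    )


def simulate_calibration_frame(
    config: SpectrometerConfig,
    reference_lines,
    rng_seed=None,
    photon_budget: float = 1e4,
    n_rows: int = 1,
) -> SpectralFrame:
    """Frame with narrow peaks at the reference frequencies, notch disabled.

    The 0 GHz (laser-lock) line is rendered 3x brighter than the other
    reference lines so anchor detection can separate anchors from satellite
    lines by prominence, mirroring how the elastic line dominates a real
    calibration image.
    """
    lines = sorted(float(f) for f in reference_lines)
    if len(lines) < 2:
        raise CalibrationInsufficiencyError(
            f"calibration needs >= 2 reference lines, got {len(lines)}"
        )
    cfg = config.without_notch()
    order, nu = _pixel_frequencies(cfg)
    sigma = cfg.instrument_kernel.effective_sigma
    noiseless = np.zeros_like(nu)
    for m in (-1, 0, 1):
        f = nu + m * cfg.fsr
        for line in lines:
            amp = 3.0 * photon_budget if line == 0.0 else photon_budget
            noiseless += voigt_peak(f, amp, line, cfg.rayleigh_intrinsic_fwhm, sigma)
    noisy = (
        noiseless.copy()
        if rng_seed is None
        else apply_camera_noise(noiseless, cfg.camera, rng_seed)
    )
    anchors = cfg.anchor_positions_px
    line_px = {
        line: anchors + frequency_to_pixel_offset(line, cfg) for line in lines
    }
    counts = np.tile(noisy, (n_rows, 1))
    return SpectralFrame(
        counts=counts,
        exposure=cfg.camera.exposure,
        metadata={
            "truth": {"anchor_px": anchors, "line_px": line_px},
            "reference_lines_ghz": lines,
            "calibration": True,
        },
        noiseless=np.tile(noiseless, (n_rows, 1)),
    )


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def uniform_phantom(
    shape: tuple[int, int, int],
    shift: float = WATER.shift,
    linewidth: float = WATER.linewidth,
    reflectivity: float = WATER.reflectivity,
    voxel_size_um: tuple[float, float, float] = (0.7, 1.5, 1.5),
) -> Phantom:
    """Homogeneous (water-like) phantom on an (x, y, z) grid."""
    return Phantom(
        shift_ghz=np.full(shape, shift),
        linewidth_ghz=np.full(shape, linewidth),
        rayleigh_reflectivity=np.full(shape, reflectivity),
        voxel_size_um=voxel_size_um,
    )


def simulate_timelapse_phantom(
    base: Phantom,
    folding_domain: np.ndarray,
    delta_shift_ghz: float,
    timepoints_min,
    fluorescence_scale: float = 2.5138,
) -> Phantom:
    """Time-lapse phantom: the masked domain stiffens linearly over time.

    Inside ``folding_domain`` the Brillouin shift ramps from the base value
    at the first timepoint to ``base + delta_shift_ghz`` at the last; voxels
    outside the mask are time-invariant.  A matched fluorescence channel
    carries the mask geometry at a finer xy pixel size (``fluorescence_scale``
    times the Brillouin sampling), emulating the SPIM camera used for
    image-guided analysis.
    """
    if base.has_time:
        raise InvalidParameterError("base phantom must not already have a time axis")
    if delta_shift_ghz < 0:
        raise InvalidParameterError("delta_shift must be non-negative")
    mask = np.asarray(folding_domain, dtype=bool)
    if mask.shape != base.grid_shape:
        raise InvalidParameterError(
            f"mask shape {mask.shape} does not match phantom grid {base.grid_shape}"
        )
    t = np.asarray(timepoints_min, dtype=float)
    if t.size < 1:
        raise InvalidParameterError("need at least one timepoint")
    span = t[-1] - t[0]
    ramp = np.zeros_like(t) if span == 0 else (t - t[0]) / span

    nx, ny, nz = base.grid_shape
    fluo_shape = (
        int(np.floor(nx * fluorescence_scale)),
        int(np.floor(ny * fluorescence_scale)),
        nz,
    )
    mask_fluo = resize(
        mask.astype(float), fluo_shape, order=1, mode="edge", anti_aliasing=False
    )
    shift_t = np.empty((t.size, nx, ny, nz))
    fluo_t = np.empty((t.size,) + fluo_shape)
    for i, r in enumerate(ramp):
        shift_t[i] = base.shift_ghz + delta_shift_ghz * r * mask
        fluo_t[i] = mask_fluo  # geometry is static; intensity marks the domain
    vx, vy, vz = base.voxel_size_um
    return Phantom(
        shift_ghz=shift_t,
        linewidth_ghz=np.broadcast_to(base.linewidth_ghz, shift_t.shape).copy(),
        rayleigh_reflectivity=np.broadcast_to(
            base.rayleigh_reflectivity, shift_t.shape
        ).copy(),
        voxel_size_um=base.voxel_size_um,
        timepoints_min=t,
        fluorescence=fluo_t,
        fluorescence_pixel_um=(vx / fluorescence_scale, vy / fluorescence_scale),
    )


def phantom_line_materials(
    phantom: Phantom, y: int, z: int, t: int | None = None
) -> list[Material]:
    """Materials along the illumination line at scan position (y, z[, t])."""
    idx = (slice(None), y, z) if t is None else (t, slice(None), y, z)
    shifts = phantom.shift_ghz[idx]
    widths = phantom.linewidth_ghz[idx]
    refl = phantom.rayleigh_reflectivity[idx]
    return [
        Material(shift=float(s), linewidth=float(w), reflectivity=float(r))
        for s, w, r in zip(shifts, widths, refl)
    ]
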