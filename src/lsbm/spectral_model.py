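"""Domain types and closed-form spectral models.

Conventions used throughout the package:

* Frequencies are signed GHz relative to the laser line.  The Stokes peak of
  a sample with Brillouin shift ``nu_B`` sits at ``-nu_B``, the anti-Stokes
  peak at ``+nu_B``.  Precision metrics are reported in MHz.
* Intensities are photon/camera counts.
* A Lorentzian of amplitude ``A``, center ``c`` and full width at half
  maximum ``w`` is ``A * (w/2)**2 / ((nu - c)**2 + (w/2)**2)``: ``A`` is the
  peak height, not the area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import voigt_profile

from .errors import ConfigurationError, InvalidParameterError

__all__ = [
    "GeometryConfig",
    "PeakModel",
    "InstrumentKernel",
    "NotchConfig",
    "CameraConfig",
    "SpectrometerConfig",
    "lorentzian_profile",
    "broadened_brillouin_profile",
    "brillouin_shift_physics",
]

GAUSSIAN_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeometryConfig:
    """Scattering geometry of the microscope.

    ``scattering_angle`` is the angle between illumination and detection
    wavevectors in degrees: 180 for the epi-line (backscattering) geometry,
    90 for the orthogonal-line geometry where the probed phonon runs at 45
    degrees to both beams.
    """

    scattering_angle: float = 180.0
    wavelength_nm: float = 780.24
    refractive_index: float = 1.33
    sound_velocity: float = 1490.0  # m/s, water-like phantom default

    def __post_init__(self) -> None:
        if not 0.0 < self.scattering_angle <= 180.0:
            raise InvalidParameterError(
                f"scattering_angle must be in (0, 180] deg, got {self.scattering_angle}"
            )
        if self.wavelength_nm <= 0:
            raise InvalidParameterError("wavelength must be positive")
        if self.refractive_index < 1.0:
            raise InvalidParameterError("refractive_index must be >= 1")
        if self.sound_velocity <= 0:
            raise InvalidParameterError("sound_velocity must be positive")


@dataclass(frozen=True)
class PeakModel:
    """A fitted or prescribed spectral peak.

    ``kind`` selects the line-shape family: a plain Lorentzian, a Lorentzian
    on a quadratic background, or a Brillouin line broadened by the
    instrument response.  ``background`` holds polynomial baseline
    coefficients (constant first), empty for a pure peak.
    """

    kind: str = "lorentzian"
    amplitude: float = 1.0  # counts, peak height of the underlying Lorentzian
    center: float = 0.0  # GHz
    fwhm: float = 0.3  # GHz
    background: tuple[float, ...] = ()

    _KINDS = ("lorentzian", "quadratic_background", "broadened_brillouin")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise InvalidParameterError(f"unknown peak kind {self.kind!r}")
        if self.fwhm <= 0:
            raise InvalidParameterError(f"fwhm must be positive, got {self.fwhm}")
        if self.amplitude < 0:
            raise InvalidParameterError("amplitude must be non-negative")


@dataclass(frozen=True)
class InstrumentKernel:
    """Instrument/NA broadening kernel applied to the intrinsic Lorentzian.

    ``kind='gaussian'`` with ``sigma`` in GHz models the combined effect of
    the finite VIPA resolution and illumination NA; ``kind='delta'`` disables
    broadening.  The kernel always integrates to one, so it conserves the
    area of the line it broadens.
    """

    kind: str = "gaussian"
    sigma: float = 0.297  # GHz; Gaussian FWHM ~0.7 GHz

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "delta"):
            raise InvalidParameterError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "gaussian" and self.sigma < 0:
            raise InvalidParameterError("kernel sigma must be non-negative")

    @property
    def effective_sigma(self) -> float:
        return 0.0 if self.kind == "delta" else self.sigma

    @property
    def fwhm(self) -> float:
        return GAUSSIAN_FWHM_PER_SIGMA * self.effective_sigma


@dataclass(frozen=True)
class NotchConfig:
    """Rubidium-vapor notch filter rejecting the elastic (Rayleigh) line.

    Transmission is ``exp(-od * g(nu))`` with ``g`` a unit-peak Gaussian
    (Doppler) absorption profile at each configured line center.  An optical
    depth of ``ln(1e8) ~ 18.42`` yields 80 dB suppression at line center.
    """

    line_centers: tuple[float, ...] = (0.0,)  # GHz relative to laser
    optical_depth: float = math.log(1e8)
    doppler_fwhm: float = 0.55  # GHz, Rb vapor at ~100 C

    def __post_init__(self) -> None:
        if self.optical_depth < 0:
            raise InvalidParameterError("optical_depth must be non-negative")
        if self.doppler_fwhm <= 0:
            raise InvalidParameterError("doppler_fwhm must be positive")

    @property
    def center_suppression_db(self) -> float:
        """Suppression at line center in dB (10*log10 of intensity ratio)."""
        return 10.0 * self.optical_depth / math.log(10.0)


@dataclass(frozen=True)
class CameraConfig:
    """EMCCD-like camera: Poisson photons x gain, Gaussian read noise."""

    read_noise: float = 2.0  # counts rms
    gain: float = 1.0  # counts per photon
    full_well: float = 65535.0  # counts
    exposure: float = 0.1  # s

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise InvalidParameterError("gain must be positive")
        if self.read_noise < 0:
            raise InvalidParameterError("read_noise must be non-negative")


@dataclass(frozen=True)
class SpectrometerConfig:
    """VIPA spectrometer geometry and sampling.

    The VIPA replicates the spectrum across diffraction orders spaced by one
    free spectral range (``fsr``).  Within each order the pixel offset from
    the order's Rayleigh anchor follows
    ``dp(nu) = (nu / spectral_sampling) * (1 + dispersion_nonlinearity * nu / fsr)``,
    i.e. linear with an optional dimensionless quadratic correction.
    """

    fsr: float = 15.15  # GHz
    n_orders_visible: int = 3
    spectral_sampling: float = 0.35  # GHz per pixel
    spatial_sampling: float = 0.7  # um per pixel along the line
    dispersion_nonlinearity: float = 0.0
    instrument_kernel: InstrumentKernel = field(default_factory=InstrumentKernel)
    notch: NotchConfig = field(default_factory=NotchConfig)
    camera: CameraConfig = field(default_factory=CameraConfig)
    rayleigh_intrinsic_fwhm: float = 0.001  # GHz; laser linewidth scale

    def __post_init__(self) -> None:
        if self.fsr <= 0:
            raise InvalidParameterError("fsr must be positive")
        if not 0.1 <= self.spectral_sampling <= 1.0:
            raise InvalidParameterError(
                f"spectral_sampling must lie in [0.1, 1] GHz/px, got {self.spectral_sampling}"
            )
        if self.n_orders_visible < 1:
            raise InvalidParameterError("n_orders_visible must be >= 1")
        if self.spatial_sampling <= 0:
            raise InvalidParameterError("spatial_sampling must be positive")

    # --- derived pixel layout -------------------------------------------
    @property
    def order_pitch_px(self) -> float:
        """Pixel spacing between Rayleigh anchors of adjacent orders."""
        return self.fsr / self.spectral_sampling

    @property
    def first_anchor_px(self) -> float:
        # leave a half-window plus margin before the first anchor so the
        # full (-FSR/2, +FSR/2) window of every order is on the detector
        return 0.5 * self.order_pitch_px + 4.0

    @property
    def anchor_positions_px(self) -> np.ndarray:
        return self.first_anchor_px + self.order_pitch_px * np.arange(
            self.n_orders_visible
        )

    @property
    def n_pixels(self) -> int:
        last = self.anchor_positions_px[-1]
        return int(math.ceil(last + 0.5 * self.order_pitch_px + 4.0))

    def without_notch(self) -> "SpectrometerConfig":
        return replace(self, notch=replace(self.notch, optical_depth=0.0))


# ---------------------------------------------------------------------------
# line shapes
# ---------------------------------------------------------------------------

def lorentzian_profile(freq_grid, amplitude: float, center: float, fwhm: float):
    """Lorentzian peak of height ``amplitude`` evaluated on ``freq_grid``.

    Returns ``A * (w/2)^2 / ((nu - c)^2 + (w/2)^2)``; the profile reaches
    ``A`` at the center and ``A/2`` at ``c +/- w/2``.
    """
    if fwhm <= 0:
        raise InvalidParameterError(f"fwhm must be positive, got {fwhm}")
    if amplitude < 0:
        raise InvalidParameterError("amplitude must be non-negative")
    nu = np.asarray(freq_grid, dtype=float)
    hwhm_sq = (0.5 * fwhm) ** 2
    return amplitude * hwhm_sq / ((nu - center) ** 2 + hwhm_sq)


def voigt_peak(freq_grid, amplitude: float, center: float, fwhm: float, sigma: float):
    """Lorentzian (height ``amplitude``, FWHM ``fwhm``) convolved with a
    unit-area Gaussian of standard deviation ``sigma``.

    Closed form via the Voigt function; reduces to :func:`lorentzian_profile`
    as ``sigma -> 0``.  ``amplitude`` remains the height of the *underlying*
    Lorentzian (the convolved peak is lower and wider).
    """
    if fwhm <= 0:
        raise InvalidParameterError(f"fwhm must be positive, got {fwhm}")
    nu = np.asarray(freq_grid, dtype=float)
    gamma = 0.5 * fwhm
    if sigma <= 0:
        return lorentzian_profile(nu, amplitude, center, fwhm)
    # Lorentzian area = A * pi * gamma; Voigt is the unit-area convolution
    area = amplitude * math.pi * gamma
    return area * voigt_profile(nu - center, sigma, gamma)


def broadened_brillouin_profile(
    freq_grid,
    amplitude: float,
    center: float,
    intrinsic_fwhm: float,
    instrument_kernel: InstrumentKernel | None = None,
    *,
    analytic: bool = True,
):
    """Brillouin line shape: intrinsic Lorentzian broadened by the instrument.

    With the default Gaussian kernel the result is a Voigt profile computed
    in closed form.  With ``analytic=False`` the convolution is carried out
    numerically on the (uniform) working grid, which also supports future
    non-Gaussian kernels; a delta kernel returns the plain Lorentzian either
    way.

    Parameters
    ----------
    freq_grid : array
        Uniform frequency grid in GHz (uniformity is required only for the
        numerical path).
    amplitude, center, intrinsic_fwhm :
        Height, position (GHz) and FWHM (GHz) of the underlying Lorentzian.
    instrument_kernel :
        Unit-area broadening kernel; defaults to the package-default Gaussian.
    """
    if intrinsic_fwhm <= 0:
        raise InvalidParameterError("intrinsic_fwhm must be positive")
    kernel = InstrumentKernel() if instrument_kernel is None else instrument_kernel
    nu = np.asarray(freq_grid, dtype=float)
    sigma = kernel.effective_sigma
    if sigma == 0.0:
        return lorentzian_profile(nu, amplitude, center, intrinsic_fwhm)
    if analytic:
        return voigt_peak(nu, amplitude, center, intrinsic_fwhm, sigma)

    # numerical convolution on the working grid
    if nu.size < 2:
        raise ConfigurationError("numerical convolution needs a grid of >= 2 samples")
    df = float(nu[1] - nu[0])
    if not np.allclose(np.diff(nu), df, rtol=1e-8, atol=1e-12):
        raise ConfigurationError("numerical convolution requires a uniform grid")
    half_width = 5.0 * sigma
    if 2 * half_width >= nu[-1] - nu[0]:
        raise ConfigurationError(
            "instrument kernel wider than the frequency grid span"
        )
    n_half = int(math.ceil(half_width / df))
    k_ax = df * np.arange(-n_half, n_half + 1)
    kernel_vals = np.exp(-0.5 * (k_ax / sigma) ** 2)
    kernel_vals /= kernel_vals.sum()
    # pad so tails entering from outside the grid are represented
    pad_ax_lo = nu[0] + df * np.arange(-n_half, 0)
    pad_ax_hi = nu[-1] + df * np.arange(1, n_half + 1)
    padded_ax = np.concatenate([pad_ax_lo, nu, pad_ax_hi])
    padded = lorentzian_profile(padded_ax, amplitude, center, intrinsic_fwhm)
    return np.convolve(padded, kernel_vals, mode="valid")


# ---------------------------------------------------------------------------
# scattering physics
# ---------------------------------------------------------------------------

def brillouin_shift_physics(geometry: GeometryConfig) -> float:
    """Expected Brillouin shift in GHz for a given scattering geometry.

    ``nu_B = 2 n V sin(theta/2) / lambda``: the phonon wavevector probed is
    set by the angle between illumination and detection, so backscattering
    (theta=180) maximizes the shift and the orthogonal geometry (theta=90)
    scales it by sin(45) = 1/sqrt(2).
    """
    theta = math.radians(geometry.scattering_angle)
    lam_m = geometry.wavelength_nm * 1e-9
    shift_hz = (
        2.0
        * geometry.refractive_index
        * geometry.sound_velocity
        * math.sin(0.5 * theta)
        / lam_m
    )
    return shift_hz / 1e9
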