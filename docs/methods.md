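# Methods

## Forward model of the spectrometer

The simulator renders one spectrum per point of the illumination line.  In
the frequency coordinate of VIPA order *k* (signed GHz, zero at that
order's Rayleigh anchor) the expected photon count is

    I_k(ν) = Σ_{m∈{-1,0,+1}} S(ν + m·FSR)

where *S* is the instrument-broadened, notch-filtered source spectrum on
the true-frequency axis.  The ±1 replicas are the tails of peaks belonging
to adjacent orders; truncating at |m| ≤ 1 is exact to the level of
second-order Lorentzian tails (≲10⁻⁴ of a peak at one FSR distance).  The
source spectrum consists of the elastic Rayleigh line at 0 GHz and the
Stokes/anti-Stokes Brillouin doublet at ∓ν_B, each an intrinsic Lorentzian
convolved with the Gaussian instrument kernel (evaluated in closed form as
a Voigt profile).

Pixels map to order frequencies through
`dp(ν) = (ν/s)(1 + b·ν/FSR)` with `s` the sampling in GHz/px and `b` a
dimensionless quadratic nonlinearity (0 by default).  Order anchors repeat
with a constant pixel pitch of `FSR/s`; the model assumes this pitch is the
same for all visible orders, which is also what the linear remapping of the
reconstruction assumes.

**Notch.**  The Rb-vapor cell transmits `exp(-OD·g(ν))` with `g` a
unit-peak Gaussian (Doppler) profile.  The elastic line is five orders of
magnitude narrower than the notch, so its attenuation is evaluated at its
line center *before* instrument broadening — this is why a strong notch
suppresses the Rayleigh line even though the instrument smears it over
±1 GHz on the camera.  The Brillouin peaks sit several GHz outside the
notch; they are attenuated at the detected frequency, which only touches
their far tails near 0 GHz, well outside every fit range.

**Noise.**  Per pixel: Poisson photon statistics, multiplied by the camera
gain, plus additive Gaussian read noise, clipped at the full well.  The
EM-register excess-noise factor of an electron-multiplying camera is not
modeled.  Every random stream is an explicit seed or `numpy` generator;
frames are bit-reproducible from (config, phantom, seed), and each row of a
frame draws from an independent child stream.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| FSR | 15.15 GHz | VIPA free spectral range of the modeled instrument |
| spectral sampling | 0.35 GHz/px | middle of the instrument's 0.25–0.5 GHz/px range |
| spatial sampling | 0.7 µm/px | line sampling of the modeled instrument |
| visible orders | 3 | minimum summed by the reconstruction |
| instrument kernel | Gaussian, σ = 0.297 GHz (0.7 GHz FWHM) | typical VIPA spectral resolution; sets the measured Rayleigh width |
| notch | OD = ln 10⁸ (80 dB), Doppler FWHM 0.55 GHz | Rb vapor near 100 °C; 80 dB elastic suppression |
| camera | gain 1 count/photon, read noise 2 counts rms, 0.1 s exposure | counts ≈ photons so the shot-noise budget is explicit |
| water phantom | ν_B = 5.05 GHz, Γ_B = 0.4 GHz, reflectivity 10⁶ | water at 780 nm in backscattering; elastic/inelastic ratio before the notch |
| fit ranges | ±[2.0, FSR/2 − 0.4] GHz | excludes the notch region and the order edges; user-overridable |
| remap grid | 0.1 GHz/sample | fine enough that grid quantization is ≪1 MHz |
| fit tolerances | rel. 10⁻⁸, ≤100 iterations | makes ≤1 MHz center accuracy attainable |
| validity | convergence + center off the range edge + R² ≥ 0.5 | invalid voxels become NaN, never zeros |

## Reconstruction and fitting

Each camera row is processed independently (the batch path is the per-row
path in a loop, so results are invariant to row order and batch size).
Per order, intensities at integer pixels are interpolated onto the common
signed-frequency grid with a cubic spline; samples that coincide with
source pixels pass through unchanged, and samples outside an order's
coverage are NaN and flag truncation.  Orders are summed sample-wise in
extended precision so summation is exactly permutation-invariant.

Stokes and anti-Stokes peaks are fitted separately by bounded least
squares (`scipy.optimize.least_squares`) with amplitude, center, width and
a polynomial baseline free; initialization is argmax/half-range/max-minus-
baseline.  Three line-shape families are available: plain Lorentzian,
Lorentzian on a quadratic background, and the instrument-broadened
Brillouin shape (Voigt with the kernel σ fixed).  The broadened model is
the default because it matches the line shape the simulated (and real)
spectrometer actually produces.  A practical caveat found while validating
the fitter: a *pure* Lorentzian of Γ ≈ 0.4 GHz sampled at ≳0.4 GHz/sample
leaves the 4-parameter fit quasi-degenerate (3–4 informative samples), with
center errors up to tens of MHz even at negligible noise; the broadened
model (effective FWHM ≈ 0.93 GHz) is well-conditioned over the whole
0.25–0.5 GHz sampling range, with mean center error ≈ 0.1 MHz at high
signal.

The reported Brillouin shift is `(|c_S| + |c_AS|)/2` and the linewidth the
mean of the two FWHMs; if exactly one fit is valid its magnitude is used
and flagged.  SNR is the amplitude convention, `20·log₁₀(peak height /
residual sd over the fit range)`, with `+inf` for a zero-residual fit; the
convention is recorded so the power convention can be reconstructed.

## Calibration

Anchors are the most periodic subset of prominence-ranked maxima (VIPA
orders repeat with constant pitch, which rejects satellite and Brillouin
peaks), refined by 3-point parabolic interpolation of the log intensity —
exact for Gaussian-topped peaks.  Calibration frames are simulated with
the notch disabled so the 0 GHz line is visible; the 0 GHz (laser-lock)
line is rendered brighter than the other reference lines, mirroring the
dominance of the elastic line in a real calibration image.  Reference
satellites pair with the nearest anchor *below* them and, within an order,
sorted positions pair with sorted reference frequencies; orders with an
incomplete satellite set are skipped rather than risk mispairing.  The
dispersion (GHz/px, plus optional quadratic term) comes from the reference
offsets, the pitch from a least-squares line through anchor-vs-order-index,
and FSR = pitch/dispersion — so the FSR estimate is invariant under a
uniform pixel shift of all anchors.

The shipped ⁸⁷Rb D₂ constants (ground-state splitting 6.834682610904 GHz,
excited-state intervals 72.218/156.947/266.650 MHz) come from the standard
atomic-physics compilation of rubidium line data.  The default line set is
{0, 6.8347} GHz: at the default 0.7 GHz spectral resolution the
excited-state satellites (≈0.27 GHz apart) are not resolvable, so the
extended set is only useful in high-resolution configurations (it is what
constrains the quadratic dispersion term in the tests).

## Quantification conventions

0-based indices; x along the illumination line, y the light-sheet scan
axis, z depth.  Rescaling to the fluorescence grid uses bilinear
interpolation with output size `floor(input × scale)` (scale 2.5138 by
default) and nearest-neighbor resampling of validity masks.  Overlay
registration is offset-based: the y offset centers the fluorescence field
(half its diameter, 450 px by default), the x offset is a user-supplied
landmark shift — no automatic registration is attempted, matching the
manual alignment step of the imaging workflow.  Median projections ignore
invalid voxels (median of an even count = mean of the central pair); ROI
statistics are mean ± sd or median + IQR (linear-interpolation quantiles)
over valid masked voxels only.  Relative time series subtract the central
statistic at the reference timepoint; dispersions are untouched.

## Simulated study conditions and problem sizes

The characterization suites run at desk scale, chosen so each quantity's
sampling error is small against its tolerance:

* **Precision**: 50 water frames of 16 line positions each (the center-of-
  field selection of a longer line), photon budget auto-tuned so the
  per-frame fitted SNR ratio is ≈10, full calibrate→remap→sum→fit per row,
  per-frame shift = mean over valid rows.  The tuning exploits that the
  fitted amplitude-to-residual ratio scales as √budget.
* **Fit accuracy**: 200 spectra, centers uniform in [4.5, 5.5] GHz,
  sampling uniform in [0.25, 0.5] GHz/sample, Poisson noise at 10⁶ photons
  peak (shot-noise contribution ≪ 0.5 MHz).
* **Shot-noise scaling**: budgets 30–1000 photons (1.5 decades), 32
  repeats each; log–log slope of precision vs budget.
* **End-to-end phantom**: 20×4×2 voxel embryo-like phantom, 3 timepoints,
  15 MHz ramp in a masked folding domain, budget 2000; recovery via the
  fluorescence-guided path (rescale → overlay → masked mean → relative
  series).

## What the phantom does and does not emulate

The generator reproduces the *spectroscopic* physics — dispersion, notch,
shot noise, order structure — with exactly known per-voxel ground truth.
It does not model optical aberrations, sample-induced scattering or
absorption, refractive-index heterogeneity, fluorescence photophysics, or
focal-sweep synchronization; the fluorescence channel carries only the
mask geometry at SPIM pixel size.  Passing tests therefore demonstrate the
correctness and statistical efficiency of the analysis pipeline under
shot-noise-limited conditions, not robustness to the optical artifacts of
real tissue.

## Known limitations

* The per-order pixel pitch is assumed constant across visible orders (the
  true VIPA pitch drifts slowly with order index); with the quadratic
  dispersion term enabled the replica hand-off at order boundaries is
  approximate at the window edges, outside the fit ranges.
* The notch is applied at the detected frequency for the inelastic
  components (exact only for the narrow elastic line); the error is
  confined to Brillouin tails inside the notch, outside every fit range.
* Linewidth estimates from the broadened model are accurate only insofar
  as the kernel σ is known; a mismatched σ biases Γ_B (but not the center,
  for symmetric kernels).
* EM excess noise and camera quantization are not modeled; counts are
  real-valued.
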