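# lsbm — line-scan Brillouin microscopy spectral analysis

Brillouin microscopy probes the mechanical (viscoelastic) properties of
living samples without labels or contact: light scattered off thermally
excited acoustic phonons is shifted in frequency by the Brillouin shift
ν<sub>B</sub> = 2 n V sin(θ/2)/λ (a few GHz for water and soft tissue) and
broadened by the Brillouin linewidth Γ<sub>B</sub>.  A line-scan instrument
disperses the light from an entire illumination line through a VIPA
(virtually imaged phased array) etalon, producing a camera frame with one
spectrum per spatial point, replicated across diffraction orders spaced by
the free spectral range (FSR).  A rubidium-vapor cell notch-suppresses the
elastic (Rayleigh) line, and the laser is locked to the ⁸⁷Rb D₂ transition,
whose hyperfine components double as calibration frequency references.

This package implements the spectral-analysis pipeline of such an
instrument, for microscopists and method developers who need to go from raw
spectrometer frames to quantitative Brillouin shift maps:

1. **Calibration** — detect the per-order Rayleigh anchor pixels, fit the
   pixel→GHz dispersion against Rb D₂ reference lines, and recover the FSR.
2. **Reconstruction** — remap each spectrum onto a linear frequency axis by
   cubic-spline interpolation (the remapping depends only on the Rayleigh
   anchor and the FSR), sum ≥3 VIPA orders to raise the effective SNR, and
   fit the Stokes and anti-Stokes peaks separately by least squares with
   Lorentzian / instrument-broadened line shapes.  The reported shift is the
   average of the two fitted center magnitudes.
3. **Quantification** — assemble per-line measurements into 3D/4D shift
   volumes, rescale and register them onto fluorescence (SPIM) images,
   median-project re-sliced slabs, and compute mask-guided ROI statistics
   and relative time series.
4. **Simulation** — a physics-based forward model of the spectrometer
   (multi-order VIPA dispersion, Rb notch, Poisson shot noise + camera
   gain/read noise) plus embryo-like time-lapse phantoms with a "folding
   domain" of locally elevated shift, so every stage is testable with known
   ground truth and no hardware.

## Worked example

Simulate two 8-row water frames and a calibration frame, calibrate,
and reconstruct:

```sh
$ lsbm simulate --out water.h5 --calibration-out cal.h5 \
      --n-frames 2 --rows 8 --photon-budget 2000
$ lsbm calibrate --frame cal.h5 --out calibration.json
INFO lsbm: FSR 15.1500 GHz, residual rms 1.60e-05 GHz
$ lsbm reconstruct --frames water.h5 --calibration calibration.json \
      --out-csv rows.csv --out-volume map.h5
$ head -3 rows.csv
row,shift_GHz,linewidth_GHz,amplitude_counts,snr_dB,r_squared,n_iterations,valid
0,5.054676617278888,0.42006290573551464,3096.265557045147,49.560060261232124,0.9998734671904831,12,True
1,5.05588162161288,0.4031165345053269,3192.0833446667225,43.9471485669869,0.9995656524329379,11,True
```

The recovered FSR matches the configured 15.15 GHz to ~6 µGHz on a
noiseless calibration frame.  Each CSV row is one point along the
illumination line: the fitted Brillouin shift (water: 5.05 GHz ground
truth), linewidth, Stokes peak amplitude, SNR in dB (20·log₁₀ of the
fitted amplitude over the residual standard deviation), goodness of fit and
iteration count.  At a photon budget of 2000 the per-spectrum scatter is a
few MHz, consistent with shot-noise-limited operation.

The same steps are available as library calls
(`lsbm.simulate_frame`, `lsbm.calibrate_frame`, `lsbm.process_frame`, ...),
and `lsbm characterize` runs the precision / spectral-resolution / bead-PSF
suites in one go.

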