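# File formats

All counts and GHz quantities are stored as 64-bit floats; round trips are
lossless.

## Frame stacks

* **TIFF** (`.tif`/`.tiff`): one page per frame, shape (rows, spectral
  pixels), float64 counts.
* **HDF5** (`.h5`/`.hdf5`):
  * `/frames` — (n_frames, rows, spectral pixels) float64, attribute
    `exposure_s`;
  * `/truth/*` — optional simulator ground-truth datasets (e.g.
    `shift_ghz`, `anchor_px`), one dataset per field.

## Calibration model (JSON)

```json
{
  "order_anchors_px": [25.64, 68.93, 112.21],
  "fsr": 15.15,
  "c1_px_per_ghz": 2.857,
  "c2_px_per_ghz2": 0.0,
  "residual_rms_ghz": 1.6e-05,
  "metadata": {"reference_lines_ghz": [0.0, 6.834682610904]}
}
```

`pixel - anchor[k] = c1·ν + c2·ν²` maps order *k*'s pixels to signed GHz.

## Shift volumes (HDF5)

* `/maps/shift`, `/maps/linewidth`, `/maps/snr` — float64 grids (GHz, GHz,
  dB); invalid voxels are NaN in `shift`;
* `/maps/valid` — uint8 (0/1);
* attributes: `voxel_size_um` (x, y, z triplet), `geometry`
  (`O-LSBM`/`E-LSBM`), optional `timepoints_min`, optional
  `calibration_json` (embedded provenance).

## Tables (CSV)

* Per-row measurements: `row, shift_GHz, linewidth_GHz, amplitude_counts,
  snr_dB, r_squared, n_iterations, valid`.
* ROI time series: `timepoint_min, stat_GHz, dispersion_GHz, n_voxels`
  (for median+IQR the dispersion column is the IQR half-width).
* Reference lines (input to `lsbm calibrate`): column `frequency_GHz`,
  optional `label`.

## Masks

Label TIFF; any non-zero pixel is inside the ROI.

## Run configuration (YAML)

Schema-validated (unknown keys are rejected).  All keys optional; defaults
shown:

```yaml
spectrometer:
  fsr: 15.15
  n_orders_visible: 3
  spectral_sampling: 0.35      # GHz per pixel
  spatial_sampling: 0.7        # um per pixel
  dispersion_nonlinearity: 0.0
  instrument_kernel: {kind: gaussian, sigma: 0.297}
  notch: {line_centers: [0.0], optical_depth: 18.42, doppler_fwhm: 0.55}
  camera: {read_noise: 2.0, gain: 1.0, full_well: 65535.0, exposure: 0.1}
geometry:
  scattering_angle: 180.0      # degrees; 90 for the orthogonal geometry
  wavelength_nm: 780.24
  refractive_index: 1.33
  sound_velocity: 1490.0       # m/s
fit:
  model_kind: broadened_brillouin
  fit_range_lo: 2.0            # GHz; hi defaults to FSR/2 - margin
  target_df: 0.1               # GHz per remapped sample
  min_orders: 3
  instrument_sigma: 0.297
  r2_threshold: 0.5
registration:
  xy_scale: 2.5138
  y_offset: 450
  x_offset: 0
seed: 0
log_level: INFO
```
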