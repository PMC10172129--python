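"""Shared fixtures: default spectrometer, calibration model, water frames."""

from __future__ import annotations

import numpy as np
import pytest

from lsbm import rb_d2
from lsbm.calibration import calibrate_frame
from lsbm.simulator import WATER, simulate_calibration_frame, simulate_frame
from lsbm.spectral_model import SpectrometerConfig


@pytest.fixture(scope="session")
def spec_config() -> SpectrometerConfig:
    return SpectrometerConfig()


@pytest.fixture(scope="session")
def calib(spec_config):
    """Calibration model fitted to a noiseless Rb D2 calibration frame."""
    frame = simulate_calibration_frame(
        spec_config, rb_d2.DEFAULT_REFERENCE_LINES_GHZ
    )
    return calibrate_frame(
        frame, rb_d2.DEFAULT_REFERENCE_LINES_GHZ,
        expected_orders=spec_config.n_orders_visible,
    )


@pytest.fixture()
def water_frame_factory(spec_config):
    """Factory for noisy homogeneous water frames."""

    def make(n_rows: int = 4, photon_budget: float = 2000.0, seed: int = 0):
        return simulate_frame(
            [WATER] * n_rows, spec_config, photon_budget, rng_seed=seed
        )

    return make


@pytest.fixture(scope="session")
def noiseless_water_row(spec_config) -> np.ndarray:
    from lsbm.simulator import simulate_row_spectrum

    return simulate_row_spectrum(WATER, spec_config, 1e5)["noiseless"]
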