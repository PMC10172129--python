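"""Published frequency constants of the 87Rb D2 line (780.24 nm).

The spectrometer is calibrated against hyperfine components of the 87Rb D2
transition, whose splittings are known to sub-kHz accuracy from atomic
spectroscopy.  The laser is locked to the D2 line, so calibration line
frequencies are expressed in GHz relative to the laser frequency.

Values follow the standard compilation of 87Rb D2 data (Steck, "Rubidium 87
D Line Data"); only differences between hyperfine components matter here, so
the absolute optical frequency is never needed.
"""

from __future__ import annotations

# 5S1/2 ground-state hyperfine splitting, F=1 <-> F=2 (GHz).  This is the
# dominant, exactly known interval used to set the frequency scale.
GROUND_STATE_SPLITTING_GHZ: float = 6.834682610904

# 5P3/2 excited-state hyperfine intervals (GHz): F'=0->1, 1->2, 2->3.
EXCITED_STATE_INTERVALS_GHZ: tuple[float, float, float] = (
    0.0722180,
    0.1569470,
    0.2666500,
)

# Default calibration line set: the lock line itself (0 GHz) plus the line
# reached by hopping the ground-state splitting.  Two lines of exactly known
# separation are the minimum needed to fix GHz-per-pixel.
DEFAULT_REFERENCE_LINES_GHZ: tuple[float, ...] = (
    0.0,
    GROUND_STATE_SPLITTING_GHZ,
)

# Extended set adding components displaced by excited-state intervals,
# useful when a quadratic dispersion term must be constrained.
EXTENDED_REFERENCE_LINES_GHZ: tuple[float, ...] = (
    0.0,
    GROUND_STATE_SPLITTING_GHZ - EXCITED_STATE_INTERVALS_GHZ[2],
    GROUND_STATE_SPLITTING_GHZ,
    GROUND_STATE_SPLITTING_GHZ + EXCITED_STATE_INTERVALS_GHZ[1],
)
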