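"""Spectrometer calibration: Rayleigh anchors, FSR, pixel->GHz mapping.

The remapping of a VIPA spectrum depends only on the pixel position of the
Rayleigh (elastic) line in each diffraction order and on the free spectral
range.  Calibration therefore consists of (1) locating the per-order anchor
pixels with sub-pixel precision, (2) fixing the GHz-per-pixel dispersion from
reference lines of exactly known frequency (the Rb D2 hyperfine components),
and (3) reading the FSR off the anchor pitch expressed in frequency units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    CalibrationInsufficiencyError,
    DetectionError,
    RangeError,
    RankDeficiencyError,
)
from .simulator import SpectralFrame

__all__ = [
    "CalibrationModel",
    "detect_order_anchors",
    "detect_reference_peaks",
    "fit_dispersion",
    "calibrate_frame",
    "pixel_to_frequency",
    "frequency_to_pixel",
]


@dataclass
class CalibrationModel:
    """Per-order pixel->frequency mapping anchored on the Rayleigh line.

    Within order ``k`` the signed frequency ``nu`` (GHz relative to the laser
    line, 0 exactly at the anchor) satisfies
    ``pixel - anchor[k] = c1 * nu + c2 * nu**2``.
    ``fsr`` is the anchor pitch converted to frequency, ``residual_rms_ghz``
    the rms misfit of the calibration input expressed in GHz.
    """

    order_anchors_px: np.ndarray
    fsr: float
    c1_px_per_ghz: float
    c2_px_per_ghz2: float = 0.0
    residual_rms_ghz: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.order_anchors_px = np.asarray(self.order_anchors_px, dtype=float)
        if self.order_anchors_px.ndim != 1 or self.order_anchors_px.size < 1:
            raise RankDeficiencyError("need at least one order anchor")
        if np.any(np.diff(self.order_anchors_px) <= 0):
            raise RankDeficiencyError("order anchors must be strictly increasing")
        if self.fsr <= 0:
            raise RankDeficiencyError("fsr must be positive")
        if self.c1_px_per_ghz <= 0:
            raise RankDeficiencyError("dispersion c1 must be positive")

    @property
    def n_orders(self) -> int:
        return self.order_anchors_px.size

    def valid_pixel_range(self, order: int) -> tuple[float, float]:
        """Pixel interval of ``order`` covering (-FSR/2, +FSR/2)."""
        anchor = self.order_anchors_px[order]
        half = self.fsr / 2.0
        lo = anchor + self._offset(-half)
        hi = anchor + self._offset(half)
        return float(lo), float(hi)

    def _offset(self, nu):
        return self.c1_px_per_ghz * np.asarray(nu) + self.c2_px_per_ghz2 * np.asarray(nu) ** 2

    # --- serialization ---------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "order_anchors_px": self.order_anchors_px.tolist(),
                "fsr": self.fsr,
                "c1_px_per_ghz": self.c1_px_per_ghz,
                "c2_px_per_ghz2": self.c2_px_per_ghz2,
                "residual_rms_ghz": self.residual_rms_ghz,
                "metadata": self.metadata,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        d = json.loads(text)
        return cls(
            order_anchors_px=np.asarray(d["order_anchors_px"], dtype=float),
            fsr=float(d["fsr"]),
            c1_px_per_ghz=float(d["c1_px_per_ghz"]),
            c2_px_per_ghz2=float(d.get("c2_px_per_ghz2", 0.0)),
            residual_rms_ghz=float(d.get("residual_rms_ghz", 0.0)),
            metadata=d.get("metadata", {}),
        )


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def _parabolic_refine(row: np.ndarray, idx: int) -> float:
    """Sub-pixel peak position by 3-point parabolic interpolation of log counts."""
    if idx <= 0 or idx >= row.size - 1:
        return float(idx)
    triplet = row[idx - 1 : idx + 2].astype(float)
    if np.any(triplet <= 0):
        # fall back to linear-intensity parabola if log is undefined
        y0, y1, y2 = triplet
    else:
        y0, y1, y2 = np.log(triplet)
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:  # not a local max in the interpolant
        return float(idx)
    return float(idx + 0.5 * (y0 - y2) / denom)


def detect_order_anchors(
    frame_row: np.ndarray,
    expected_orders: int,
    min_prominence_frac: float = 0.05,
) -> np.ndarray:
    """Sub-pixel Rayleigh-anchor pixel positions, one per visible order.

    Candidate maxima are ranked by prominence; among the strongest
    candidates the subset of size ``expected_orders`` that best forms an
    arithmetic progression (VIPA orders repeat with a constant pixel pitch)
    is selected, which rejects satellite/Brillouin peaks.  Positions are
    refined by 3-point parabolic interpolation of the log intensity and
    returned sorted ascending.
    """
    row = np.asarray(frame_row, dtype=float)
    if row.ndim != 1:
        raise DetectionError("frame_row must be 1D")
    span = float(row.max() - row.min())
    if span <= 0:
        raise DetectionError("flat row: no peaks found", candidates=[])
    peaks, props = find_peaks(row, prominence=min_prominence_frac * span)
    if peaks.size < expected_orders:
        raise DetectionError(
            f"found {peaks.size} candidate peaks, expected {expected_orders}",
            candidates=peaks.tolist(),
        )
    # keep the strongest candidates, then pick the most periodic subset
    order_by_prom = np.argsort(props["prominences"])[::-1]
    n_keep = min(peaks.size, max(3 * expected_orders, expected_orders))
    cand = np.sort(peaks[order_by_prom[:n_keep]])
    if expected_orders == 1:
        best = (int(cand[np.argmax(row[cand])]),)
    else:
        best, best_cost = None, np.inf
        for subset in combinations(range(cand.size), expected_orders):
            pos = cand[list(subset)].astype(float)
            if expected_orders == 2:
                cost = 0.0
            else:
                k = np.arange(expected_orders)
                coeff = np.polyfit(k, pos, 1)
                cost = float(np.sqrt(np.mean((np.polyval(coeff, k) - pos) ** 2)))
            # prefer periodic subsets; among equally periodic ones, brighter
            cost -= 1e-6 * float(row[cand[list(subset)]].sum() / span)
            if cost < best_cost:
                best_cost, best = cost, tuple(int(c) for c in cand[list(subset)])
    refined = np.array([_parabolic_refine(row, i) for i in best])
    return np.sort(refined)


def detect_reference_peaks(
    frame_row: np.ndarray,
    anchors: np.ndarray,
    min_prominence_frac: float = 0.02,
    exclusion_px: float = 2.0,
) -> np.ndarray:
    """Sub-pixel positions of non-anchor (reference) peaks in a calibration row."""
    row = np.asarray(frame_row, dtype=float)
    span = float(row.max() - row.min())
    if span <= 0:
        raise DetectionError("flat row: no peaks found", candidates=[])
    peaks, _ = find_peaks(row, prominence=min_prominence_frac * span)
    out = []
    for p in peaks:
        if np.min(np.abs(anchors - p)) <= exclusion_px:
            continue
        out.append(_parabolic_refine(row, int(p)))
    return np.asarray(sorted(out))


# ---------------------------------------------------------------------------
# dispersion fit
# ---------------------------------------------------------------------------

def fit_dispersion(
    anchor_positions: np.ndarray,
    reference_lines,
    quadratic: bool = False,
    order_indices=None,
) -> CalibrationModel:
    """Least-squares FSR and pixel->GHz mapping from anchors + reference lines.

    ``anchor_positions`` are the per-order Rayleigh pixel positions;
    ``reference_lines`` is a sequence of ``(pixel, frequency_GHz)`` pairs for
    lines of known frequency (relative to the laser).  The anchor pitch gives
    the order spacing in pixels; the reference lines give GHz-per-pixel; the
    FSR is pitch/dispersion.  With ``quadratic`` a second-order dispersion
    term is included (needs >= 2 distinct non-zero reference frequencies).
    """
    anchors = np.sort(np.asarray(anchor_positions, dtype=float))
    refs = [(float(p), float(f)) for p, f in reference_lines]
    if anchors.size < 2:
        raise RankDeficiencyError(
            "need >= 2 order anchors to measure the inter-order pitch"
        )
    if np.any(np.diff(anchors) <= 0):
        raise RankDeficiencyError("anchor positions must be distinct")
    nonzero = [(p, f) for p, f in refs if f != 0.0]
    if not nonzero:
        raise RankDeficiencyError(
            "need at least one non-zero-frequency reference line to fix the "
            "frequency scale"
        )
    n_distinct = len({f for _, f in nonzero})
    if quadratic and n_distinct < 2:
        raise RankDeficiencyError(
            "quadratic dispersion needs >= 2 distinct non-zero reference lines"
        )

    # inter-order pitch: least-squares line through anchor vs order index
    # (order_indices allows non-adjacent orders, e.g. orders 0 and 2)
    k = (
        np.arange(anchors.size)
        if order_indices is None
        else np.asarray(sorted(order_indices), dtype=float)
    )
    if k.size != anchors.size:
        raise RankDeficiencyError("order_indices must match anchor count")
    pitch, intercept = np.polyfit(k, anchors, 1)
    anchor_resid_px = anchors - (pitch * k + intercept)

    # dispersion from reference offsets relative to the nearest anchor
    offs = np.array([p - anchors[np.argmin(np.abs(anchors - p))] for p, _ in nonzero])
    freqs = np.array([f for _, f in nonzero])
    cols = [freqs] if not quadratic else [freqs, freqs**2]
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, offs, rcond=None)
    c1 = float(coef[0])
    c2 = float(coef[1]) if quadratic else 0.0
    if c1 <= 0:
        raise RankDeficiencyError("fitted dispersion is non-positive; degenerate input")
    ref_resid_px = offs - design @ coef

    fsr = float(pitch / c1)
    resid_px = np.concatenate([anchor_resid_px, ref_resid_px])
    residual_rms_ghz = float(np.sqrt(np.mean(resid_px**2)) / c1)
    return CalibrationModel(
        order_anchors_px=anchors,
        fsr=fsr,
        c1_px_per_ghz=c1,
        c2_px_per_ghz2=c2,
        residual_rms_ghz=residual_rms_ghz,
        metadata={
            "n_reference_lines": len(refs),
            "quadratic": quadratic,
            "pitch_px": float(pitch),
        },
    )


def calibrate_frame(
    frame: SpectralFrame | np.ndarray,
    reference_lines_ghz,
    expected_orders: int,
    quadratic: bool = False,
    row: int | None = None,
) -> CalibrationModel:
    """End-to-end calibration from a calibration frame.

    Detects the per-order anchors (the 0 GHz line), locates the remaining
    reference peaks, pairs them order-by-order with the sorted non-zero
    reference frequencies, and fits the dispersion model.
    """
    lines = sorted(float(f) for f in reference_lines_ghz)
    if len(lines) < 2:
        raise CalibrationInsufficiencyError(
            f"calibration needs >= 2 reference lines, got {len(lines)}"
        )
    counts = frame.counts if isinstance(frame, SpectralFrame) else np.asarray(frame)
    if counts.ndim == 1:
        counts = counts[None, :]
    r = counts.shape[0] // 2 if row is None else row
    profile = counts[r]
    anchors = detect_order_anchors(profile, expected_orders)
    satellites = detect_reference_peaks(profile, anchors)
    nonzero = sorted(f for f in lines if f != 0.0)
    # Reference lines sit at a positive pixel offset from the anchor of their
    # own order; a satellite therefore pairs with the largest anchor below it.
    # Satellites below the first anchor (partial peaks of an off-detector
    # order) are discarded.  Within each order, sorted satellite positions
    # pair with sorted reference frequencies; orders with an incomplete
    # satellite set are skipped to avoid mispairing.
    pairs = [(float(a), 0.0) for a in anchors]
    per_order: dict[int, list[float]] = {}
    for s in satellites:
        if s <= anchors[0]:
            continue
        k = int(np.searchsorted(anchors, s, side="right") - 1)
        per_order.setdefault(k, []).append(float(s))
    for k, sats in per_order.items():
        if len(sats) == len(nonzero):
            pairs.extend(zip(sorted(sats), nonzero))
    model = fit_dispersion(anchors, pairs, quadratic=quadratic)
    model.metadata["reference_lines_ghz"] = lines
    return model


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

def pixel_to_frequency(
    calib: CalibrationModel, order: int, pixel, tolerance_px: float = 0.5
):
    """Signed GHz (relative to the laser line) of a fractional pixel position.

    Exactly 0 at the order's anchor.  Raises :class:`RangeError` when the
    pixel lies outside the order's valid (-FSR/2, +FSR/2) range by more than
    ``tolerance_px``.
    """
    if not 0 <= order < calib.n_orders:
        raise RangeError(f"order {order} out of range [0, {calib.n_orders})")
    p = np.asarray(pixel, dtype=float)
    lo, hi = calib.valid_pixel_range(order)
    if np.any(p < lo - tolerance_px) or np.any(p > hi + tolerance_px):
        raise RangeError(
            f"pixel outside order {order} valid range [{lo:.2f}, {hi:.2f}]"
        )
    dp = p - calib.order_anchors_px[order]
    c1, c2 = calib.c1_px_per_ghz, calib.c2_px_per_ghz2
    if c2 == 0.0:
        nu = dp / c1
    else:
        disc = c1 * c1 + 4.0 * c2 * dp
        if np.any(disc <= 0):
            raise RangeError("pixel outside the invertible dispersion branch")
        nu = 2.0 * dp / (c1 + np.sqrt(disc))
    return nu if nu.ndim else float(nu)


def frequency_to_pixel(calib: CalibrationModel, order: int, freq_ghz):
    """Inverse of :func:`pixel_to_frequency` (fractional pixel position)."""
    if not 0 <= order < calib.n_orders:
        raise RangeError(f"order {order} out of range [0, {calib.n_orders})")
    nu = np.asarray(freq_ghz, dtype=float)
    p = calib.order_anchors_px[order] + calib._offset(nu)
    return p if p.ndim else float(p)
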