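"""Measurement channels, data types, and self-calibrated baseline fitting.

Maps forward-model responses onto the symmetric two-source/two-detector
probe: collinear source 1, detector A, detector B, source 2 at 0, 25, 37
and 62 mm, giving two short single-distance channels at 25 mm (1A, 2B),
two long ones at 37 mm (1B, 2A), and one dual-slope set (1AB2).

Data values:

* single-distance intensity  Y = ln(ac)
* single-distance phase      Y = phase (rad)
* dual-slope intensity       mean paired slope of ln(r²·ac) vs r, mm⁻¹
* dual-slope phase           mean paired slope of phase vs r, rad/mm

The dual-slope average cancels every per-source and per-detector coupling
factor (multiplicative gains on amplitude, additive offsets on phase),
which is what makes absolute baseline fitting possible without instrument
calibration.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .forward import C_VACUUM_MM_S, homogeneous_fd_reflectance


class DataTypeKind(enum.Enum):
    """The six FD data types distinguished by the analysis."""

    SDI25 = "SDI25"
    SDI37 = "SDI37"
    SDPHI25 = "SDPhi25"
    SDPHI37 = "SDPhi37"
    DSI = "DSI"
    DSPHI = "DSPhi"

    @property
    def is_phase(self) -> bool:
        return self in (DataTypeKind.SDPHI25, DataTypeKind.SDPHI37, DataTypeKind.DSPHI)

    @property
    def is_dual_slope(self) -> bool:
        return self in (DataTypeKind.DSI, DataTypeKind.DSPHI)

    @property
    def distance(self) -> float | None:
        """Source–detector distance (mm) for single-distance kinds."""
        return {
            DataTypeKind.SDI25: 25.0,
            DataTypeKind.SDPHI25: 25.0,
            DataTypeKind.SDI37: 37.0,
            DataTypeKind.SDPHI37: 37.0,
        }.get(self)


#: Channel id → (source, detector) position indices in the probe layout.
CHANNELS = ("1A", "1B", "2A", "2B")


@dataclass(frozen=True)
class ProbeGeometry:
    """Collinear optode positions (mm): source1, detectorA, detectorB, source2."""

    source1: float = 0.0
    detector_a: float = 25.0
    detector_b: float = 37.0
    source2: float = 62.0

    def distance(self, channel: str) -> float:
        src = {"1": self.source1, "2": self.source2}[channel[0]]
        det = {"A": self.detector_a, "B": self.detector_b}[channel[1]]
        return abs(det - src)

    @property
    def short(self) -> float:
        return self.distance("1A")

    @property
    def long(self) -> float:
        return self.distance("1B")

    def __post_init__(self) -> None:
        if not math.isclose(self.distance("1A"), self.distance("2B")) or not math.isclose(
            self.distance("1B"), self.distance("2A")
        ):
            raise ValueError("probe must be symmetric: |1A| = |2B| and |1B| = |2A|")
        if self.short >= self.long:
            raise ValueError("short channel distance must be below long distance")


DEFAULT_GEOMETRY = ProbeGeometry()


@dataclass(frozen=True)
class ChannelReading:
    """AC amplitude and phase of one channel at one wavelength."""

    channel: str
    wavelength: float
    ac: float
    phase: float

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if not self.ac > 0:
            raise ValueError("ac amplitude must be positive")


def sd_datavalue(reading: ChannelReading, kind: str = "intensity") -> float:
    """Single-distance data value: ln(ac) for intensity, phase (rad) for phase."""
    if kind == "intensity":
        return math.log(reading.ac)
    if kind == "phase":
        return reading.phase
    raise ValueError("kind must be 'intensity' or 'phase'")


def dual_slope(
    readings: dict[str, ChannelReading],
    kind: str = "intensity",
    geometry: ProbeGeometry = DEFAULT_GEOMETRY,
) -> float:
    """Dual-slope data value from the four channels of one wavelength.

    DS = ½·[(Y(1B) − Y(1A)) + (Y(2A) − Y(2B))] / (r_long − r_short)

    with Y = ln(r²·ac) for intensity and Y = phase for phase. Per-source and
    per-detector gains/offsets cancel exactly in this average.
    """
    missing = [c for c in CHANNELS if c not in readings]
    if missing:
        raise ValueError(f"dual slope needs all four channels; missing {missing}")
    wavelengths = {readings[c].wavelength for c in CHANNELS}
    if len(wavelengths) != 1:
        raise ValueError("all four channels must share a wavelength")

    def y(ch: str) -> float:
        rd = readings[ch]
        if kind == "intensity":
            return math.log(geometry.distance(ch) ** 2 * rd.ac)
        if kind == "phase":
            return rd.phase
        raise ValueError("kind must be 'intensity' or 'phase'")

    dr = geometry.long - geometry.short
    return 0.5 * ((y("1B") - y("1A")) + (y("2A") - y("2B"))) / dr


def model_ds_slopes(
    mua: float,
    mus_prime: float,
    n: float = 1.4,
    modulation_hz: float = 140e6,
    geometry: ProbeGeometry = DEFAULT_GEOMETRY,
) -> tuple[float, float]:
    """Model dual-slope (intensity, phase) pair for a homogeneous medium.

    Two-distance slopes of ln(r²·ac) and phase between the probe's short and
    long distances, from the closed-form semi-infinite solution.
    """
    r = np.array([geometry.short, geometry.long])
    phi = homogeneous_fd_reflectance(mua, mus_prime, n, modulation_hz, r)
    dr = geometry.long - geometry.short
    s_int = float(np.diff(np.log(r**2 * np.abs(phi)))[0] / dr)
    s_pha = float(np.diff(np.unwrap(np.angle(phi)))[0] / dr)
    return s_int, s_pha


def _slope_initial_guess(
    s_int: float, s_pha: float, n: float, modulation_hz: float
) -> tuple[float, float]:
    """Infinite-medium analytic inversion of the slope pair (starting point).

    For an infinite medium ln(r·ac) and phase decay linearly with slopes
    −Re(k) and +Im(−k); using the measured two-distance slopes as (kr, ki):
    μs′ = 2·kr·ki·v/(3ω) and μa = (kr² − ki²)/(3μs′).
    """
    kr = -s_int
    ki = s_pha
    v = C_VACUUM_MM_S / n
    omega = 2.0 * math.pi * modulation_hz
    mus = 2.0 * kr * ki * v / (3.0 * omega)
    mua = (kr**2 - ki**2) / (3.0 * mus)
    return max(mua, 1e-4), max(mus, 0.05)


def fit_baseline_selfcal(
    ds_intensity_slope: float,
    ds_phase_slope: float,
    n: float = 1.4,
    modulation_hz: float = 140e6,
    geometry: ProbeGeometry = DEFAULT_GEOMETRY,
) -> tuple[float, float]:
    """Absolute (μa, μs′) from a dual-slope intensity/phase pair.

    Inverts the homogeneous semi-infinite model so that its two-distance
    dual slopes reproduce the measured pair — the self-calibrated baseline
    method. The measured intensity slope must be negative and the phase
    slope positive (attenuation and increasing phase delay with distance).
    """
    if not ds_intensity_slope < 0:
        raise ValueError("dual-slope intensity slope must be negative")
    if not ds_phase_slope > 0:
        raise ValueError("dual-slope phase slope must be positive")

    target = np.array([ds_intensity_slope, ds_phase_slope])
    guess = _slope_initial_guess(ds_intensity_slope, ds_phase_slope, n, modulation_hz)

    def residual(log_params):
        mua, mus = np.exp(log_params)
        model = model_ds_slopes(mua, mus, n, modulation_hz, geometry)
        return (np.array(model) - target) / np.abs(target)

    sol = optimize.least_squares(
        residual,
        np.log(guess),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise RuntimeError(
            f"self-calibrated fit did not converge (residual {np.max(np.abs(sol.fun)):.2e})"
        )
    mua, mus = np.exp(sol.x)
    return float(mua), float(mus)
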