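"""Occlusion-protocol analysis: channel time series → hemodynamic rates.

Pipeline, applied independently per data type exactly as a homogeneous
analysis would:

1. Self-calibrated baseline fit of (μa, μs′) per wavelength from the
   dual-slope intensity/phase pair averaged over the baseline phase.
2. Modified Beer–Lambert step: Δμa(t) = [Y(t) − Y0] / (∂Y/∂μa), the
   derivative (total generalized pathlength of that data type) evaluated on
   the homogeneous baseline medium.
3. Two-wavelength inversion to ΔO(t), ΔD(t), ΔT(t) (μM).
4. Linear fit over the protocol's initial window:
   blood flow  BF = (dΔT/dt)/ctHb during venous occlusion, and
   oxygen consumption  OC = 4·d[(ΔD−ΔO)/2]/dt during arterial occlusion,
   with the factor 4 for hemoglobin's four oxygen-binding sites.

Units: BF in mL_blood/(100 mL_tissue)/min, OC in μmol_O2/(100 mL_tissue)/min;
reported errors are the standard errors of the fitted slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chromophores import CTHB_BLOOD_UM, DEFAULT_PAIR, WavelengthPair, delta_hb_from_delta_mua
from .probe import (
    DEFAULT_GEOMETRY,
    DataTypeKind,
    ProbeGeometry,
    fit_baseline_selfcal,
)
from .forward import homogeneous_fd_reflectance

#: Channels contributing to each single-distance kind (symmetric pairs).
_SD_CHANNELS = {25.0: ("1A", "2B"), 37.0: ("1B", "2A")}


@dataclass(frozen=True)
class OcclusionProtocol:
    """Timing and metadata of a cuff-occlusion protocol (durations in s)."""

    mode: str
    baseline_s: float
    occlusion_s: float
    recovery_s: float
    fit_window_s: float
    cuff_mmhg: float

    def __post_init__(self) -> None:
        if self.mode not in ("venous", "arterial"):
            raise ValueError("mode must be 'venous' or 'arterial'")
        if self.fit_window_s > self.occlusion_s:
            raise ValueError("fit window cannot exceed the occlusion phase")

    @property
    def onset_s(self) -> float:
        return self.baseline_s

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.occlusion_s + self.recovery_s


#: 1-min baseline/occlusion/recovery at 60 mmHg, 10 s fit window.
VENOUS_PROTOCOL = OcclusionProtocol("venous", 60.0, 60.0, 60.0, 10.0, 60.0)
#: 2-min baseline/occlusion/recovery at 200 mmHg, 60 s fit window.
ARTERIAL_PROTOCOL = OcclusionProtocol("arterial", 120.0, 120.0, 120.0, 60.0, 200.0)


@dataclass
class HemodynamicTrace:
    """Baseline-referenced hemoglobin time series for one data type.

    Arrays in μM on a common time base (s); ΔT = ΔO + ΔD.
    """

    time_s: np.ndarray
    d_oxy: np.ndarray
    d_deoxy: np.ndarray
    kind: DataTypeKind

    @property
    def d_total(self) -> np.ndarray:
        return self.d_oxy + self.d_deoxy

    @property
    def desaturation(self) -> np.ndarray:
        """(ΔD − ΔO)/2, the arterial-occlusion observable."""
        return 0.5 * (self.d_deoxy - self.d_oxy)


@dataclass(frozen=True)
class RatesResult:
    """A fitted hemodynamic rate with its slope standard error."""

    kind: DataTypeKind
    value: float
    stderr: float
    units: str
    slope_um_per_s: float
    n_samples: int


def _ols_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and its standard error."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = t.size
    if n < 3:
        raise ValueError("need at least 3 samples for a slope fit")
    tc = t - t.mean()
    sxx = float(np.dot(tc, tc))
    slope = float(np.dot(tc, y)) / sxx
    resid = y - y.mean() - slope * tc
    sigma2 = float(np.dot(resid, resid)) / (n - 2)
    return slope, math.sqrt(sigma2 / sxx)


def datavalues_from_channels(
    frame: pd.DataFrame, geometry: ProbeGeometry = DEFAULT_GEOMETRY
) -> dict[tuple[DataTypeKind, float], pd.Series]:
    """Reduce a channel table to per-(kind, wavelength) data-value series.

    ``frame`` follows the channel CSV schema: columns ``time_s``,
    ``channel`` (1A|1B|2A|2B), ``wavelength_nm``, ``ac``, ``phase_rad``.
    Single-distance values average the two symmetric channels of each
    distance (ln ac for intensity, phase for phase); dual-slope values are
    the gain-cancelling paired-slope average.
    """
    required = {"time_s", "channel", "wavelength_nm", "ac", "phase_rad"}
    if not required.issubset(frame.columns):
        raise ValueError(f"channel table needs columns {sorted(required)}")
    out: dict[tuple[DataTypeKind, float], pd.Series] = {}
    for lam, sub in frame.groupby("wavelength_nm"):
        wide_ac = sub.pivot(index="time_s", columns="channel", values="ac")
        wide_ph = sub.pivot(index="time_s", columns="channel", values="phase_rad")
        if wide_ac.isna().any().any():
            raise ValueError("misaligned time bases across channels")
        t = wide_ac.index
        for dist, (c1, c2) in _SD_CHANNELS.items():
            int_kind = DataTypeKind.SDI25 if dist == 25.0 else DataTypeKind.SDI37
            pha_kind = DataTypeKind.SDPHI25 if dist == 25.0 else DataTypeKind.SDPHI37
            out[(int_kind, lam)] = pd.Series(
                0.5 * (np.log(wide_ac[c1]) + np.log(wide_ac[c2])), index=t
            )
            out[(pha_kind, lam)] = pd.Series(
                0.5 * (wide_ph[c1] + wide_ph[c2]), index=t
            )
        r2 = {c: geometry.distance(c) ** 2 for c in ("1A", "1B", "2A", "2B")}
        dr = geometry.long - geometry.short
        ds_int = 0.5 * (
            np.log(r2["1B"] * wide_ac["1B"] / (r2["1A"] * wide_ac["1A"]))
            + np.log(r2["2A"] * wide_ac["2A"] / (r2["2B"] * wide_ac["2B"]))
        ) / dr
        ds_pha = 0.5 * (
            (wide_ph["1B"] - wide_ph["1A"]) + (wide_ph["2A"] - wide_ph["2B"])
        ) / dr
        out[(DataTypeKind.DSI, lam)] = pd.Series(ds_int, index=t)
        out[(DataTypeKind.DSPHI, lam)] = pd.Series(ds_pha, index=t)
    return out


def fit_baseline_from_channels(
    frame: pd.DataFrame,
    protocol: OcclusionProtocol,
    geometry: ProbeGeometry = DEFAULT_GEOMETRY,
    n: float = 1.4,
    modulation_hz: float = 140e6,
) -> dict[float, tuple[float, float]]:
    """Self-calibrated baseline (μa, μs′) per wavelength.

    Averages the dual-slope intensity and phase values over the baseline
    phase and inverts the homogeneous model.
    """
    values = datavalues_from_channels(frame, geometry)
    out = {}
    for lam in sorted({k[1] for k in values}):
        si = values[(DataTypeKind.DSI, lam)]
        sp = values[(DataTypeKind.DSPHI, lam)]
        mask = si.index < protocol.onset_s
        out[lam] = fit_baseline_selfcal(
            float(si[mask].mean()), float(sp[mask].mean()), n, modulation_hz, geometry
        )
    return out


def generalized_pathlength(
    kind: DataTypeKind,
    mua: float,
    mus_prime: float,
    n: float = 1.4,
    modulation_hz: float = 140e6,
    geometry: ProbeGeometry = DEFAULT_GEOMETRY,
    step: float = 1e-5,
) -> float:
    """Total generalized pathlength ∂Y/∂μa of a data type (homogeneous).

    Central finite difference of the data value on the closed-form
    semi-infinite model. Negative for intensity kinds (attenuation), in mm;
    rad·mm for phase kinds; per-mm slopes for dual-slope kinds.
    """
    def value(m: float) -> float:
        r = np.array([geometry.short, geometry.long])
        phi = homogeneous_fd_reflectance(m, mus_prime, n, modulation_hz, r)
        if kind is DataTypeKind.DSI:
            y = np.log(r**2 * np.abs(phi))
            return float((y[1] - y[0]) / (r[1] - r[0]))
        if kind is DataTypeKind.DSPHI:
            y = np.unwrap(np.angle(phi))
            return float((y[1] - y[0]) / (r[1] - r[0]))
        idx = 0 if kind.distance == geometry.short else 1
        return float(np.angle(phi[idx])) if kind.is_phase else float(np.log(np.abs(phi[idx])))

    deriv = (value(mua + step) - value(mua - step)) / (2.0 * step)
    if deriv == 0:
        raise ZeroDivisionError(f"vanishing pathlength derivative for {kind}")
    return deriv


def mbll_delta_mua(
    series: pd.Series,
    baseline_props: tuple[float, float],
    kind: DataTypeKind,
    baseline_end_s: float,
    n: float = 1.4,
    modulation_hz: float = 140e6,
    geometry: ProbeGeometry = DEFAULT_GEOMETRY,
) -> pd.Series:
    """Modified Beer–Lambert conversion of one data-value series to Δμa(t).

    Δμa(t) = [Y(t) − Y0] / (∂Y/∂μa) with Y0 the mean over the baseline
    phase and the derivative from :func:`generalized_pathlength` on the
    homogeneous baseline medium (μa, μs′) = ``baseline_props``. An ac
    decrease (intensity drop) maps to Δμa > 0 because the intensity
    pathlength derivative is negative.
    """
    mua0, mus0 = baseline_props
    deriv = generalized_pathlength(kind, mua0, mus0, n, modulation_hz, geometry)
    y0 = float(series[series.index < baseline_end_s].mean())
    return (series - y0) / deriv


def traces_to_hemoglobin(
    dmua_by_wavelength: dict[float, pd.Series],
    kind: DataTypeKind,
    pair: WavelengthPair = DEFAULT_PAIR,
) -> HemodynamicTrace:
    """Per-sample two-wavelength inversion of Δμa series to a trace."""
    s1 = dmua_by_wavelength[pair.lambda1]
    s2 = dmua_by_wavelength[pair.lambda2]
    if not s1.index.equals(s2.index):
        raise ValueError("wavelength series are not time-aligned")
    d_oxy, d_deoxy, _ = delta_hb_from_delta_mua(s1.to_numpy(), s2.to_numpy(), pair)
    return HemodynamicTrace(s1.index.to_numpy(float), d_oxy, d_deoxy, kind)


def _fit_window(trace: HemodynamicTrace, protocol: OcclusionProtocol) -> np.ndarray:
    t = trace.time_s
    if protocol.onset_s + protocol.fit_window_s > t[-1]:
        raise ValueError("fit window extends beyond the recorded time range")
    return (t >= protocol.onset_s) & (t <= protocol.onset_s + protocol.fit_window_s)


def blood_flow(
    trace: HemodynamicTrace,
    protocol: OcclusionProtocol = VENOUS_PROTOCOL,
    cthb_um: float = CTHB_BLOOD_UM,
) -> RatesResult:
    """Blood flow from the initial ΔT slope during venous occlusion.

    BF = (dΔT/dt)/ctHb converted to mL_blood/(100 mL_tissue)/min; the
    slope is an ordinary least-squares fit over the protocol's initial
    window after occlusion onset and the error is the slope's standard
    error under the same fit.
    """
    if protocol.mode != "venous":
        raise ValueError("blood flow requires a venous protocol")
    mask = _fit_window(trace, protocol)
    slope, se = _ols_slope(trace.time_s[mask], trace.d_total[mask])
    scale = 60.0 * 100.0 / cthb_um  # μM/s → mL/(100 mL)/min
    return RatesResult(
        kind=trace.kind,
        value=slope * scale,
        stderr=se * scale,
        units="mL_blood/(100 mL_tissue)/min",
        slope_um_per_s=slope,
        n_samples=int(mask.sum()),
    )


def oxygen_consumption(
    trace: HemodynamicTrace,
    protocol: OcclusionProtocol = ARTERIAL_PROTOCOL,
) -> RatesResult:
    """Oxygen consumption from the initial (ΔD−ΔO)/2 slope (arterial).

    OC = 4·d[(ΔD−ΔO)/2]/dt converted to μmol_O2/(100 mL_tissue)/min
    (μM/s × 0.1 per-100-mL × 60 s/min × 4 binding sites = ×24).
    """
    if protocol.mode != "arterial":
        raise ValueError("oxygen consumption requires an arterial protocol")
    mask = _fit_window(trace, protocol)
    slope, se = _ols_slope(trace.time_s[mask], trace.desaturation[mask])
    scale = 4.0 * 0.1 * 60.0
    return RatesResult(
        kind=trace.kind,
        value=slope * scale,
        stderr=se * scale,
        units="umol_O2/(100 mL_tissue)/min",
        slope_um_per_s=slope,
        n_samples=int(mask.sum()),
    )


def analyze_occlusion(
    frame: pd.DataFrame,
    protocol: OcclusionProtocol,
    geometry: ProbeGeometry = DEFAULT_GEOMETRY,
    pair: WavelengthPair = DEFAULT_PAIR,
    n: float = 1.4,
    modulation_hz: float = 140e6,
) -> dict:
    """Full pipeline on a channel table: baseline fit, traces, rates.

    Returns ``{"baseline": {λ: (μa, μs′)}, "traces": {kind: trace},
    "rates": {kind: RatesResult}, "ratios": DataFrame}``.
    """
    values = datavalues_from_channels(frame, geometry)
    baseline = fit_baseline_from_channels(frame, protocol, geometry, n, modulation_hz)
    traces: dict[DataTypeKind, HemodynamicTrace] = {}
    rates: dict[DataTypeKind, RatesResult] = {}
    for kind in DataTypeKind:
        dmua = {
            lam: mbll_delta_mua(
                values[(kind, lam)], baseline[lam], kind, protocol.onset_s,
                n, modulation_hz, geometry,
            )
            for lam in (pair.lambda1, pair.lambda2)
        }
        trace = traces_to_hemoglobin(dmua, kind, pair)
        traces[kind] = trace
        if protocol.mode == "venous":
            rates[kind] = blood_flow(trace, protocol)
        else:
            rates[kind] = oxygen_consumption(trace, protocol)
    return {
        "baseline": baseline,
        "traces": traces,
        "rates": rates,
        "ratios": ratio_report(rates),
    }


_REPORT_PAIRS = [
    ("SD37/SD25_I", DataTypeKind.SDI37, DataTypeKind.SDI25),
    ("SD37/SD25_Phi", DataTypeKind.SDPHI37, DataTypeKind.SDPHI25),
    ("DS/SD25_I", DataTypeKind.DSI, DataTypeKind.SDI25),
    ("DS/SD25_Phi", DataTypeKind.DSPHI, DataTypeKind.SDPHI25),
]


def ratio_report(rates: dict[DataTypeKind, RatesResult]) -> pd.DataFrame:
    """Rate ratios between data-type pairs (deep-probing over shallow).

    Entries whose reference rate is zero are flagged (``valid=False``,
    ratio NaN) rather than raising.
    """
    rows = []
    for name, num, den in _REPORT_PAIRS:
        if num not in rates or den not in rates:
            continue
        denom = rates[den].value
        valid = denom != 0
        rows.append(
            {
                "kind_pair": name,
                "ratio": rates[num].value / denom if valid else np.nan,
                "numerator": rates[num].value,
                "denominator": denom,
                "valid": valid,
            }
        )
    return pd.DataFrame(rows)
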