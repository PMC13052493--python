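"""Synthetic forearm FD-NIRS recordings.

Generates everything the analysis pipeline assumes it is given: a cohort of
layered forearm anatomies (adipose / muscle / bone), occlusion-driven
per-layer hemoglobin schedules, and noisy per-channel AC-amplitude/phase
time series at the instrument's 2.4 Hz sampling rate, including
multiplicative source/detector amplitude gains and additive phase offsets
(the couplings that dual-slope acquisition cancels).

The layer parameterization reproduces the standard simulation conditions
for this tissue system: baseline hemoglobin 50/100/50 μM at 75% StO2 with
water fractions 20/80/32% for adipose/muscle/bone, reduced scattering
1.0/0.5/1.5 mm⁻¹ at 690 nm with scattering powers 0.1/1/0.7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chromophores import (
    DEFAULT_PAIR,
    TissueComposition,
    WavelengthPair,
    mua_from_composition,
    mus_prime_from_composition,
)
from .forward import LayeredMedium, OpticalLayer, layered_fd_reflectance
from .occlusion import OcclusionProtocol
from .probe import CHANNELS, DEFAULT_GEOMETRY, ProbeGeometry
from .sensitivity import HemodynamicScenario, scenario_to_absorption

#: Layer compositions: adipose, muscle, bone (top to bottom).
LAYER_COMPOSITIONS = (
    TissueComposition(37.5, 12.5, water_fraction=0.20, scattering_power=0.1, mus_ref=1.0),
    TissueComposition(75.0, 25.0, water_fraction=0.80, scattering_power=1.0, mus_ref=0.5),
    TissueComposition(37.5, 12.5, water_fraction=0.32, scattering_power=0.7, mus_ref=1.5),
)

#: Cohort anatomy ranges spanned by the study population (mm).
ATT_RANGE = (1.5, 9.5)
BONE_DEPTH_RANGE = (14.0, 26.0)


@dataclass(frozen=True)
class SubjectAnatomy:
    """Forearm layer thicknesses: adipose (ATT) and muscle (MTT), mm."""

    subject_id: int
    att_mm: float
    mtt_mm: float

    def __post_init__(self) -> None:
        if self.att_mm < 0 or self.mtt_mm <= 0:
            raise ValueError("layer thicknesses must be non-negative (MTT positive)")

    @property
    def bone_depth_mm(self) -> float:
        """Depth of the bone surface, ATT + MTT."""
        return self.att_mm + self.mtt_mm


#: The 14-subject forearm cohort (ATT, MTT in mm).
FOREARM_COHORT = tuple(
    SubjectAnatomy(i + 1, att, mtt)
    for i, (att, mtt) in enumerate(
        [
            (3.0, 11.0), (4.0, 10.5), (2.5, 12.5), (3.7, 13.3), (4.5, 14.0),
            (6.5, 13.0), (7.0, 13.5), (6.2, 14.5), (5.0, 16.0), (1.7, 19.8),
            (1.5, 20.5), (2.0, 21.5), (9.5, 15.0), (8.0, 18.0),
        ]
    )
)


def layered_media(
    thicknesses_mm,
    compositions=LAYER_COMPOSITIONS,
    pair: WavelengthPair = DEFAULT_PAIR,
    include_water: bool = True,
    n: float = 1.4,
    modulation_hz: float = 140e6,
) -> dict[float, LayeredMedium]:
    """Per-wavelength media from layer compositions and thicknesses.

    ``thicknesses_mm`` lists the finite thicknesses of all layers but the
    last (semi-infinite) one; zero-thickness layers are dropped (a missing
    adipose layer degenerates cleanly to a two-layer medium).
    """
    thicknesses = list(thicknesses_mm) + [math.inf]
    if len(thicknesses) != len(compositions):
        raise ValueError("need one thickness per layer (last layer infinite)")
    media = {}
    for lam in (pair.lambda1, pair.lambda2):
        layers = [
            OpticalLayer(
                mua_from_composition(c, lam, include_water),
                mus_prime_from_composition(c, lam),
                t,
            )
            for c, t in zip(compositions, thicknesses)
            if t > 0
        ]
        media[lam] = LayeredMedium(tuple(layers), n, modulation_hz)
    return media


def make_subject(
    anatomy: SubjectAnatomy,
    n_layers: int = 3,
    pair: WavelengthPair = DEFAULT_PAIR,
    include_water: bool = True,
) -> dict[float, LayeredMedium]:
    """Three-layer (or two-layer) media for one subject's anatomy."""
    if n_layers == 3:
        return layered_media([anatomy.att_mm, anatomy.mtt_mm], LAYER_COMPOSITIONS,
                             pair, include_water)
    if n_layers == 2:
        return layered_media([anatomy.att_mm], LAYER_COMPOSITIONS[:2], pair, include_water)
    raise ValueError("n_layers must be 2 or 3")


def generate_cohort(n: int = 14, seed: int | None = None) -> list[SubjectAnatomy]:
    """The fixed 14-subject cohort, or a seeded random cohort of size n.

    Random subjects draw ATT uniformly in the cohort ATT range and bone
    depth uniformly in the cohort bone-depth range (MTT = depth − ATT).
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    if n == 14:
        return list(FOREARM_COHORT)
    rng = np.random.default_rng(seed)
    att = rng.uniform(*ATT_RANGE, size=n)
    depth = rng.uniform(*BONE_DEPTH_RANGE, size=n)
    return [
        SubjectAnatomy(i + 1, float(a), float(d - a)) for i, (a, d) in enumerate(zip(att, depth))
    ]


@dataclass(frozen=True)
class InstrumentModel:
    """Source/detector couplings and noise of the FD instrument.

    Amplitude gains multiply the AC amplitude (per source and detector);
    phase offsets add (rad). Noise is i.i.d. Gaussian per sample, relative
    on amplitude and absolute (rad) on phase. Sampling at 2.4 Hz.
    """

    source_gains: tuple[float, float] = (1.0, 1.0)
    detector_gains: tuple[float, float] = (1.0, 1.0)
    source_phase_offsets: tuple[float, float] = (0.0, 0.0)
    detector_phase_offsets: tuple[float, float] = (0.0, 0.0)
    amplitude_noise_rel: float = 0.002
    phase_noise_rad: float = math.radians(0.1)
    sampling_hz: float = 2.4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.source_gains + self.detector_gains):
            raise ValueError("amplitude gains must be positive")

    @classmethod
    def with_random_couplings(cls, seed: int, **kwargs) -> "InstrumentModel":
        """Instrument with seeded random gains/offsets (noise seed reused)."""
        rng = np.random.default_rng(seed)
        return cls(
            source_gains=tuple(np.exp(rng.uniform(-0.7, 0.7, 2))),
            detector_gains=tuple(np.exp(rng.uniform(-0.7, 0.7, 2))),
            source_phase_offsets=tuple(rng.uniform(-0.5, 0.5, 2)),
            detector_phase_offsets=tuple(rng.uniform(-0.5, 0.5, 2)),
            seed=seed,
            **kwargs,
        )

    def channel_coupling(self, channel: str) -> tuple[float, float]:
        """(amplitude gain, phase offset) for a channel like '1A'."""
        si = int(channel[0]) - 1
        di = 0 if channel[1] == "A" else 1
        return (
            self.source_gains[si] * self.detector_gains[di],
            self.source_phase_offsets[si] + self.detector_phase_offsets[di],
        )


@dataclass(frozen=True)
class OcclusionSchedule:
    """Piecewise-linear occlusion drive for a hemodynamic scenario.

    The scenario's per-layer amplitudes are reached by a linear ramp over
    ``ramp_s`` seconds of the occlusion phase (default: the whole phase),
    held until cuff release, then relaxed exponentially with time constant
    ``recovery_tau_s``. Amplitudes are zero throughout baseline.
    """

    scenario: HemodynamicScenario
    protocol: OcclusionProtocol
    ramp_s: float | None = None
    recovery_tau_s: float = 20.0

    def __post_init__(self) -> None:
        modes = (self.scenario.mode, self.protocol.mode)
        if modes[0] != modes[1]:
            raise ValueError(f"scenario mode {modes[0]} != protocol mode {modes[1]}")

    def envelope(self, t) -> np.ndarray:
        """Dimensionless drive in [0, 1] at time(s) t (s)."""
        t = np.asarray(t, dtype=float)
        p = self.protocol
        ramp = self.ramp_s if self.ramp_s is not None else p.occlusion_s
        if not 0 < ramp <= p.occlusion_s:
            raise ValueError("ramp must fit inside the occlusion phase")
        u = np.zeros_like(t)
        occ = (t >= p.onset_s) & (t < p.onset_s + p.occlusion_s)
        u[occ] = np.minimum((t[occ] - p.onset_s) / ramp, 1.0)
        rec = t >= p.onset_s + p.occlusion_s
        level = min(p.occlusion_s / ramp, 1.0)
        u[rec] = level * np.exp(-(t[rec] - (p.onset_s + p.occlusion_s)) / self.recovery_tau_s)
        return u

    def ramp_rates_um_per_s(self) -> np.ndarray:
        """Programmed per-layer concentration ramp rates during occlusion."""
        ramp = self.ramp_s if self.ramp_s is not None else self.protocol.occlusion_s
        return np.asarray(self.scenario.amplitudes, dtype=float) / ramp


def default_scenarios() -> dict:
    """Named scenario library for the standard simulation conditions.

    ``venous_default``/``arterial_default``: per-layer amplitudes
    (5, 10, 0) μM for adipose/muscle/bone — the canonical unequal-flow,
    bone-inert condition. ``arterial_muscle``: muscle desaturation fixed at
    ΔD2 = −ΔO2 = 20 μM with a moderate adipose contribution. The
    ``*_adipose_sweep`` entries vary the adipose amplitude across its
    standard range at fixed muscle amplitude (venous: ΔT1 2–20 μM over
    ΔT2 = 10; arterial: ΔD1 2–24 μM over ΔD2 = 20).
    """
    venous_sweep = tuple(
        HemodynamicScenario("venous", (float(a), 10.0, 0.0))
        for a in np.linspace(2.0, 20.0, 10)
    )
    arterial_sweep = tuple(
        HemodynamicScenario("arterial", (float(a), 20.0, 0.0))
        for a in np.linspace(2.0, 24.0, 12)
    )
    return {
        "venous_default": HemodynamicScenario("venous", (5.0, 10.0, 0.0)),
        "arterial_default": HemodynamicScenario("arterial", (5.0, 10.0, 0.0)),
        "arterial_muscle": HemodynamicScenario("arterial", (10.0, 20.0, 0.0)),
        "venous_adipose_sweep": venous_sweep,
        "arterial_adipose_sweep": arterial_sweep,
    }


def noiseless_channel_matrix(
    media: dict[float, LayeredMedium],
    schedule: OcclusionSchedule,
    geometry: ProbeGeometry = DEFAULT_GEOMETRY,
    sampling_hz: float = 2.4,
) -> tuple[np.ndarray, dict[float, np.ndarray]]:
    """Ideal (coupling- and noise-free) channel responses over the protocol.

    Returns ``(time_s, {wavelength: complex array (n_times, 2)})`` with the
    columns holding the short- and long-distance responses. Symmetric
    channel pairs (1A/2B and 1B/2A) share these values by construction.
    Repeated drive levels (baseline, plateau) are evaluated once.
    """
    p = schedule.protocol
    t = np.arange(0.0, p.total_s, 1.0 / sampling_hz)
    env = schedule.envelope(t)
    lams = sorted(media)
    change = scenario_to_absorption(schedule.scenario, WavelengthPair(lams[0], lams[1]))
    r = np.array([geometry.short, geometry.long])
    out: dict[float, np.ndarray] = {}
    levels, inverse = np.unique(env, return_inverse=True)
    for j, lam in enumerate(sorted(media)):
        medium = media[lam]
        if change.dmua.shape[0] != len(medium.layers):
            raise ValueError(
                f"scenario has {change.dmua.shape[0]} layers, medium has "
                f"{len(medium.layers)}"
            )
        base = np.array([l.mua for l in medium.layers])
        resp = np.empty((levels.size, 2), dtype=complex)
        for i, lev in enumerate(levels):
            resp[i] = layered_fd_reflectance(
                medium.with_mua(base + lev * change.dmua[:, j]), r
            )
        out[lam] = resp[inverse]
    return t, out


def apply_instrument(
    time_s: np.ndarray,
    responses: dict[float, np.ndarray],
    instrument: InstrumentModel,
    geometry: ProbeGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Turn ideal responses into a noisy instrument channel table.

    Applies per-channel amplitude gains and phase offsets, then adds seeded
    Gaussian noise (relative on AC amplitude, absolute on phase). Output
    follows the channel CSV schema ``time_s, channel, wavelength_nm, ac,
    phase_rad``.
    """
    rng = np.random.default_rng(instrument.seed)
    rows = []
    col_of = {"1A": 0, "1B": 1, "2A": 1, "2B": 0}  # distance column per channel
    for lam in sorted(responses):
        resp = responses[lam]
        for ch in CHANNELS:
            gain, offset = instrument.channel_coupling(ch)
            ac = np.abs(resp[:, col_of[ch]]) * gain
            ph = np.angle(resp[:, col_of[ch]]) + offset
            ac = ac * (1.0 + instrument.amplitude_noise_rel * rng.standard_normal(ac.size))
            ph = ph + instrument.phase_noise_rad * rng.standard_normal(ph.size)
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": time_s,
                        "channel": ch,
                        "wavelength_nm": lam,
                        "ac": ac,
                        "phase_rad": ph,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_occlusion(
    media: dict[float, LayeredMedium],
    schedule: OcclusionSchedule,
    instrument: InstrumentModel = InstrumentModel(),
    geometry: ProbeGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """End-to-end synthetic recording for one subject and protocol.

    Convenience wrapper: :func:`noiseless_channel_matrix` then
    :func:`apply_instrument`. Identical seeds give identical tables.
    """
    t, resp = noiseless_channel_matrix(media, schedule, geometry, instrument.sampling_hz)
    return apply_instrument(t, resp, instrument, geometry)


def write_channels(frame: pd.DataFrame, path) -> None:
    """Write a channel table as CSV with 12-significant-digit values."""
    frame.to_csv(path, index=False, float_format="%.12g")
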