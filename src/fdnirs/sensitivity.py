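"""Layer sensitivities and the hemodynamic-ratio engine.

A data type's *partial generalized pathlength* in layer k is the first
derivative of the data value with respect to that layer's absorption
coefficient; normalising by the total (sum over layers) gives the layer
sensitivity S_k, which sums to 1 by construction. Weighted with the
two-wavelength hemoglobin-inversion coefficients a±, b±, the sensitivities
turn programmed per-layer absorption changes into the *effective* ΔT or
(ΔD−ΔO) that a homogeneous analysis of each data type would report, and
hence into blood-flow and oxygen-consumption ratios between data types.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .chromophores import (
    DEFAULT_PAIR,
    LN10,
    WavelengthPair,
    inversion_coefficients,
    lookup_extinction,
)
from .forward import LayeredMedium, layered_fd_reflectance
from .probe import DEFAULT_GEOMETRY, DataTypeKind, ProbeGeometry

_EPS_UM_TO_MM = 1e-7  # decadic cm^-1 M^-1 × μM → mm^-1 (before ln10)


@dataclass(frozen=True)
class PartialPathlengths:
    """Per-layer ∂Y/∂μa,k (mm for intensity, rad·mm for phase)."""

    per_layer: tuple[float, ...]

    @property
    def total(self) -> float:
        return float(sum(self.per_layer))


@dataclass(frozen=True)
class SensitivityProfile:
    """Normalized per-layer sensitivities, Σk Sk = 1."""

    per_layer: tuple[float, ...]
    kind: DataTypeKind
    wavelength: float


@dataclass(frozen=True)
class LayerAbsorptionChange:
    """Δμa per layer (rows) per wavelength of the pair (columns), mm⁻¹."""

    dmua: np.ndarray  # shape (n_layers, 2)
    pair: WavelengthPair = DEFAULT_PAIR


@dataclass(frozen=True)
class HemodynamicScenario:
    """Programmed per-layer hemoglobin changes.

    ``mode="venous"``: per-layer ΔT_k (μM), split into ΔO/ΔD with the
    accumulation saturation ``saturation`` (the oxygen saturation of the
    accumulating blood).  ``mode="arterial"``: per-layer ΔD_k (μM) with
    ΔO_k = −ΔD_k (pure desaturation, no volume change).
    """

    mode: str
    amplitudes: tuple[float, ...]
    saturation: float = 0.75

    def __post_init__(self) -> None:
        if self.mode not in ("venous", "arterial"):
            raise ValueError("mode must be 'venous' or 'arterial'")
        if not 0.0 <= self.saturation <= 1.0:
            raise ValueError("saturation must lie in [0, 1]")
        if self.mode == "arterial" and any(a < 0 for a in self.amplitudes):
            raise ValueError("arterial ΔD_k must be non-negative")

    @property
    def n_layers(self) -> int:
        return len(self.amplitudes)

    def delta_hb(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-layer (ΔO_k, ΔD_k) in μM implied by the scenario."""
        amp = np.asarray(self.amplitudes, dtype=float)
        if self.mode == "venous":
            return amp * self.saturation, amp * (1.0 - self.saturation)
        return -amp, amp


@lru_cache(maxsize=8192)
def _datavalue(medium: LayeredMedium, kind: DataTypeKind, geometry: ProbeGeometry) -> float:
    """Scalar data value Y of ``kind`` for the medium under the probe."""
    r = np.array([geometry.short, geometry.long])
    phi = layered_fd_reflectance(medium, r)
    if kind is DataTypeKind.DSI:
        y = np.log(r**2 * np.abs(phi))
        return float((y[1] - y[0]) / (r[1] - r[0]))
    if kind is DataTypeKind.DSPHI:
        y = np.unwrap(np.angle(phi))
        return float((y[1] - y[0]) / (r[1] - r[0]))
    idx = 0 if kind.distance == geometry.short else 1
    if kind.is_phase:
        return float(np.angle(phi[idx]))
    return float(np.log(np.abs(phi[idx])))


@lru_cache(maxsize=4096)
def partial_pathlengths(
    medium: LayeredMedium,
    kind: DataTypeKind,
    step: float = 1e-5,
    geometry: ProbeGeometry = DEFAULT_GEOMETRY,
) -> PartialPathlengths:
    """Per-layer derivative of the data value w.r.t. layer absorption.

    Central finite difference with step ``step`` (mm⁻¹) on each layer's μa.
    """
    base_mua = [l.mua for l in medium.layers]
    derivs = []
    for k in range(len(medium.layers)):
        up = list(base_mua)
        dn = list(base_mua)
        up[k] += step
        dn[k] -= step
        y_up = _datavalue(medium.with_mua(up), kind, geometry)
        y_dn = _datavalue(medium.with_mua(dn), kind, geometry)
        derivs.append((y_up - y_dn) / (2.0 * step))
    return PartialPathlengths(tuple(derivs))


def normalized_sensitivity(
    medium: LayeredMedium,
    kind: DataTypeKind,
    wavelength: float = 690.0,
    geometry: ProbeGeometry = DEFAULT_GEOMETRY,
) -> SensitivityProfile:
    """Layer sensitivities S_k = l_k / Σ l_j for one data type.

    The wavelength tags the profile (the medium itself must already carry
    that wavelength's optical properties).
    """
    pl = partial_pathlengths(medium, kind, geometry=geometry)
    if pl.total == 0:
        raise ZeroDivisionError("total generalized pathlength vanishes")
    return SensitivityProfile(
        tuple(l / pl.total for l in pl.per_layer), kind, wavelength
    )


def scenario_to_absorption(
    scenario: HemodynamicScenario, pair: WavelengthPair = DEFAULT_PAIR
) -> LayerAbsorptionChange:
    """Per-layer, per-wavelength Δμa (mm⁻¹) implied by a scenario.

    Venous: Δμa,k(λ) = ln10·[εO(λ)·s + εD(λ)·(1−s)]·ΔT_k ;
    arterial: Δμa,k(λ) = ln10·[εD(λ) − εO(λ)]·ΔD_k  (unit-consistent,
    concentrations in μM).
    """
    d_oxy, d_deoxy = scenario.delta_hb()
    cols = []
    for lam in (pair.lambda1, pair.lambda2):
        eps_o, eps_d, _ = lookup_extinction(lam)
        cols.append(LN10 * (eps_o * d_oxy + eps_d * d_deoxy) * _EPS_UM_TO_MM)
    return LayerAbsorptionChange(np.column_stack(cols), pair)


def _effective_sums(
    kind: DataTypeKind,
    media: dict[float, LayeredMedium],
    change: LayerAbsorptionChange,
    geometry: ProbeGeometry,
) -> tuple[float, float]:
    """(ΔT_eff, (ΔD−ΔO)_eff) in μM for one data type.

    Sensitivity-weights the layer Δμa at each wavelength into an effective
    homogeneous Δμa, then applies the two-wavelength inversion.
    """
    pair = change.pair
    coef = inversion_coefficients(pair)
    eff = []
    for j, lam in enumerate((pair.lambda1, pair.lambda2)):
        prof = normalized_sensitivity(media[lam], kind, lam, geometry)
        if len(prof.per_layer) != change.dmua.shape[0]:
            raise ValueError("layer count mismatch between medium and change")
        eff.append(float(np.dot(prof.per_layer, change.dmua[:, j])))
    d_total = coef.a_minus * eff[0] + coef.b_minus * eff[1]
    d_diff = coef.a_plus * eff[0] + coef.b_plus * eff[1]
    return d_total, d_diff


def ratio_deltaT(
    kind_x: DataTypeKind,
    kind_y: DataTypeKind,
    media: dict[float, LayeredMedium],
    change: LayerAbsorptionChange,
    geometry: ProbeGeometry = DEFAULT_GEOMETRY,
) -> float:
    """Ratio of effective ΔT between data types y and x (ΔT_y / ΔT_x).

    Under a venous scenario whose per-layer ΔT_k are proportional to layer
    blood flow, this is the blood-flow ratio the two data types report.
    ``media`` maps each wavelength of the change's pair to the baseline
    medium at that wavelength.
    """
    ty, _ = _effective_sums(kind_y, media, change, geometry)
    tx, _ = _effective_sums(kind_x, media, change, geometry)
    if tx == 0:
        raise ZeroDivisionError("effective ΔT of reference data type is zero")
    return ty / tx


def ratio_deoxy_oxy(
    kind_x: DataTypeKind,
    kind_y: DataTypeKind,
    media: dict[float, LayeredMedium],
    change: LayerAbsorptionChange,
    geometry: ProbeGeometry = DEFAULT_GEOMETRY,
) -> float:
    """Ratio of effective (ΔD−ΔO) between data types y and x.

    Under an arterial scenario with ΔO_k = −ΔD_k this is the
    oxygen-consumption ratio the two data types report.
    """
    _, dy = _effective_sums(kind_y, media, change, geometry)
    _, dx = _effective_sums(kind_x, media, change, geometry)
    if dx == 0:
        raise ZeroDivisionError("effective (ΔD−ΔO) of reference data type is zero")
    return dy / dx


_RATIO_PAIRS = {
    "SD37/SD25_I": (DataTypeKind.SDI25, DataTypeKind.SDI37),
    "SD37/SD25_Phi": (DataTypeKind.SDPHI25, DataTypeKind.SDPHI37),
    "DS/SD25_I": (DataTypeKind.SDI25, DataTypeKind.DSI),
    "DS/SD25_Phi": (DataTypeKind.SDPHI25, DataTypeKind.DSPHI),
}


def sweep_ratios(
    build_media,
    scenario: HemodynamicScenario,
    l1_grid: Sequence[float],
    bone_depth_grid: Sequence[float] | None = None,
    pair: WavelengthPair = DEFAULT_PAIR,
    geometry: ProbeGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Tabulate hemodynamic ratios over layer-thickness grids.

    ``build_media(l1, bone_depth)`` must return the per-wavelength media
    {λ: LayeredMedium} for a top-layer thickness ``l1`` (mm) and, for
    three-layer models, a bone depth L1+L2 (mm); for two-layer models pass
    ``bone_depth_grid=None`` and the callable receives ``bone_depth=None``.

    Returns a tidy DataFrame with columns ``L1_mm``, ``bone_depth_mm``,
    ``kind_pair``, ``ratio``. The ratio column holds effective-ΔT ratios for
    venous scenarios and effective-(ΔD−ΔO) ratios for arterial ones.
    """
    change = scenario_to_absorption(scenario, pair)
    ratio_fn = ratio_deltaT if scenario.mode == "venous" else ratio_deoxy_oxy
    rows = []
    depths = [None] if bone_depth_grid is None else list(bone_depth_grid)
    for l1 in l1_grid:
        for depth in depths:
            if depth is not None and depth <= l1:
                raise ValueError("bone depth must exceed the top-layer thickness")
            media = build_media(l1, depth)
            for name, (kx, ky) in _RATIO_PAIRS.items():
                rows.append(
                    {
                        "L1_mm": float(l1),
                        "bone_depth_mm": np.nan if depth is None else float(depth),
                        "kind_pair": name,
                        "ratio": ratio_fn(kx, ky, media, change, geometry),
                    }
                )
    return pd.DataFrame(rows)
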