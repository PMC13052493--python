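"""Hemoglobin and water spectroscopy.

Extinction-coefficient lookup, Beer's-law composition of tissue absorption,
the two-wavelength inversion between absorption changes and hemoglobin
concentration changes, the scattering power law, and whole-blood
concentration conversions.

Units used throughout the package:

* wavelength — nm
* absorption and reduced scattering coefficients — mm⁻¹
* hemoglobin concentrations — μM (micromolar)
* molar extinction coefficients — decadic, cm⁻¹·M⁻¹ (compendium convention);
  Beer's law applies the ln(10) factor explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

LN10 = float(np.log(10.0))

#: Decadic cm⁻¹·M⁻¹ × μM → mm⁻¹ (×0.1 for cm→mm, ×1e−6 for μM→M), before ln10.
_EPS_UM_TO_MM = 1e-7

#: Hemoglobin molar mass used for whole-blood conversions, g/mol.
HB_MOLAR_MASS = 64500.0

#: Hemoglobin concentration in whole blood assumed by the occlusion
#: estimators: 15 g/dL ≈ 2.33 mM, stored exactly in μM.
CTHB_BLOOD_UM = 15.0 * 10.0 / HB_MOLAR_MASS * 1e6


class DegenerateSystemError(ValueError):
    """Raised when the two-wavelength inversion matrix is singular."""


@dataclass(frozen=True)
class WavelengthPair:
    """Ordered pair of distinct wavelengths (nm) for dual-wavelength work."""

    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        if self.lambda1 == self.lambda2:
            raise DegenerateSystemError(
                f"wavelength pair must be distinct, got {self.lambda1} nm twice"
            )


#: The instrument's standard pair.
DEFAULT_PAIR = WavelengthPair(690.0, 830.0)


@dataclass(frozen=True)
class TissueComposition:
    """Baseline chromophore content of one tissue layer.

    Parameters
    ----------
    oxy, deoxy:
        Oxy-/deoxyhemoglobin concentrations, μM.
    water_fraction:
        Water volume fraction, 0–1.
    scattering_power:
        Exponent ``b`` of the reduced-scattering power law λ^(−b).
    mus_ref:
        Reduced scattering coefficient at ``lambda_ref``, mm⁻¹.
    lambda_ref:
        Reference wavelength for ``mus_ref``, nm.
    """

    oxy: float
    deoxy: float
    water_fraction: float = 0.0
    scattering_power: float = 0.0
    mus_ref: float = 1.0
    lambda_ref: float = 690.0

    def __post_init__(self) -> None:
        if self.oxy < 0 or self.deoxy < 0:
            raise ValueError("hemoglobin concentrations must be non-negative")
        if not 0.0 <= self.water_fraction <= 1.0:
            raise ValueError("water fraction must lie in [0, 1]")

    @property
    def total(self) -> float:
        """Total hemoglobin T = O + D, μM."""
        return self.oxy + self.deoxy

    @property
    def sto2(self) -> float:
        """Hemoglobin oxygen saturation O/T (fraction)."""
        if self.total == 0:
            raise ValueError("StO2 undefined for zero total hemoglobin")
        return self.oxy / self.total


@dataclass(frozen=True)
class InversionCoefficients:
    """Linear coefficients mapping (Δμa(λ1), Δμa(λ2)) to hemoglobin sums.

    ``a_minus·Δμa(λ1) + b_minus·Δμa(λ2) = ΔO + ΔD  (= ΔT)``
    ``a_plus·Δμa(λ1)  + b_plus·Δμa(λ2)  = ΔD − ΔO``

    with Δμa in mm⁻¹ and concentrations in μM.
    """

    a_plus: float
    a_minus: float
    b_plus: float
    b_minus: float


@lru_cache(maxsize=1)
def _spectra() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    path = resources.files("fdnirs.data").joinpath("extinction_spectra.csv")
    with path.open("rb") as fh:
        table = np.loadtxt(fh, delimiter=",", comments="#", skiprows=7)
    wl, eps_o, eps_d, mua_w = table.T
    if not np.all(np.diff(wl) > 0):  # pragma: no cover - packaged data
        raise RuntimeError("extinction grid must be strictly increasing")
    return wl, eps_o, eps_d, mua_w


def lookup_extinction(wavelength: float) -> tuple[float, float, float]:
    """Return (εO, εD, μa_water) at ``wavelength``.

    εO/εD are decadic molar extinction coefficients in cm⁻¹·M⁻¹; μa_water is
    in mm⁻¹. Linear interpolation between grid points; a grid point returns
    the tabulated value exactly.
    """
    wl, eps_o, eps_d, mua_w = _spectra()
    if not (wl[0] <= wavelength <= wl[-1]):
        raise ValueError(
            f"wavelength {wavelength} nm outside supported range "
            f"[{wl[0]:.0f}, {wl[-1]:.0f}] nm"
        )
    return (
        float(np.interp(wavelength, wl, eps_o)),
        float(np.interp(wavelength, wl, eps_d)),
        float(np.interp(wavelength, wl, mua_w)),
    )


def mua_from_composition(
    comp: TissueComposition, wavelength: float, include_water: bool = True
) -> float:
    """Absorption coefficient (mm⁻¹) of a tissue composition via Beer's law.

    μa = ln10·(εO·O + εD·D) (converted to mm⁻¹) plus, when ``include_water``,
    the water volume fraction times the water absorption spectrum. The
    hemoglobin-only branch (``include_water=False``) matches conventions that
    quote heme absorption alone.
    """
    eps_o, eps_d, mua_w = lookup_extinction(wavelength)
    mua = LN10 * (eps_o * comp.oxy + eps_d * comp.deoxy) * _EPS_UM_TO_MM
    if include_water:
        mua += comp.water_fraction * mua_w
    return mua


def mus_prime_from_composition(comp: TissueComposition, wavelength: float) -> float:
    """Reduced scattering coefficient (mm⁻¹) from the layer's power law."""
    return mus_prime_power_law(
        comp.mus_ref, comp.scattering_power, wavelength, lambda_ref=comp.lambda_ref
    )


def mus_prime_power_law(
    mus_ref: float, b: float, wavelength: float, lambda_ref: float = 690.0
) -> float:
    """Power-law reduced scattering μs′(λ) = μs′(λref)·(λ/λref)^(−b)."""
    if mus_ref <= 0:
        raise ValueError("reference reduced scattering must be positive")
    if wavelength <= 0 or lambda_ref <= 0:
        raise ValueError("wavelengths must be positive")
    return mus_ref * (wavelength / lambda_ref) ** (-b)


def _extinction_matrix(pair: WavelengthPair) -> np.ndarray:
    """2×2 matrix M with Δμa[mm⁻¹] = M @ (ΔO, ΔD)[μM]."""
    rows = []
    for lam in (pair.lambda1, pair.lambda2):
        eps_o, eps_d, _ = lookup_extinction(lam)
        rows.append([LN10 * eps_o * _EPS_UM_TO_MM, LN10 * eps_d * _EPS_UM_TO_MM])
    return np.asarray(rows)


def inversion_coefficients(pair: WavelengthPair = DEFAULT_PAIR) -> InversionCoefficients:
    """Two-wavelength inversion coefficients a±, b± for the given pair.

    Derived from the inverse of the Beer's-law extinction matrix so that the
    identities on :class:`InversionCoefficients` hold exactly. The
    denominator εO(λ1)εD(λ2) − εO(λ2)εD(λ1) must be non-zero.
    """
    m = _extinction_matrix(pair)
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if abs(det) < 1e-30:
        raise DegenerateSystemError(
            f"singular extinction system for pair {pair}; "
            "wavelengths too close or isosbestic-degenerate"
        )
    # Rows of inv(M): ΔO = (m22·Δμ1 − m12·Δμ2)/det, ΔD = (−m21·Δμ1 + m11·Δμ2)/det
    a_minus = (m[1, 1] - m[1, 0]) / det
    b_minus = (m[0, 0] - m[0, 1]) / det
    a_plus = -(m[1, 1] + m[1, 0]) / det
    b_plus = (m[0, 0] + m[0, 1]) / det
    return InversionCoefficients(
        a_plus=a_plus, a_minus=a_minus, b_plus=b_plus, b_minus=b_minus
    )


def delta_hb_from_delta_mua(
    dmua1, dmua2, pair: WavelengthPair = DEFAULT_PAIR
):
    """Invert absorption changes at two wavelengths to (ΔO, ΔD, ΔT) in μM.

    ``dmua1``/``dmua2`` are Δμa (mm⁻¹) at ``pair.lambda1``/``pair.lambda2``;
    scalars or arrays (e.g. time series) are accepted and broadcast.
    """
    dmua1 = np.asarray(dmua1, dtype=float)
    dmua2 = np.asarray(dmua2, dtype=float)
    if not (np.all(np.isfinite(dmua1)) and np.all(np.isfinite(dmua2))):
        raise ValueError("absorption changes must be finite")
    m = _extinction_matrix(pair)
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if abs(det) < 1e-30:
        raise DegenerateSystemError("singular extinction system")
    d_oxy = (m[1, 1] * dmua1 - m[0, 1] * dmua2) / det
    d_deoxy = (-m[1, 0] * dmua1 + m[0, 0] * dmua2) / det
    return d_oxy, d_deoxy, d_oxy + d_deoxy


def blood_concentration(mass_conc_g_dl: float) -> float:
    """Convert a hemoglobin mass concentration (g/dL) to molarity in μM."""
    if mass_conc_g_dl < 0:
        raise ValueError("mass concentration must be non-negative")
    return mass_conc_g_dl * 10.0 / HB_MOLAR_MASS * 1e6


def blood_volume_fraction(tissue_total_um: float, cthb_um: float = CTHB_BLOOD_UM) -> float:
    """Fraction of tissue volume occupied by blood, T_tissue / ctHb_blood."""
    if tissue_total_um < 0:
        raise ValueError("tissue hemoglobin must be non-negative")
    if cthb_um == 0:
        raise ZeroDivisionError("blood hemoglobin concentration must be non-zero")
    return tissue_total_um / cthb_um
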