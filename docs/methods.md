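# Methods

## Physical model

Light transport is modelled with the frequency-domain diffusion
approximation in laterally infinite plane-layered media. Each layer k has
absorption μa,k and reduced scattering μs′,k (mm⁻¹); the bottom layer is
semi-infinite. The diffusion coefficient is D = 1/(3μs′) (absorption not
included in D), the source is an isotropic point at depth z0 = 1/μs′ of the
top layer, and the surface boundary is the extrapolated (Dirichlet)
condition φ(−zb) = 0 with zb = 2·A(n)·D₁ and A(n) from the standard
internal-reflection polynomial (A(1.4) ≈ 2.0). All layers share n = 1.4 —
the community default for soft tissue; no inter-layer Fresnel terms. With
the exp(−iωt) time convention the complex wavenumber is
k² = (μa − iω/v)/D, which makes the measured phase *increase* with
source–detector distance, as FD instruments report it.

Two solver paths exist and are tested against each other:

* homogeneous semi-infinite: the exact image-source closed form (the image
  pair about the extrapolated plane is the exact solution of the Dirichlet
  problem, which is why that boundary condition — rather than the Robin
  partial-current form — is used consistently in both solvers; the
  difference between the two conditions is a sub-percent overall factor
  that cancels in every slope, difference, and ratio the pipeline uses);
* N-layer: per spatial frequency s, the two fundamental solutions of the
  1-D complex Helmholtz problem are propagated to the source depth — an
  impedance (Riccati-style) recursion upward from the matched semi-infinite
  bottom layer, and a scaled transfer-matrix propagation downward from the
  surface (exponential factors carried separately to avoid overflow; the
  source may sit below the first interface when the top layer is thinner
  than 1/μs′). The surface fluence follows from the Wronskian formula, and
  an inverse order-zero Hankel transform returns to physical distance.

The Hankel integral uses composite Gauss–Legendre panels on [0, s_max] with
s_max = max(32·μs′₁, 10·max μs′) mm⁻¹ and about three panels (order 10) per
Bessel oscillation at the farthest detector. An optional refinement check
doubles the panel count and raises if the result moves by more than 1e−7
relative — a tolerance chosen just above the double-precision cancellation
floor of the oscillatory sum at r = 60 mm (~2e−8). Validated limits:
degenerate identical layers agree with the closed form to ~2e−8 over
r ∈ [15, 60] mm; an interface at 40 mm is invisible at r = 25 mm to 3e−5;
merging equal bottom layers changes nothing to 1e−11.

## Data types and self-calibration

The probe is collinear and symmetric (source 1, detector A, detector B,
source 2 at 0/25/37/62 mm), giving paired single-distance channels at 25 mm
(1A, 2B) and 37 mm (1B, 2A) and one dual-slope set. Data values are
Y = ln(ac) and phase for single-distance kinds; dual-slope kinds use the
average of the two paired two-distance slopes of ln(r²·ac) (intensity) and
phase. The r² compensation is the standard multi-distance reduction; it is
irrelevant for single-distance time-differences (r fixed) and for
normalized sensitivities, but is the convention under which the absolute
baseline fit is exact. Per-source and per-detector amplitude gains and
phase offsets cancel identically in the dual-slope average — the
self-calibration property, asserted to 1e−12 against random couplings.

Absolute baseline (μa, μs′) per wavelength comes from inverting the
homogeneous closed form so its two-distance dual slopes match the measured
pair (trust-region least squares on log-parameters; the analytic
infinite-medium slope relations provide the starting point). On layered
tissue this fit is deliberately a *homogeneous-equivalent*: the whole
analysis chain assumes homogeneity exactly as the measurement convention
does, and the layered truth enters only through the synthetic data.

## Sensitivities and the ratio engine

The partial generalized pathlength of layer k for a data type is
l_k = ∂Y/∂μa,k, computed by central finite differences (step 1e−5 mm⁻¹,
checked against Richardson extrapolation at 1e−4). Normalized
sensitivities S_k = l_k/Σl_j sum to 1 by construction. For two data types
x, y and per-layer absorption changes Δμa,k(λ), the engine forms each
type's effective Δμa per wavelength as Σ_k S_k Δμa,k and converts to
effective ΔT and (ΔD−ΔO) with the two-wavelength inversion coefficients

a∓ = (εD(λ₂) ∓ εO(λ₂))/det,  b∓ = (εO(λ₁) ∓ εD(λ₁))/det,
det = εO(λ₁)εD(λ₂) − εO(λ₂)εD(λ₁),

where the sign of the (ΔD−ΔO) pair is fixed so that
a⁺Δμa(λ₁) + b⁺Δμa(λ₂) ≡ ΔD−ΔO exactly matches the direct 2×2 inversion
(some presentations print the opposite sign for a⁺; ratios are unaffected
but the identity form is what the tests pin down). Scenario objects map
programmed per-layer hemoglobin changes to Δμa: venous blood accumulation
ΔT_k split at saturation s (default 0.75, the baseline StO2 — the split is
a package choice exposed as a parameter), arterial desaturation ΔD_k with
ΔO_k = −ΔD_k.

## Occlusion estimators

Blood flow: OLS slope of ΔT over the first 10 s after venous occlusion
onset, divided by the hemoglobin concentration of whole blood
(15 g/dL at 64,500 g/mol = 2325.6 μM; the printed blood-volume fractions
4.3%/2.2% are quoted against the rounded 2.3 mM working value), reported in
mL_blood/(100 mL_tissue)/min. Oxygen consumption: 4× the OLS slope of
(ΔD−ΔO)/2 over the first 60 s after arterial onset (factor 4 for the four
O₂-binding sites), in μmol_O₂/(100 mL_tissue)/min. Errors are the OLS
slope standard errors. Occlusion onset is taken from protocol metadata
(cuff-pressure recordings are out of scope). The baseline reference Y0 is
the mean over the entire baseline phase, which minimises its noise
contribution.

The modified Beer–Lambert step divides each data type's baseline-referenced
signal by that type's total generalized pathlength evaluated on the
*fitted homogeneous* medium. This is what makes the recovered rates
"effective" on layered tissue: the layered partial-pathlength sum and the
homogeneous-equivalent pathlength differ by 10–20% for single-distance
kinds, and that factor is part of the measurement model, not an error. The
end-to-end verification therefore predicts each rate as
(Σ_k l_k^layered Δμ̇a,k)/L_hom per wavelength followed by the hemoglobin
inversion — with l_k evaluated at the medium state in the middle of the fit
window, since an OLS slope over a slightly convex response estimates the
mean derivative there. Noiseless synthetic runs agree with this prediction
to 0.05% (venous) and 0.05% (arterial) for all six data types, comfortably
within the 2% linearization bound asserted in the tests; baseline-state
linearization would leave arterial phase kinds ~4.5% off because the
desaturation scenario drives Δμa(690) to ~25% of baseline μa.

## Synthetic data

The generator emulates the measurement conditions the analysis assumes: a
cohort of 14 forearm anatomies (adipose 1.5–9.5 mm, bone depth 14–26 mm,
held as a fixed table; arbitrary cohort sizes sample those ranges
uniformly), three-layer baseline optics derived by Beer's law from layer
compositions (adipose/muscle/bone hemoglobin 50/100/50 μM at StO2 75%,
water 20/80/32%, μs′(690) = 1.0/0.5/1.5 mm⁻¹ with scattering powers
0.1/1/0.7), occlusion drives (linear ramp over the occlusion phase —
only the initial-window slope matters to the estimators — then exponential
recovery with a 20 s time constant), per-channel evaluation of the layered
forward model at 2.4 Hz, multiplicative source/detector gains, additive
phase offsets, and i.i.d. Gaussian noise (0.2% relative amplitude, 0.1°
phase per sample — plausible FD instrument figures, chosen so phase-derived
rates are the noisier ones, and configurable). One seeded generator per
simulation; identical seeds give byte-identical CSV output (values written
at 12 significant digits).

What the generator does *not* emulate — motion artifacts, cuff-pressure
transients, probe-contact effects, physiological drift and pulsation,
myoglobin, finite lateral extent and limb curvature — bounds what passing
tests show about real recordings: they validate the analysis chain under
the diffusion model's own assumptions, not instrument- or
physiology-robustness.

## Design choices and numerical details

* Extinction spectra ship as a packaged CSV digest (650–1000 nm, 10 nm
  grid, linear interpolation): decadic molar extinction of oxy-/deoxy-
  hemoglobin (compendium lineage) and near-infrared water absorption. The
  690 and 830 nm rows carry the compendium values to the digits given;
  intermediate rows are a smooth digest adequate for interpolation, not a
  primary reference. Beer's law applies ln(10) explicitly; internal units
  are mm⁻¹, μM, nm throughout.
* Baseline layer absorptions can be computed with or without the water
  term (`include_water`); the water-inclusive branch reproduces the
  standard tabulated values (e.g. muscle 0.0170 mm⁻¹ at 690 nm), the
  hemoglobin-only branch the corresponding 0.0166 mm⁻¹ convention.
* The venous ΔT split across ΔO/ΔD uses the accumulating-blood saturation
  parameter because venous pooling adds partially oxygenated blood; the
  arterial mode is volume-conserving by construction.
* Derivative caching: sensitivity profiles are memoised on the frozen
  medium/geometry objects, making cohort sweeps and the ratio engine cheap
  after first evaluation.
* Degenerate inputs: zero-thickness layers are dropped before solving
  (an absent adipose layer degenerates to a two-layer medium); equal
  wavelengths, non-positive amplitudes, unphysical slope signs, and
  windows outside the record raise typed errors.

## Known limitations

* The solver requires the top layer of a *stack* to contain no interface
  shallower than numerical support for the source — in practice the source
  depth 1/μs′ may lie below the first interface (handled exactly), but
  sub-diffusive regimes (very low μs′·L products) inherit the usual
  diffusion-approximation error near the source.
* One qualitative claim about layered media is not reproduced by this
  implementation: sweeping the top layer's reduced scattering below the
  muscle value (μs′₁ ≤ μs′₂) does not force all deep-over-shallow ratios
  below 1 here — the ratios depend monotonically on the scattering
  contrast (which the tests assert) but do not change sign. The behaviour
  may hinge on unstated details of other layered solutions (source
  placement, boundary treatment); treat conclusions drawn from that corner
  of parameter space with care.
* Blood flow is, as in the underlying measurement convention, a
  blood-*volume* accumulation rate; vascular compliance and redistribution
  are outside the model.
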