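# fdnirs

Frequency-domain near-infrared spectroscopy (FD-NIRS) of layered tissue,
built around the question of what noninvasive optical measurements of
skeletal muscle actually measure when the muscle sits between a superficial
adipose layer and deep bone.

The package is for researchers in diffuse optics and muscle physiology who
want to model — and generate synthetic data for — forearm measurements with
a symmetric two-source/two-detector probe: single-distance (SD) intensity
and phase at 25 and 37 mm, and dual-slope (DS) intensity and phase, at 690
and 830 nm with 140 MHz modulation.

## What it computes

**Forward model.** Complex diffuse reflectance of N-layer media from the
frequency-domain photon-diffusion equation: per spatial frequency, an
impedance recursion through the layer stack with an extrapolated boundary
(zb = 2AD), inverse Hankel transform to physical distance. A closed-form
semi-infinite solution serves as the homogeneous special case,

φ(r) ∝ e^(−k r₁)/r₁ − e^(−k r₂)/r₂,  k² = (μa − iω/v)/D,  D = 1/(3μs′).

**Probe reduction.** Data values Y = ln(ac) (SD intensity), phase (SD
phase), and the paired-slope averages of ln(r²·ac) and phase (dual slope),
which cancel all source/detector couplings; self-calibrated absolute
(μa, μs′) from the DS intensity/phase pair.

**Layer sensitivities and ratios.** Partial generalized pathlengths
l_k = ∂Y/∂μa,k, normalized sensitivities S_k = l_k/Σl_j, and the
two-wavelength ratio engine: for data types x, y the effective
ΔT_y/ΔT_x and (ΔD−ΔO)_y/(ΔD−ΔO)_x from per-layer absorption changes via
the hemoglobin-inversion coefficients a±, b±.

**Occlusion pipeline.** Channel time series → modified Beer–Lambert
Δμa(t) per data type → ΔO/ΔD/ΔT (μM) → blood flow
BF = (1/ctHb)·d(ΔT)/dt during venous occlusion and oxygen consumption
OC = 4·d[(ΔD−ΔO)/2]/dt during arterial occlusion, with OLS slope standard
errors.

**Synthetic data.** A 14-subject forearm cohort (adipose 1.5–9.5 mm, bone
depth 14–26 mm), three-layer baseline optics from hemoglobin/water
compositions, occlusion schedules, and a noisy instrument model at 2.4 Hz.

## Worked example

`python examples/layer_sensitivities.py` prints, for a 1.5 mm adipose layer:

```
Blood-flow ratio SD(37 mm)/SD(25 mm) vs bone depth (adipose 1.5 mm):
  depth   intensity   phase
    14 mm      0.980    0.840
    17 mm      0.998    0.890
    20 mm      1.011    0.934
    23 mm      1.018    0.966
    26 mm      1.021    0.987
```

With muscle-dominant venous blood accumulation (ΔT = 5/10/0 μM in
adipose/muscle/bone), the long-distance channel reports *less* flow than
the short one when the flow-inert bone is shallow (ratios < 1 at 14 mm),
and the ratio rises past 1 as the bone recedes — while phase ratios stay
below intensity ratios because phase senses deeper. A two-layer model
(no bone) cannot produce the sub-unity branch of this transition; that
contrast is the package's central phenomenology.

`examples/occlusion_analysis.py` runs the full simulate→analyze loop and
prints per-data-type blood flow with slope errors; `examples/
forward_model.py` and `examples/baseline_recovery.py` demonstrate the
forward solver and the self-calibrated optics fit.

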