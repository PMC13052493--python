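"""Self-calibrated absolute optics from dual-slope data.

Synthesises the dual-slope intensity and phase values a probe would record
on a homogeneous medium, multiplies every channel by arbitrary source and
detector couplings, and recovers (μa, μs′) — demonstrating that the
dual-slope reduction needs no instrument calibration.
"""

import numpy as np

from fdnirs import ChannelReading, dual_slope, fit_baseline_selfcal, homogeneous_fd_reflectance

truth = {"mua": 0.0170, "musp": 0.50}  # muscle-like, mm^-1

# channel readings with arbitrary unknown couplings
rng = np.random.default_rng(4)
gains = {"1": 2.4, "2": 0.7, "A": 1.9, "B": 0.4}
offsets = {"1": 0.31, "2": -0.12, "A": -0.25, "B": 0.44}
readings = {}
for ch, r in (("1A", 25.0), ("1B", 37.0), ("2A", 37.0), ("2B", 25.0)):
    resp = homogeneous_fd_reflectance(truth["mua"], truth["musp"], r=r)
    readings[ch] = ChannelReading(
        ch, 690.0,
        resp.ac * gains[ch[0]] * gains[ch[1]],
        resp.phase + offsets[ch[0]] + offsets[ch[1]],
    )

s_int = dual_slope(readings, "intensity")
s_pha = dual_slope(readings, "phase")
mua, musp = fit_baseline_selfcal(s_int, s_pha)

print(f"dual-slope intensity: {s_int:+.5f} mm⁻¹   dual-slope phase: {s_pha:+.5f} rad/mm")
print(f"recovered μa  = {mua:.4f} mm⁻¹  (truth {truth['mua']:.4f})")
print(f"recovered μs′ = {musp:.4f} mm⁻¹  (truth {truth['musp']:.2f})")
print("\nThe source/detector gains and phase offsets cancel in the paired-"
      "slope average, so the absolute optical properties come back exactly.")
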