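"""End-to-end occlusion experiment on a synthetic subject.

Simulates a venous occlusion (1 min baseline / 1 min cuff at 60 mmHg /
1 min recovery) on a three-layer forearm with muscle-dominant blood
accumulation, adds realistic instrument couplings and noise, then runs the
full analysis: self-calibrated baseline optics, modified Beer–Lambert
conversion per data type, hemoglobin traces, and blood flow from the
initial ΔT slope. Prints the per-data-type blood flow (mean ± slope SE) and
the deep-over-shallow ratios.
"""

from fdnirs import (
    FOREARM_COHORT,
    HemodynamicScenario,
    InstrumentModel,
    OcclusionSchedule,
    VENOUS_PROTOCOL,
    make_subject,
    simulate_occlusion,
)
from fdnirs.occlusion import analyze_occlusion

subject = FOREARM_COHORT[0]
media = make_subject(subject)
scenario = HemodynamicScenario("venous", (5.0, 10.0, 0.0))  # ΔT μM per layer
schedule = OcclusionSchedule(scenario, VENOUS_PROTOCOL)
instrument = InstrumentModel.with_random_couplings(seed=42)

frame = simulate_occlusion(media, schedule, instrument)
result = analyze_occlusion(frame, VENOUS_PROTOCOL)

print(f"Subject {subject.subject_id} (bone depth {subject.bone_depth_mm} mm), "
      f"venous occlusion, {len(frame)} channel samples\n")
print("Fitted baseline optics (homogeneous-equivalent):")
for lam, (mua, musp) in result["baseline"].items():
    print(f"  λ = {lam:.0f} nm: μa = {mua:.4f} mm⁻¹, μs′ = {musp:.3f} mm⁻¹")

print("\nBlood flow by data type [mL_blood/(100 mL_tissue)/min]:")
for kind, rate in result["rates"].items():
    print(f"  {kind.value:8s} {rate.value:6.3f} ± {rate.stderr:.3f}")

print("\nRate ratios (deep-probing over shallow):")
print(result["ratios"][["kind_pair", "ratio"]].to_string(index=False))

print("\nThe intensity-based deep channels (SD 37 mm, DS) report lower flow "
      "than the 25 mm channel because they sense the flow-inert bone at "
      "14 mm depth — their ratios below 1 are the signature of that bone "
      "contribution. Phase-derived rates carry much larger slope errors "
      "(phase is the noisier data type), so their single-run ratios "
      "scatter around the noiseless expectation.")
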