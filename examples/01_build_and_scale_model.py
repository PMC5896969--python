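"""Build a subject-specific lower-limb model and inspect its scaling.

Constructs the reduced musculoskeletal model for the first cohort subject,
prints the segment masses (which always sum to body mass), the CT-based hip
joint width, and the muscle-strength capacity at the two study strength
levels.
"""

from hipload import build_reference_model, reference_cohort
from hipload.dynamics import strength_simple

anthro = reference_cohort()[0]
model = build_reference_model(anthro)

print(f"subject {anthro.subject_id}: {anthro.mass} kg, {anthro.height} m, "
      f"BMI {anthro.bmi} kg/m^2")
print(f"hip joint width (CT): {model.hjw:.0f} mm, mode {model.hjw_mode}")
print(f"total segment mass:   {model.total_mass:.1f} kg (= body mass)")
print(f"fascicles per leg:    {len(model.fascicles_of('L'))}")
print()
print("hip-spanning fascicle groups (left leg, strength = sigma x PCSA):")
for f in model.fascicles_of("L"):
    print(f"  {f.name:22s} PCSA {f.pcsa:6.1f} cm^2   "
          f"N(40) {strength_simple(f, 40):7.0f} N   N(90) {strength_simple(f, 90):7.0f} N")
# The per-fascicle strengths are what the recruitment criteria normalize by;
# the 40 vs 90 N/cm^2 column is the factorial study's strength factor.
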