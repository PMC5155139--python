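# Example configuration for `paleobite run-palaeoecology`.
#
# The input CSVs referenced below can be generated with
#   paleobite simulate skull --seed 1 --out-prefix synthetic
#   paleobite simulate microwear --seed 3 --out-prefix synthetic
# or replaced with real measurement tables of the same schema.
#
# Allometric coefficients shown here are SYNTHETIC placeholders with
# plausible magnitudes, not published values; supply your own for real
# analyses.

body_mass:
  models:
    UMORL:            # upper-molar-occlusal-row length (mm) -> mass (kg)
      slope: 2.8
      intercept: -3.2
      pe_fraction: 0.14     # 14% prediction error
      re_factor: 1.0
    TSL:              # total skull length (mm) -> mass (kg)
      slope: 3.1
      intercept: -5.9
      pe_fraction: 0.19
      re_factor: 1.0
  measurements:
    - {specimen_id: S1, predictor_name: UMORL, value_mm: 21.0}
    - {specimen_id: S1, predictor_name: TSL, value_mm: 95.0}

prey_size:
  # refit from a predator-mass (x) / max-prey-mass (y) training table
  training_csv: synthetic_preytrain.csv

bite_force:
  levers_csv: synthetic_levers.csv
  muscle_stress_kPa: 300          # constant muscle stress
  comparative_csv: synthetic_comparative.csv   # columns: mass_kg, force_N

rps:
  premolar_width_mm: 6.0          # body mass taken from the best estimate

bending:
  sections_csv: synthetic_sections.csv

microwear:
  counts_csv: synthetic_microwear.csv
  metric: bray-curtis
  k: 5
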