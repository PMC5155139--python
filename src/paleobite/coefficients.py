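"""Placeholder allometric coefficient blocks.

These are SYNTHETIC, non-canonical values with plausible orders of
magnitude, shipped only so the pipeline runs end to end without user
input.  The published dasyuromorphian body-mass formulae and the
predator/prey regression they stand in for are not reproduced here;
real analyses must supply their own coefficients (config file) or refit
from a training table.
"""

from __future__ import annotations

# log10(mass kg) = intercept + slope * log10(measurement mm)
SYNTHETIC_MASS_MODELS: dict[str, dict[str, float]] = {
    # total skull length
    "TSL": {"slope": 3.1, "intercept": -5.9, "pe_fraction": 0.19,
            "re_factor": 1.0},
    # upper-molar-occlusal-row length
    "UMORL": {"slope": 2.8, "intercept": -3.2, "pe_fraction": 0.14,
              "re_factor": 1.0},
    "lower-molar-row-length": {"slope": 2.9, "intercept": -3.6,
                               "pe_fraction": 0.16, "re_factor": 1.0},
}

# log10(max prey mass kg) = intercept + slope * log10(predator mass kg)
SYNTHETIC_PREY_MODEL: dict[str, float] = {
    "slope": 1.2, "intercept": 0.1, "re_factor": 1.1,
}
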