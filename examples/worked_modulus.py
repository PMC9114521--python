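"""Calibration-mode Young's moduli for the two measured cell pairs.

The stretching stress is never printed by a bench run; it is recovered
from one reference (modulus, mean-strain) pair and then applied to the
other group means.  The two cell types yield nearly identical stresses
(17.5997 vs 17.5993 Pa), consistent with a single shared operating
point.
"""

from depstretch import calibrate_stress, modulus_from_strain

print("HUVEC (reference: normal group, E = 203.7 Pa at strain 0.0864)")
stress = calibrate_stress(203.7, 0.0864)
print(f"  calibrated stress           : {stress:.5f} Pa")
print(f"  modulus at strain 0.1013    : "
      f"{modulus_from_strain(0.1013, stress).modulus:.1f} Pa  (TNF-a treated)")

print("\nMCF-10A (reference: normal group, E = 257.3 Pa at strain 0.0684)")
stress2 = calibrate_stress(257.3, 0.0684)
print(f"  calibrated stress           : {stress2:.5f} Pa")
print(f"  modulus at strain 0.0901    : "
      f"{modulus_from_strain(0.0901, stress2).modulus:.1f} Pa  (CB treated)")

print("\nLower modulus after treatment = softer cells: the inflammatory")
print("cytokine and the actin inhibitor both reduce stiffness.")
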