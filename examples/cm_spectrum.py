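"""Clausius–Mossotti spectrum of a cell-like particle in stretching buffer.

Sweeps Re(f_CM) over frequency for placeholder cell/buffer dielectric
parameters, prints the DEP regime at the 12 MHz operating point and the
crossover frequency below which the cell would be repelled instead of
attracted.
"""

from depstretch import (
    DielectricBody,
    cm_factor,
    cm_spectrum,
    crossover_frequency,
    dep_regime,
)

cell = DielectricBody(eps_rel=60.0, sigma=0.01, radius=7.5e-6)
buffer = DielectricBody(eps_rel=78.0, sigma=0.005)  # 50 uS/cm

print("freq_hz      re_fcm")
for pt in cm_spectrum(cell, buffer, 1e4, 1e9, 11):
    print(f"{pt.freq:12.4g} {pt.re_fcm:+.4f}")

fc = crossover_frequency(cell, buffer)
print(f"\ncrossover frequency: {'none' if fc is None else f'{fc:.4g} Hz'}")
print(f"regime at 12 MHz: {dep_regime(cell, buffer, 12e6)} "
      f"(Re(f_CM) = {cm_factor(cell, buffer, 12e6).real:+.4f})")
print("\nA positive Re(f_CM) (p-DEP) pulls the particle toward the field")
print("maximum at the electrode tips; a negative one repels it.  The sign")
print("flips at the crossover frequency, so the drive frequency and buffer")
print("conductivity select the stretching regime for a given cell type.")
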