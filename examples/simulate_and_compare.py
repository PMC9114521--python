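"""Full synthetic experiment: simulate, analyze, compare two populations.

Runs the capture–stretch–release controller over a normal and a treated
population (true mean strains 0.0864 and 0.1013), feeds the resulting
length traces through the strain/modulus pipeline with QC, and prints
the two-group comparison report.
"""

import numpy as np

from depstretch import (
    CaptureModel,
    ControllerConfig,
    PopulationModel,
    analyze_traces,
    calibrate_stress,
    compare_groups,
    run_cycles,
)

rng = np.random.default_rng(1)
controller = ControllerConfig()
stress = calibrate_stress(203.7, 0.0864)

results = {}
for label, mean in (("normal", 0.0864), ("treated", 0.1013)):
    pop = PopulationModel(label=label, mean_strain=mean)
    log = run_cycles(controller, CaptureModel(), pop, n_cycles=30, rng=rng)
    results[label] = analyze_traces(log.traces, stress=stress)
    print(f"{label}: {log.n_measured} cells measured in 30 cycles "
          f"({log.throughput_cells_per_min():.1f} cells/min)")

report = compare_groups(results["normal"], results["treated"])
print()
print(report.to_text())
print("\nThe treated group strains more at the same stress, so its modulus")
print("is lower: the drug softened the cells.  The interval-proportion")
print("table shows the treated group depleted in the stiff (low-strain)")
print("bins and enriched above 0.09.")
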