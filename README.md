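# depstretch

Automated dielectrophoretic (DEP) single-cell mechanics, as software: the
electromechanics, device models and population analysis of a microfluidic
chip that traps single cells in a port array, stretches them with a
nonuniform AC field, and converts the imaged length change into strain and
Young's modulus — plus a synthetic device simulator so the whole pipeline
runs and is testable with no hardware attached.

Intended users: microfluidics and single-cell biomechanics groups who want
to prototype DEP stretching assays, sanity-check chip designs (electrode
gap, trap-array hydraulics, controller thresholds), or analyse length-trace
data from such a device.

## The model in brief

A cell of radius r and complex permittivity ε\*_p = ε_p − jσ_p/ω in a
medium ε\*_m feels the time-averaged DEP force

    F_DEP = 2π r³ ε_m Re(f_CM) ∇E²_rms,    f_CM = (ε*_p − ε*_m)/(ε*_p + 2 ε*_m)

with ω = 2πf.  Re(f_CM) ∈ [−0.5, 1] sets the sign (p-DEP attraction vs
n-DEP repulsion) and changes sign at the crossover frequency.  A trapped
cell at an electrode tip experiences the stretching stress

    σ = n Re(f_CM) ε_m E0²,        E = σ / ε,

where n = |E|·r·(d|E|/dx)/E0² is a dimensionless constant of the electrode
geometry (computed here by a 2D Laplace solver) and ε = (L_max − L_0)/L_0
is the strain from a cell's detected-length trace (min/max rule).  The
trap-array chip itself is modelled as a hydraulic resistor network solved
by Kirchhoff analysis, and a three-state (capture → stretch → release)
controller simulator generates realistic 50 fps traces for two-group
experiments.  See `docs/methods.md` for assumptions, defaults and limits.

## Worked example

Stress calibration from a reference (modulus, strain) pair, applied to the
other measured group means (`python examples/worked_modulus.py`):

```
HUVEC (reference: normal group, E = 203.7 Pa at strain 0.0864)
  calibrated stress           : 17.59968 Pa
  modulus at strain 0.1013    : 173.7 Pa  (TNF-a treated)

MCF-10A (reference: normal group, E = 257.3 Pa at strain 0.0684)
  calibrated stress           : 17.59932 Pa
  modulus at strain 0.0901    : 195.3 Pa  (CB treated)
```

The two independently calibrated stresses agree to four significant
figures — both cell types were stretched at one shared operating point —
and in each pair the treated cells strain more at the same stress, i.e.
they are softer.

A full synthetic experiment (`python examples/simulate_and_compare.py`)
simulates 30 controller cycles per group (~500 cells each at ~48 cells/min),
analyses the traces and prints the comparison:

```
                                normal       treated
n (valid/input)                490/499       493/500
mean strain                     0.0913        0.1045
...
delta mean strain   +0.0132
delta group modulus -24.4 Pa
```

The remaining examples cover one capability each: `cm_spectrum.py`
(Clausius–Mossotti spectrum and crossover), `electrode_field.py` (field
solve → geometric constant → physics-mode stress) and `device_network.py`
(per-port pressure differences, port blocking, release-flow split).

## Command line

A thin CLI mirrors the library: `depstretch spectrum | field | network |
simulate | analyze | compare`, with `--config` accepting a YAML/JSON run
configuration (schema-validated; unit strings like `"50 uS/cm"` are
converted on load).  For instance:

```sh
depstretch simulate --seed 1 --cycles 10 --out run/
depstretch analyze --traces run/traces_normal.csv --out run/results_normal.csv
depstretch compare run/results_normal.csv run/results_treated.csv
```

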