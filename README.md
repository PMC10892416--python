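# mearray

Desk-scale simulation of **magnetoelectric (ME) cantilever sensor arrays**
for biomagnetic measurements: magnetostatic crosstalk between the
high-permeability sensor layers, the biomagnetic excitation field of a
current dipole inside a three-shell head stand-in, and the linearized
transduction chain from magnetic flux to piezoelectric voltage.

ME sensors are composite cantilevers — a magnetostrictive FeCoSiB film and a
piezoelectric AlN film on opposite faces of a silicon substrate — operated at
their first bending resonance. Because the magnetostrictive film is strongly
soft-magnetic (µr ≈ 10³), each sensor in an array redirects flux away from
its neighbors. This *crosstalk* makes the response of a sensor depend on its
position in the array and on the spacing to its neighbors, which matters for
anyone designing wearable or operating-room ME arrays (e.g. for localizing
deep-brain-stimulation electrodes).

## What it computes

For a 3 × 5 array of sensors (rows stacked vertically, columns horizontally,
long axis along x) the package solves the self-consistent magnetization
problem over all magnetostrictive layers,

    M(r) = χ [ H_applied(r) + H_demag(r; M) ],    χ = µr − 1,

by discretizing each layer into rectangular cells and using the exact closed
form for the field of a uniformly magnetized prism (dense method-of-moments
solve). The applied field is either a homogeneous H₀ (default 1 A/m along x)
or the exterior field of a current dipole (default 1 mA·m along y at
(30, −20, 30) mm) inside a spherically symmetric three-shell volume
conductor, evaluated with the Sarvas closed form.

Per sensor, spacing and excitation kind the report contains the mean |Bx|
and mean |B| in the magnetostrictive layer, the air-reference (χ = 0) value,
the flux-concentration ratio, and the open-circuit electrode voltage from a
single-mode Euler–Bernoulli model of the composite cantilever with
piezomagnetic drive and structural damping.

## Worked example

```python
import mearray as m

report = m.run_homogeneous_sweep(spacings=(5e-3, 50e-3))   # 1 A/m along x
met = m.crosstalk_metrics(report)
print(f"central-sensor reduction: {met['central_reduction_pct']:.1f} %")
print(f"corner-vs-central excess: {met['corner_excess_pct']:.1f} %")
print(f"S_2,3 mean |Bx| at 5 mm:  {report.value('S_2,3', 5e-3):.3e} T")
print(f"S_2,3 mean |Bx| at 50 mm: {report.value('S_2,3', 50e-3):.3e} T")

beam = m.CompositeBeam.from_sensor()
print(f"f1 = {m.resonance_frequency(beam):.1f} Hz")
```

prints

```
central-sensor reduction: 16.7 %
corner-vs-central excess: 8.5 %
S_2,3 mean |Bx| at 5 mm:  7.728e-04 T
S_2,3 mean |Bx| at 50 mm: 9.277e-04 T
f1 = 685.6 Hz
```

The central sensor S_2,3 loses 16.7 % of its internal flux when its
neighbors move from 50 mm to 5 mm away (the crosstalk effect), the corner
sensors — with the fewest close neighbors — exceed the central one by 8.5 %,
and the first bending mode of the stack sits at 686 Hz by composite beam
theory. The voltage-to-flux ratio V / mean|Bx| is position-independent to
machine precision under homogeneous excitation (the chain is linear), so
electric and magnetic crosstalk percentages coincide.

## Command line

```sh
mearray simulate --excitation homogeneous --out results/
mearray report results/report.json --plots
```

`simulate` writes `report.csv` / `report.json` (one row per sensor ×
spacing: label, row, col, spacing, excitation, mean_abs_Bx, mean_abs_B,
air_mean_abs_Bx, concentration_Bx, mean_abs_V, V_per_Bx; SI units, tesla and
volt) plus a provenance block; `report` prints the crosstalk metrics with
their defining formulas and optionally renders summary figures. All defaults
can be overridden through a YAML config (`--config`), documented in
`mearray.config.RunConfig`.

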