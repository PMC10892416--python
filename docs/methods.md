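# Methods

## Physical model

The simulation is one-way coupled and quasi-static, in three stages.

**1. Applied field.** At the working frequency (848 Hz) displacement and
eddy currents in tissue and air are negligible for the magnetic field, so
the excitation is evaluated in closed form: a homogeneous H₀, or a current
dipole inside a spherically symmetric three-shell conductor whose exterior
field follows the Sarvas formula

    B(r) = µ0/(4πF²) [ F Q×r₀ − (Q×r₀·r) ∇F ].

Two well-known properties of the spherical conductor are exploited and
tested: the exterior field is independent of the radial conductivity
profile, and radial dipole components are magnetically silent. The skin /
skull / white-matter conductivities (1.00 / 0.05 / 0.43 S/m) and
permittivities are carried on the head model for completeness and for
optional electric-field work, but they cannot influence the exterior B —
this is the price of the spherical stand-in, and it is a documented
limitation rather than an approximation error. The Sarvas evaluator is
validated against an independent Geselowitz boundary-integral oracle (a
Legendre-series surface potential integrated over a Gauss–Legendre sphere
quadrature); agreement is at the 10⁻¹⁰ level, asserted below 1 % in the
tests. A secondary stabilization dipole (1 µA·m, 2 mm below the main one)
is implemented as an off-by-default option: the original numerical setup
needed it, closed forms do not. The same applies to the artificial air
conductivity (10⁻⁶ S/m) used by vector-potential FEM formulations — noted,
not replicated.

**2. Magnetostatics (the crosstalk mechanism).** Only the magnetostrictive
films are magnetically active (χ = µr − 1 ≈ 10³); substrate, piezo film,
air and tissue have µr = 1. Each film (22.90 × 1.80 mm × 20 µm) is tiled
with nx × ny × nz rectangular cells carrying uniform magnetization. The
field of a uniformly magnetized prism is assembled from the closed-form
field of uniformly charged rectangles (log/arctan corner sums; the
principal-branch arctan gives the correct solid-angle branch on both sides
of each face). The self-term of a cubic cell is exactly −M/3 at the
center, which the tests pin against a brute-force surface-charge
integration. The self-consistency system (I − χK) M = χ H_applied is
solved densely by LU; a damped fixed-point fallback exists and reports its
residual on failure. Cell flux density is B = µ0 (H_applied + H_demag + M);
layer observables are volume-weighted means of |Bx| (and |B| — the two give
identical percentage metrics here; which one the published figures use is
ambiguous, so both are reported).

Default grid: **24 × 6 × 1 cells per film** (single cell through the 20 µm
thickness). The crosstalk percentages move by less than 0.1 points between
the 12 × 3 × 1 and 24 × 6 × 1 grids, so the property-test suites run on the
coarse grid and the headline numbers on the default grid. A point-dipole
far-field kernel can replace the exact prism kernel beyond a configurable
cutoff (off by default; it reproduces the exact operator to ~10⁻⁴).

**3. Transduction.** A single-mode clamped-free Euler–Bernoulli model of
the three-layer stack. Section properties use wide-beam plate moduli
E/(1 − ν²), justified by width-to-thickness ratios ≈ 8 for every layer.
The mean axial field in the MS film produces the actuation stress
σ = e_h,11 H_x, equivalent to the bending moment M₀ = e_h,11 H_x A_ms
(z_ms − z_n); modal projection with structural damping η gives the
curvature field, and the open-circuit condition D₃ = 0 in the AlN film
converts bending strain to the electrode potential
V(x) = e31,f ε₁(x) t_pe/(ε0 εr). The reported voltage is the mean |V| over
the electrode. A 10-mode superposition and a finite-difference eigensolver
serve as oracles (single-mode error < 2 % at resonance, eigenfrequency
agreement < 0.1 %).

Because the chain is linear and every sensor carries the same beam, the
ratio V/mean|Bx| is position-independent to machine precision under
homogeneous excitation. The published near-constancy of this ratio (spread
of a few percent, attributed there to numerical error) is therefore
reproduced trivially by construction in this reduced model; the meaningful
reproduction is that the *magnetic* responses vary strongly while the
ratio does not. Under dipole excitation the drive uses the signed mean of
H_x, so partial sign cancellation inside a film can lower the ratio — the
same qualitative outlier structure the full 3-D model shows.

## Parameters

| Parameter | Default | Units | Note |
|---|---|---|---|
| Layer dims (MS / sub / PE) | 22.90×1.80×0.020 / 26.25×2.45×0.300 / 25.60×1.60×0.020 | mm | published sensor geometry |
| FeCoSiB ρ, E, ν | 7250, 150e9, 0.33 | kg/m³, Pa, – | literature film values |
| FeCoSiB µr | 1000 | – | soft amorphous film, literature value; fixed a priori |
| FeCoSiB e_h,11 | 5700 | T | E·dλ/dH with small-signal slope 3.8e-8 (A/m)⁻¹ |
| Si ρ, E, ν | 2329, 170e9, 0.28 | kg/m³, Pa, – | standard |
| AlN stiffness, e31/e33, εr | hexagonal matrix, −0.58/1.55, 9 | Pa, C/m², – | c-axis textured film; e31,f ≈ −0.97 C/m² |
| Loss factor η | 0.01 | – | not published; free parameter, so absolute voltages are scale-bearing only — ratios and trends are the reliable outputs |
| Array | 3 × 5, spacings {5, 10, 20, 50} mm | – | edge-to-edge gaps between sensor bounding boxes |
| Standoff | 15 | mm | nearest MS face to head surface, exact by bisection |
| Head | shells at 100 / 97 / 94 mm | mm | 20 cm head, 3 mm skull |
| Grid | 24 × 6 × 1 cells per film | – | see convergence note above |

The constants above are standard literature values for these materials,
chosen once and documented here as the package defaults. The skull permittivity is
quoted in the literature as a range (4·10⁴–10⁶); the geometric mean 2·10⁵
is stored and configurable.

**Spacing convention.** "Distance between neighbors" is interpreted as the
edge-to-edge gap between sensor bounding boxes (center-to-center is
available as a flag). At 5 mm "distance" a center-to-center reading would
imply sub-width gaps inconsistent with the published drawings.

**Array placement.** Rows stack along z with the bottom row nearest the
head; for dipole excitation the array footprint is centered laterally over
the dipole, as a monitoring array over the source region would be. With
this placement the bottom row carries the five largest responses at close
spacings, as reported for the original model. Placement is configurable;
the lateral position noticeably reshuffles the per-column ordering.

**Vertical vs horizontal crosstalk.** The published comparison names no
formula. Here it is the central-sensor reduction of a 3 × 1 column minus
that of a 1 × 5 row at the same spacings, in percentage points (the
relative ratio is reported alongside). Vertically adjacent films couple
more strongly than horizontally adjacent ones (≈ 5.8 % vs ≈ 5.1 %
reduction at 5 mm), consistent with the published direction of the effect
and within its stated 11 % bound.

## What the stand-ins do and do not show

The head stand-in replaces an MRI-derived geometry with concentric
spheres: field evaluation is exact for the sphere, but realistic-geometry
effects (local curvature, skull thickness variation) are absent, so
agreement of dipole-sweep orderings with the published model is
qualitative. STL surfaces can be imported for geometry work (standoff
placement, nesting checks via winding numbers, distance queries) but do
not enter field evaluation. The magnetization solver resolves each film
with a single cell through its 20 µm thickness; this is adequate because
the films are three orders of magnitude thinner than long. The
flux-concentration ratio under dipole excitation is strongly
placement-dependent (its denominator — the air-reference |Bx| — can pass
near zero at unfavorable positions); the orders-of-magnitude spreads seen
in the full 3-D study arise from exactly such near-zeros and are not
reproduced at the default placement.

## Numerical choices and degenerate inputs

- Direct dense LU is the default solve (3N ≈ 6500 unknowns at the
  production grid, well under 1 GB); the fixed-point fallback damps by
  1/(1 + χ/3) and raises with its residual when it cannot converge.
- Coincident cell centers, non-finite applied fields, evaluation at a
  dipole position, probes inside the head, dipoles outside the innermost
  shell, zero air-reference denominators, η = 0 exactly at resonance, and
  non-watertight or empty STL surfaces are all rejected with specific
  errors.
- The whole pipeline is deterministic: reruns are byte-identical.

## Known limitations

- One-way coupling: the inverse magnetostrictive back-action of the
  vibrating films on the magnetic field is not modeled.
- Scalar isotropic susceptibility at the small-signal working point; no
  hysteresis, no tensor permeability.
- The first clamped-free mode of the stack computes to ≈ 686 Hz from
  composite beam theory with the constants above, whereas the original
  3-D model reports 848 Hz; since an Euler–Bernoulli model can only
  overestimate a 3-D resonance for the same constants, the difference
  points to stiffer material constants or a shorter effective clamped
  length in the original setup. Ratios and trends, not absolute
  frequencies or voltages, are the outputs this package stands behind.
- Tissue permittivity and frequency dispersion play no role in the
  exterior magnetic field by construction.
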