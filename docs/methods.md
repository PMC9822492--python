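# Methods

## Geometry: from brick-and-mortar mosaic to one capillary

The stratum corneum is modelled as a periodic mosaic of rectangular
keratinocyte bricks (`a x b` footprint, height `h_k`) on a patch
`L1 x L2`, separated by lipid channels of widths `d1`, `d2`. The number of
bricks per row, `n = (L + d)/(a + d)`, is kept **real-valued**: the exact
ratio makes `a·n + (n − 1)·d` reconstruct `L` to machine precision, which
the area algebra relies on. (An integer-tiled patch appears only as the
brute-force oracle in the tests.)

The areal lipid fraction is `ε = (S − S_n)/S` with `S = L1·L2` and
`S_n = (a n1)(b n2)`; the specific surface of a brick is
`a_p = 2(ab + b·h_k + a·h_k)/(a·b·h_k)` — all six faces counted. The
equivalent-capillary hydraulic radius follows the Kozeny–Carman form
`r_h = ε/(a_p(1 − ε))`. With the reference parameters (L = 2 cm,
a = b = 20 µm, d = 50 nm, h_k = 10 µm) this yields ε = 4.976·10⁻³,
a_p = 4.0·10⁵ 1/m and r_h = 12.5 nm. A `half_specific_surface` flag
exposes the three-face convention (which doubles r_h) for comparison; the
six-face form is the default because it is the literal surface-to-volume
ratio of the brick and it reproduces the 12.5 nm reference value.

Two distinct lengths appear and are deliberately separate fields: the
keratinocyte height `h_k = 10 µm` used in the geometry reduction, and the
capillary (diffusion) length `h = 1 µm` used by the simulator and the Hill
fits.

## Transport physics

Brownian force scale `σ_F = √(6π k_B η T d_p/Δt)` per Cartesian component
(standard-normal multiplier) and Stokes drag `γ = 3π η d_p` satisfy
fluctuation–dissipation exactly: `(σ_F Δt/γ)² = 2 D Δt` with
`D = k_B T/γ`. `k_B = 1.381·10⁻²³ J/K` is defined in one place. The
momentum relaxation time `τ = ρ_p d_p²/(18η)` is ~10⁻¹³ s across the study
grid — at least five orders below any usable time step — so the
**overdamped** scheme (positions advanced by `√(2DΔt)` Gaussian steps) is
the default. A semi-implicit Langevin scheme (velocity with implicit drag)
is retained to mirror the force balance literally; its long-time
diffusivity equals `D` exactly for any Δt, and it agrees with the
overdamped scheme in passage-curve law.

A separate operation evaluates the Stokes–Einstein relation with the
**diameter** in the denominator, `k_B T/(6π η d_p)` — half the standard
radius-form value. It exists solely to rebuild a published free-vs-
effective diffusivity comparison computed in that form, and the comparison
pipeline evaluates it at **293 K**, the temperature at which that
published column is numerically consistent (the 298 K quoted alongside it
is ~2% off). The physics default elsewhere is 298 K.

## Capillary simulation

Particles are released with centres at 30 nm depth, laterally uniform over
the accessible disk. Finite size enters only through the accessible radius
`r_acc = r_h − d_p/2` (centre-excluded shell); no hydrodynamic wall
retardation is modelled. Boundary handling per step: absorption is decided
first on the straight proposed segment (centre crossing the bottom plane
`z = length`; a `surface_contact` flag moves the plane to
`length − d_p/2`), then specular reflection at the top plane and at the
cylindrical wall, iterated to at most 64 bounces (an error beyond that).
The automatic time step caps the per-axis RMS step at
`min(r_acc/5, release_offset/3)` and requires `Δt ≥ 100τ`.

Because lateral reflections never change the axial coordinate, the passage
law is exactly the 1-D reflecting/absorbing first-passage solution for any
particle size. That solution is implemented as the eigenfunction series
for `D t/L² ≥ 0.05` (truncated when the next term's envelope drops below
10⁻¹²) and the two-image `erfc` form below it (the first neglected image
contributes < 10⁻²⁰ at the crossover); its time integral reproduces the
closed-form mean first-passage time `(L² − x0²)/(2D)` to 10⁻⁶ relative,
verified by quadrature.

Two engines realise the same law: a numba per-particle kernel (default;
one Mersenne–Twister stream consumed particle by particle, bit-reproducible
from the seed) and a vectorised numpy driver built from the public
step/boundary operations, used for the Langevin scheme and as a
cross-check. First-passage times are recorded per particle and the
cumulative curve is assembled afterwards on a 200-point log-spaced grid
(plus `t_end`), which is exact on any grid and allows stopping as soon as
every particle is absorbed. Absorption times are quantised to step ends;
the induced bias on the mean passage time is ≈ Δt plus a barrier-
discretisation term of order `0.6·√(2DΔt)/L`, ~0.3% at the default step —
well inside binomial noise at N ≤ 5000.

## Hill model and fitting

From Fick's first law on the capillary, the cumulative passage fraction is
`F(t) = D_eff t^n/(h² + D_eff t^n)`. The diffusion length is **fixed** at
`h = 1 µm` during fitting — D_eff, n and h are not jointly identifiable in
this functional form. Fits are unweighted least squares on the fraction
scale over absolute time (normalised time would only rescale D_eff by a
known power factor `t_c^n`), with `D_eff` optimised in log scale,
`n ∈ (0, 5]`, initialised by the exactly-linear logit regression
`log(F/(1−F)) = log(D_eff/h²) + n log t` over interior points (clipped 0/1
points are excluded from the initialiser but kept in the nonlinear fit).
Non-convergence sets a flag instead of raising. R² is `1 − SS_res/SS_tot`
on the fraction scale.

The synthetic-curve generator evaluates the Hill form on a grid, adds
independent Gaussian noise (absolute, fraction scale), clips to [0, 1] and
restores monotonicity by running maximum — emulating digitised cumulative
counts with measurement noise. It does not emulate binomial counting
noise, correlated drift, or the early-time lag of a true first-passage
curve, so fit-recovery results on it demonstrate estimator correctness,
not robustness to those real-data features.

## Sweeps and the free/effective comparison

`run_sweep` simulates every (d_p, η) cell with seed `base + cell index`,
sizes each run as 20× the cell's analytic mean first-passage time (a
desk-scale surrogate for the reference protocol's fixed 500 s window,
which remains available via `t_end_s`), fits the Hill model with
`h = 1 µm`, and writes deterministic CSVs. The default cell budget of
1000 particles (5000 in the packaged reference config) keeps a 2×2 corner
sweep in minutes on one CPU.

On ideal-Brownian passage curves the fitted exponents come out near
`n ≈ 2` and the fitted `D_eff` well above the published effective values:
an ideal Brownian walk crosses the 1 µm capillary in ~0.01–1 s, far faster
than the reference finite-element particle tracer, whose time step, wall
treatment and inertia handling are not stated. The sweep's transferable
content is therefore the strict ordering of `D_eff` (decreasing in both
particle size and viscosity) and the high fit quality (R² > 0.99), not the
absolute `D_eff` scale; the quantitative surface of the simulator is its
agreement with the exact first-passage law.

Known misprints handled in the comparison table: the 10 mPa·s free-
diffusivity column is low by exactly 10× and the 10/15 nm ratios in that
column are mutually swapped (both confirmed by recomputation); the
affected cells are excluded from automated assertions.

## Numerical and design choices

- Counts, areas and radii are double precision throughout; the geometry
  oracle equivalence is asserted to 10⁻¹².
- RNG: one seeded generator per run; sweep cells use consecutive seeds;
  everything downstream of a seed is bit-reproducible.
- Degenerate inputs fail loudly: zero lipid channels (ε = 0) build no
  capillary, a particle wider than the capillary is rejected ("particle
  larger than capillary"), an RMS-step rule that collides with the
  overdamped validity bound raises a configuration error.
- Curve comparisons in tests use 3 binomial standard errors plus a 1/N
  discreteness allowance, with the exact law supplying the variance.

## Limitations

- No inter-particle interactions, flow, electrostatics or hindered
  (Renkin-type) diffusion; walls act purely geometrically.
- Single capillary only: no multi-layer stacking, no tortuosity or offset
  brick arrangements, no horizontal lipid-layer resistance.
- The Hill exponent is treated as an empirical shape parameter, with no
  mechanistic interpretation.
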