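# dermadiff

Modelling toolkit for nanoparticle diffusion through the stratum corneum —
the outermost, rate-limiting layer of skin — aimed at transdermal drug- and
cosmetic-delivery studies. It couples two models:

1. **Geometry reduction.** The stratum corneum is idealised as a
   brick-and-mortar mosaic: rectangular keratinocytes of footprint `a x b`
   and height `h_k` on a patch `L1 x L2`, separated by lipid channels of
   width `d1, d2`. Since transport proceeds only through the lipid
   channels, the network is collapsed, following the Kozeny–Carman
   treatment of granular beds, into a single equivalent capillary of
   hydraulic radius

   ```
   r_h = ε / (a_p (1 − ε)),    ε = (S − S_n)/S,    a_p = S_p/V_p
   ```

   where `ε` is the areal lipid fraction and `a_p` the specific surface of
   one keratinocyte. With the reference parameters (2 cm patch, 20 µm
   keratinocytes, 50 nm channels, 10 µm keratinocyte height) this gives
   `r_h = 12.5 nm`, i.e. a capillary diameter of 25 nm and length 1 µm.

2. **Transport in the capillary.** Nanoparticles (1–15 nm, density
   2200 kg/m³) in a liquid of viscosity 10–50 mPa·s undergo Brownian
   motion: a stochastic force of per-axis scale `σ_F = √(6π k_B η T d_p/Δt)`
   balanced by Stokes drag `γ = 3π η d_p`. The simulator releases particles
   30 nm below the top of the capillary, reflects them specularly off the
   top plane and cylindrical wall, and absorbs them at the bottom. The
   cumulative absorbed fraction — the passage curve `N_pt/N_p0` — is then
   fitted with the Hill-form diffusion model derived from Fick's first law,

   ```
   N_pt/N_p0 = D_eff t^n / (h² + D_eff t^n)
   ```

   with diffusion length `h` fixed at 1 µm, yielding an effective diffusion
   coefficient `D_eff` and shape exponent `n` per particle size and
   viscosity. A closed-form reflecting/absorbing first-passage solution
   serves as an exact reference law for validating the simulator.

## Worked example

`python examples/01_capillary_geometry.py`:

```
keratinocytes per row     : 997.509
lipid area fraction eps   : 4.9763e-03
specific surface a_p      : 4.0000e+05 1/m
hydraulic radius r_h      : 12.503 nm
capillary diameter d_c    : 25.006 nm
capillary length          : 1.0 um
```

Only ~0.5% of the patch surface is lipid channel; the whole network is
equivalent to one 25 nm wide, 1 µm long capillary. `examples/02` simulates
passage through it (500 particles with the diffusivity of a 5 nm sphere in
10 mPa·s, `D = 8.733e-12 m²/s`) and prints a simulated mean passage time of
`0.0604 s` against the exact `(L² − x0²)/(2D) = 0.0572 s`; `examples/03`
recovers known Hill parameters from a noisy curve (`D_eff` 9.5% off, `n`
0.2% off at 2% noise, R² = 0.996); `examples/04` runs a small
size × viscosity sweep and tabulates fitted `D_eff` against the free
Stokes–Einstein value.

The same functionality is exposed as a thin CLI:

```
dermadiff geometry                      # capillary reduction as JSON
dermadiff simulate --dp 5e-9 --eta 0.01 --out curve.csv
dermadiff fit --curve curve.csv --h 1e-6
dermadiff sweep --config src/dermadiff/configs/default_sweep.yaml --out-dir runs/
dermadiff compare --deff-table runs/deff_table.csv --out comparison.csv
```

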