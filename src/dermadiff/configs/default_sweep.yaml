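# Reference sweep over the equivalent skin capillary:
# 2 cm patch, 20 um keratinocytes, 50 nm lipid channels -> r_h = 12.5 nm
# capillary; mineral nanoparticles (2200 kg/m^3) in liquids of 10/20/50
# mPa s; 5000 particles released 30 nm below the top, run to 500 s.
diameters_nm: [1, 5, 10, 15]
viscosities_mPas: [10, 20, 50]
n_particles: 5000
t_end_s: 500.0
temperature_K: 298.0
fluid_density_kg_m3: 1000.0
particle_density_kg_m3: 2200.0
release_offset_m: 3.0e-8
capillary_length_m: 1.0e-6
seed: 0
scheme: overdamped
geometry:
  L1_m: 0.02
  L2_m: 0.02
  a_m: 2.0e-5
  b_m: 2.0e-5
  d1_m: 5.0e-8
  d2_m: 5.0e-8
  h_k_m: 1.0e-5
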