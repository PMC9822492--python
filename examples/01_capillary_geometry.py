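"""Reduce a brick-and-mortar skin patch to its equivalent capillary.

A 2 cm x 2 cm patch of stratum corneum tiled with 20 um keratinocytes
separated by 50 nm lipid channels is collapsed, Kozeny-Carman style, into a
single cylindrical capillary through which all diffusion is taken to occur.
"""

from dermadiff import BrickMortarGeometry, build_capillary, keratinocyte_count

geom = BrickMortarGeometry.square(L=0.02, a=2e-5, d=5e-8, h_k=1e-5)
cap = build_capillary(geom, length=1e-6)

print(f"keratinocytes per row     : {keratinocyte_count(0.02, 2e-5, 5e-8):.3f}")
print(f"lipid area fraction eps   : {cap.epsilon:.4e}")
print(f"specific surface a_p      : {cap.a_p:.4e} 1/m")
print(f"hydraulic radius r_h      : {cap.r_h * 1e9:.3f} nm")
print(f"capillary diameter d_c    : {cap.d_c * 1e9:.3f} nm")
print(f"capillary length          : {cap.length * 1e6:.1f} um")
print()
print("Only ~0.5% of the patch surface is lipid channel, and the channel")
print("network is equivalent to one 25 nm wide, 1 um long capillary - the")
print("bottleneck nanoparticles must diffuse through to cross the layer.")
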