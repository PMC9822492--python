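"""Fit the Hill passage model to a noisy synthetic curve.

Generates a passage curve from known Hill parameters (D_eff, n) with 2%
measurement noise, then recovers them by bounded nonlinear least squares
with the diffusion length h fixed at 1 um.
"""

import numpy as np

from dermadiff import fit_hill, generate_hill_curve

H = 1e-6
D_TRUE, N_TRUE = 5e-13, 0.8
times = np.geomspace(0.05, 500.0, 200)

curve = generate_hill_curve(D_TRUE, N_TRUE, H, times, noise_sd=0.02, seed=3)
fit = fit_hill(curve, H)

print(f"true  D_eff = {D_TRUE:.3e} m^2/s, n = {N_TRUE:.3f}")
print(f"fitted D_eff = {fit.D_eff:.3e} m^2/s ({abs(fit.D_eff-D_TRUE)/D_TRUE:.1%} off)")
print(f"fitted n     = {fit.n:.3f} ({abs(fit.n-N_TRUE)/N_TRUE:.1%} off)")
print(f"R^2          = {fit.r_squared:.4f}  converged = {fit.converged}")
print()
print("D_eff sets how fast the cumulative fraction saturates towards 1;")
print("the exponent n reshapes the curve (n = 1 is the plain Fickian")
print("balance).  With 2% noise both are recovered to within a few percent.")
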