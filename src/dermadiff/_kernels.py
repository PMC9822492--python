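"""Compiled inner loop for the overdamped passage simulation.

One particle at a time is advanced with scalar Gaussian increments until it
crosses the absorbing plane or the step budget runs out; lateral excursions
reflect specularly off the cylinder wall, axial ones off the top plane.
The per-particle sequential layout keeps the hot loop free of array
allocation and is bit-reproducible from the seed (one Mersenne-Twister
stream consumed particle by particle).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_MAX_BOUNCES = 64


@njit(cache=True)
def overdamped_passage_kernel(
    x0: np.ndarray,
    y0: np.ndarray,
    z0: np.ndarray,
    sigma: float,
    n_steps: int,
    r_acc2: float,
    plane: float,
    seed: int,
) -> np.ndarray:
    """First-passage step index per particle (-1 if never absorbed).

    ``sigma`` is the per-axis step scale sqrt(2*D*dt); ``r_acc2`` the squared
    accessible radius (pass inf to disable the lateral wall); ``plane`` the
    absorbing plane for particle centres.  Absorption is tested on the
    straight proposed segment before any reflection.
    """
    n = x0.size
    out = np.full(n, -1, dtype=np.int64)
    np.random.seed(seed)
    for i in range(n):
        x = x0[i]
        y = y0[i]
        z = z0[i]
        for s in range(n_steps):
            zn = z + sigma * np.random.standard_normal()
            if zn >= plane:
                out[i] = s + 1
                break
            if zn < 0.0:
                zn = -zn
            xn = x + sigma * np.random.standard_normal()
            yn = y + sigma * np.random.standard_normal()
            r2 = xn * xn + yn * yn
            if r2 > r_acc2:
                bounce = 0
                while r2 > r_acc2 and bounce < _MAX_BOUNCES:
                    dx = xn - x
                    dy = yn - y
                    aa = dx * dx + dy * dy
                    bb = 2.0 * (x * dx + y * dy)
                    cc = x * x + y * y - r_acc2
                    disc = bb * bb - 4.0 * aa * cc
                    if disc < 0.0:
                        disc = 0.0
                    if aa > 0.0:
                        frac = (-bb + math.sqrt(disc)) / (2.0 * aa)
                    else:
                        frac = 0.0
                    if frac < 0.0:
                        frac = 0.0
                    elif frac > 1.0:
                        frac = 1.0
                    hx = x + frac * dx
                    hy = y + frac * dy
                    hn = math.sqrt(hx * hx + hy * hy)
                    if hn == 0.0:
                        break
                    nx = hx / hn
                    ny = hy / hn
                    rx = xn - hx
                    ry = yn - hy
                    dot = rx * nx + ry * ny
                    rx -= 2.0 * dot * nx
                    ry -= 2.0 * dot * ny
                    x = hx
                    y = hy
                    xn = hx + rx
                    yn = hy + ry
                    r2 = xn * xn + yn * yn
                    bounce += 1
            x = xn
            y = yn
            z = zn
    return out
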