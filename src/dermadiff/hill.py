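"""Hill-equation model of the passage curve and its nonlinear fitting.

Starting from Fick's first law on the capillary, the cumulative passage
fraction takes the saturating form

    N_pt / N_p0 = D_eff * t^n / (h^2 + D_eff * t^n)

mathematically a Hill equation, with ``D_eff`` the effective diffusion
coefficient, ``h`` the diffusion length (the capillary length, held fixed
during fitting — a third free parameter would be degenerate with this
functional form), and ``n`` an empirical shape exponent (``n = 1`` is the
plain Fickian balance).  Fits are unweighted least squares on the fraction
scale over absolute time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np
from scipy.optimize import least_squares

from .simulate import PassageCurve

__all__ = [
    "HillFit",
    "hill_fraction",
    "linearized_init",
    "fit_hill",
    "generate_hill_curve",
]


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters for one passage curve.

    ``h`` is the fixed diffusion length used in the fit, not a fitted
    quantity.  ``converged`` is False when the optimiser failed; the best
    point found is still reported.
    """

    D_eff: float
    n: float
    h: float
    r_squared: float
    converged: bool
    residual_norm: float

    def __post_init__(self) -> None:
        if self.converged and not (self.D_eff > 0 and self.n > 0):
            raise ValueError("converged fit must have positive D_eff and n")
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")


def hill_fraction(
    D_eff: float, n: float, h: float, t: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Evaluate the Hill passage fraction D_eff*t^n / (h^2 + D_eff*t^n).

    Strictly increasing in ``t``, 0 at ``t = 0``, 1 in the long-time limit,
    and exactly 1/2 where ``D_eff * t^n = h^2``.
    """
    if not (D_eff > 0 and n > 0 and h > 0):
        raise ValueError("D_eff, n and h must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    x = D_eff * np.power(t_arr, n)
    out = x / (h**2 + x)
    if np.ndim(t) == 0:
        return float(out)
    return out


def linearized_init(curve: PassageCurve, h: float) -> Tuple[float, float]:
    """Initial (D_eff, n) from the exactly linear logit transform.

    On noiseless Hill data, ``log(F/(1-F)) = log(D_eff/h^2) + n*log(t)`` is
    an exact straight line; ordinary least squares over the interior points
    (0 < F < 1, t > 0) recovers the parameters.  Used to initialise the
    nonlinear fit.
    """
    f = np.asarray(curve.fraction, dtype=float)
    t = np.asarray(curve.times, dtype=float)
    mask = (f > 0.0) & (f < 1.0) & (t > 0.0)
    if mask.sum() < 3:
        raise ValueError("need at least 3 interior points (0 < fraction < 1) to initialise")
    y = np.log(f[mask] / (1.0 - f[mask]))
    x = np.log(t[mask])
    n0, intercept = np.polyfit(x, y, 1)
    d0 = h**2 * math.exp(intercept)
    # fall back to a Fickian guess if the data are too degenerate
    if not (d0 > 0 and np.isfinite(d0)):
        d0 = h**2 / max(t[mask][-1], 1.0)
    n0 = float(np.clip(n0, 1e-3, 5.0))
    return float(d0), n0


def fit_hill(curve: PassageCurve, h: float) -> HillFit:
    """Bounded nonlinear least squares of the Hill form with fixed ``h``.

    Free parameters ``D_eff in (0, inf)`` and ``n in (0, 5]``, initialised
    by :func:`linearized_init`; residuals on the fraction scale over all
    points (clipped endpoints included).  Non-convergence is reported via
    the ``converged`` flag rather than an exception.  ``r_squared`` is
    1 - SS_res/SS_tot on the fraction scale.
    """
    if not (h > 0):
        raise ValueError("h must be positive")
    f = np.asarray(curve.fraction, dtype=float)
    t = np.asarray(curve.times, dtype=float)
    try:
        d0, n0 = linearized_init(curve, h)
    except ValueError:
        d0, n0 = h**2 / max(float(t[-1]), 1.0), 1.0

    # optimise in log D_eff for scale invariance; n stays linear
    def residuals(theta: np.ndarray) -> np.ndarray:
        log_d, n = theta
        x = math.exp(log_d) * np.power(t, n, where=t > 0, out=np.zeros_like(t))
        return x / (h**2 + x) - f

    tiny = 1e-300
    result = least_squares(
        residuals,
        x0=np.array([math.log(max(d0, tiny)), n0]),
        bounds=([-700.0, 1e-9], [700.0, 5.0]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    d_fit = math.exp(result.x[0])
    n_fit = float(result.x[1])
    ss_res = float(np.sum(result.fun**2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -math.inf)
    return HillFit(
        D_eff=d_fit,
        n=n_fit,
        h=h,
        r_squared=r2,
        converged=bool(result.success),
        residual_norm=math.sqrt(ss_res),
    )


def generate_hill_curve(
    D_eff: float,
    n: float,
    h: float,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_p0: int = 5000,
) -> PassageCurve:
    """Synthetic passage curve drawn from the Hill model.

    Evaluates the Hill fraction on ``times``, adds independent Gaussian
    noise of standard deviation ``noise_sd`` (absolute, on the fraction
    scale), clips to [0, 1] and enforces monotone cumulative counts by a
    running maximum.  Reproducible from ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    times = np.asarray(times, dtype=float)
    f = np.asarray(hill_fraction(D_eff, n, h, times), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + noise_sd * rng.standard_normal(f.shape)
    f = np.maximum.accumulate(np.clip(f, 0.0, 1.0))
    return PassageCurve(
        times=times,
        n_passed=f * n_p0,
        fraction=f,
        n_p0=n_p0,
        meta={
            "generator": "hill",
            "D_eff_m2_s": D_eff,
            "n": n,
            "h_m": h,
            "noise_sd": noise_sd,
            "seed": seed,
            "t_end": float(times[-1]),
        },
    )
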