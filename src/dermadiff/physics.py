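"""Particle and fluid records with the closed-form force/diffusion relations.

A nanoparticle suspended in the lipid fluid feels a stochastic Brownian force
and a Stokes drag.  In the overdamped regime (momentum relaxation time
``tau = m_p/gamma`` far below any usable time step) the two combine into pure
Brownian motion with the Einstein free diffusivity ``D = k_B*T/gamma``.

The module also carries, as a deliberately separate operation, a
Stokes-Einstein variant with the particle *diameter* in place of the radius
in the denominator (``k_B*T / (6*pi*eta*d_p)``), used only to rebuild a
published comparison table that was computed in that form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Boltzmann constant, J/K.
K_B = 1.381e-23


@dataclass(frozen=True)
class ParticleSpec:
    """Spherical nanoparticle: diameter ``d_p`` (m), density ``rho_p`` (kg/m^3)."""

    d_p: float
    rho_p: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d_p) and self.d_p > 0):
            raise ValueError(f"d_p must be positive, got {self.d_p!r}")
        if not (math.isfinite(self.rho_p) and self.rho_p > 0):
            raise ValueError(f"rho_p must be positive, got {self.rho_p!r}")

    @property
    def m_p(self) -> float:
        """Particle mass, kg: rho_p * pi * d_p^3 / 6."""
        return self.rho_p * math.pi * self.d_p**3 / 6.0


@dataclass(frozen=True)
class Fluid:
    """Suspending medium: viscosity ``eta`` (Pa s), density (kg/m^3), T (K)."""

    eta: float
    rho_f: float = 1000.0
    T: float = 298.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.eta) and self.eta > 0):
            raise ValueError(f"eta must be positive, got {self.eta!r}")
        if not (math.isfinite(self.T) and self.T > 0):
            raise ValueError(f"T must be positive, got {self.T!r}")


def drag_coefficient(p: ParticleSpec, f: Fluid) -> float:
    """Stokes drag coefficient gamma = 3*pi*eta*d_p, kg/s.

    Algebraically identical to the mass form ``18*eta*m_p/(rho_p*d_p^2)``
    once ``m_p = rho_p*pi*d_p^3/6`` is substituted, so the drag force
    ``F_S = gamma*v`` is the familiar Stokes force on a sphere.
    """
    return 3.0 * math.pi * f.eta * p.d_p


def brownian_force_scale(p: ParticleSpec, f: Fluid, dt: float) -> float:
    """Per-component Brownian force magnitude sigma_F, N.

    sigma_F = sqrt(6*pi*k_B*eta*T*d_p / dt).  The stochastic force applied
    over a step of length ``dt`` is ``zeta * sigma_F`` per Cartesian
    component with ``zeta`` an independent standard-normal draw.  This scale
    satisfies fluctuation-dissipation exactly:
    ``(sigma_F*dt/gamma)^2 = 2*D_free*dt``.
    """
    if not (math.isfinite(dt) and dt > 0):
        raise ValueError(f"dt must be positive, got {dt!r}")
    return math.sqrt(6.0 * math.pi * K_B * f.eta * f.T * p.d_p / dt)


def free_diffusion_coefficient(p: ParticleSpec, f: Fluid) -> float:
    """Free Einstein diffusivity D = k_B*T / (3*pi*eta*d_p), m^2/s.

    This is ``k_B*T/gamma`` — the diffusivity the simulated Brownian
    dynamics actually realises — and coincides with the standard
    Stokes-Einstein relation ``k_B*T/(6*pi*eta*r)`` written with the radius
    ``r = d_p/2``.
    """
    return K_B * f.T / drag_coefficient(p, f)


def stokes_einstein_printed(p: ParticleSpec, f: Fluid) -> float:
    """Stokes-Einstein with the *diameter* in the denominator, m^2/s.

    D = k_B*T / (6*pi*eta*d_p): exactly half the standard (radius-form)
    value.  Kept as its own operation solely to rebuild the published
    free-vs-effective diffusivity comparison, which used this form; do not
    use it as a physical free diffusivity.
    """
    return K_B * f.T / (6.0 * math.pi * f.eta * p.d_p)


def momentum_relaxation_time(p: ParticleSpec, f: Fluid) -> float:
    """Momentum relaxation time tau = m_p/gamma = rho_p*d_p^2/(18*eta), s.

    For nanometre particles in mPa-s fluids tau is ~1e-13 s, many orders
    below any feasible time step, which justifies the overdamped default of
    the simulator.
    """
    return p.rho_p * p.d_p**2 / (18.0 * f.eta)
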