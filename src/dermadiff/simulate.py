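"""Stochastic particle tracing in the equivalent capillary.

Particles are released near the top of a cylindrical capillary (radius
``r_h``, length ``L``), reflect specularly off the top plane and the
cylindrical wall, and are absorbed the first time they cross the bottom
plane.  The cumulative fraction absorbed versus time — the passage curve —
is the simulator's primary output.

Axial motion is one-dimensional reflected/absorbed Brownian motion and is
unaffected by lateral wall bounces, so the closed-form first-passage
solution (:func:`first_passage_fraction`) is an exact reference law for the
passage curve at any particle size.  Finite particle size enters only
through the accessible radius ``r_acc = r_h - d_p/2`` (centre-excluded
shell); no hydrodynamic wall retardation is modelled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import erfc

from .geometry import CapillaryEquivalent
from .physics import (
    Fluid,
    ParticleSpec,
    brownian_force_scale,
    drag_coefficient,
    free_diffusion_coefficient,
    momentum_relaxation_time,
)

__all__ = [
    "SimulationConfig",
    "PassageCurve",
    "auto_timestep",
    "step_overdamped",
    "step_langevin",
    "apply_boundaries",
    "run_simulation",
    "first_passage_fraction",
    "mean_first_passage_time",
]

_MAX_BOUNCES = 64


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one passage-curve run.

    Parameters
    ----------
    capillary, particle, fluid
        Geometry and material records.
    n_particles
        Number of released particles N_p0.
    t_end
        End time of the run, s.  The run stops early once every particle is
        absorbed; the recorded curve still extends to ``t_end``.
    dt
        Time step, s, or ``"auto"`` to derive it from the step-size rule of
        :func:`auto_timestep`.
    record_times
        Ascending times at which cumulative counts are reported; default is
        200 log-spaced points from ``dt`` to ``t_end`` plus ``t_end``.
    release_offset
        Release depth of particle centres below the top plane, m.
    seed
        Seed for the single numpy Generator; runs are bit-reproducible.
    scheme
        ``"overdamped"`` (default) or ``"langevin"`` (explicit velocity with
        semi-implicit drag; agrees with overdamped for dt >> tau).
    engine
        ``"compiled"`` (default): numba per-particle kernel, overdamped
        scheme only; ``"reference"``: vectorised numpy loop built from
        :func:`step_overdamped`/:func:`step_langevin` and
        :func:`apply_boundaries`.  Both engines realise the same law; their
        random streams differ.
    lateral_wall
        Disable to let particles ignore the cylindrical wall (axial motion,
        hence the passage law, is unaffected; used to check that
        decoupling).
    point_particle
        Ignore the particle's geometric size: accessible radius equals
        ``r_h`` and absorption uses the centre plane.  The physics (drag,
        diffusivity) still follows ``particle``.
    surface_contact
        Absorb when the particle *surface* reaches the bottom, i.e. centre
        plane at ``length - d_p/2``, instead of the default centre-crossing
        plane at ``length``.
    """

    capillary: CapillaryEquivalent
    particle: ParticleSpec
    fluid: Fluid
    n_particles: int = 5000
    t_end: float = 500.0
    dt: Union[float, str] = "auto"
    record_times: Optional[np.ndarray] = None
    release_offset: float = 3e-8
    seed: int = 0
    scheme: str = "overdamped"
    point_particle: bool = False
    surface_contact: bool = False
    engine: str = "compiled"
    lateral_wall: bool = True

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if not (self.t_end > 0):
            raise ValueError("t_end must be positive")
        if self.scheme not in ("overdamped", "langevin"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.engine not in ("compiled", "reference"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if not (0 <= self.release_offset < self.capillary.length):
            raise ValueError("release_offset must lie inside the capillary")
        if self.accessible_radius <= 0:
            raise ValueError(
                "particle larger than capillary: accessible radius "
                f"r_h - d_p/2 = {self.accessible_radius:.3e} m is not positive"
            )

    @property
    def accessible_radius(self) -> float:
        """Radius available to particle centres, m."""
        if self.point_particle:
            return self.capillary.r_h
        return self.capillary.r_h - self.particle.d_p / 2.0

    @property
    def absorbing_plane(self) -> float:
        """Axial coordinate of the absorbing plane for particle centres, m."""
        if self.surface_contact and not self.point_particle:
            return self.capillary.length - self.particle.d_p / 2.0
        return self.capillary.length

    @property
    def diffusivity(self) -> float:
        """Free diffusivity realised by the dynamics, m^2/s."""
        return free_diffusion_coefficient(self.particle, self.fluid)

    def resolved_dt(self) -> float:
        if self.dt == "auto":
            return auto_timestep(self)
        dt = float(self.dt)  # type: ignore[arg-type]
        if not (dt > 0):
            raise ValueError("dt must be positive")
        return dt


@dataclass
class PassageCurve:
    """Cumulative passage curve N_pt / N_p0 on a time grid.

    ``first_passage_times`` holds each particle's absorption time (NaN for
    particles still inside at ``t_end``); the cumulative counts derive from
    it exactly on any grid.
    """

    times: np.ndarray
    n_passed: np.ndarray
    fraction: np.ndarray
    n_p0: int
    meta: dict = field(default_factory=dict)
    first_passage_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.n_passed = np.asarray(self.n_passed, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be ascending")
        if np.any(np.diff(self.n_passed) < 0):
            raise ValueError("cumulative counts must be non-decreasing")
        if np.any((self.fraction < 0) | (self.fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def normalized_times(self) -> np.ndarray:
        """t / t_c with t_c the end time of the run."""
        t_c = self.meta.get("t_end", self.times[-1])
        return self.times / t_c

    def mean_passage_time(self) -> float:
        """Mean first-passage time of the absorbed particles, s."""
        if self.first_passage_times is None:
            raise ValueError("per-particle passage times were not recorded")
        finite = self.first_passage_times[np.isfinite(self.first_passage_times)]
        if finite.size == 0:
            return math.nan
        return float(finite.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "time_norm": self.normalized_times,
                "n_passed": self.n_passed,
                "fraction": self.fraction,
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write the curve as CSV plus a JSON sidecar echoing the config."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"n_p0": self.n_p0, **self.meta}, indent=2))

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "PassageCurve":
        path = Path(path)
        df = pd.read_csv(path)
        meta: dict = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        n_p0 = int(meta.pop("n_p0", round(df["n_passed"].iloc[-1] / max(df["fraction"].iloc[-1], 1e-300))))
        return cls(
            times=df["time_s"].to_numpy(),
            n_passed=df["n_passed"].to_numpy(),
            fraction=df["fraction"].to_numpy(),
            n_p0=n_p0,
            meta=meta,
        )


def auto_timestep(cfg: SimulationConfig) -> float:
    """Largest admissible time step for a configuration, s.

    The per-axis RMS step ``sqrt(2*D*dt)`` is capped at the smaller of a
    fifth of the accessible radius and a third of the release offset, so a
    single step neither spans the cross-section nor jumps straight from the
    release plane to a wall.  The resulting dt must still exceed 100x the
    momentum relaxation time for the overdamped scheme to be valid;
    violating both constraints at once raises a configuration error.
    """
    r_acc = cfg.accessible_radius
    cap = min(r_acc / 5.0, cfg.release_offset / 3.0)
    if cap <= 0:
        raise ValueError("cannot derive dt: zero step-size cap (release at top?)")
    dt = cap**2 / (2.0 * cfg.diffusivity)
    tau = momentum_relaxation_time(cfg.particle, cfg.fluid)
    if dt < 100.0 * tau:
        raise ValueError(
            f"infeasible auto timestep: dt={dt:.3e} s < 100*tau={100 * tau:.3e} s"
        )
    return dt


def step_overdamped(
    positions: np.ndarray, D: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Free overdamped Brownian update: x += sqrt(2*D*dt) * zeta per axis.

    Equal in law to balancing the Brownian force against Stokes drag,
    (F_B/gamma)*dt with F_B = zeta*sigma_F, by fluctuation-dissipation.
    """
    return positions + math.sqrt(2.0 * D * dt) * rng.standard_normal(positions.shape)


def step_langevin(
    positions: np.ndarray,
    velocities: np.ndarray,
    p: ParticleSpec,
    f: Fluid,
    dt: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Velocity-explicit update with semi-implicit Stokes drag.

    m dv = (-gamma*v + zeta*sigma_F) dt, drag taken at the new velocity:
    v' = (v + zeta*sigma_F*dt/m) / (1 + gamma*dt/m),  x' = x + v'*dt.
    For dt >> tau = m/gamma this converges in law to the overdamped step and
    its long-time diffusivity equals D_free exactly for any dt.
    """
    gamma = drag_coefficient(p, f)
    m = p.m_p
    sigma_f = brownian_force_scale(p, f, dt)
    c = 1.0 / (1.0 + gamma * dt / m)
    v_new = c * (velocities + sigma_f * dt / m * rng.standard_normal(positions.shape))
    return positions + v_new * dt, v_new


def _reflect_cylinder(
    prev_xy: np.ndarray,
    prop_xy: np.ndarray,
    r_acc: float,
    vel_xy: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Specular reflection of lateral segments off the circle rho = r_acc.

    Repeatedly intersects the residual segment with the wall and mirrors it
    about the local tangent until the endpoint is interior.  ``vel_xy``, if
    given, receives the same sequence of mirror operations.
    """
    cur = prev_xy.copy()
    tgt = prop_xy.copy()
    vel = None if vel_xy is None else vel_xy.copy()
    r2 = r_acc * r_acc
    for _ in range(_MAX_BOUNCES):
        out = np.einsum("ij,ij->i", tgt, tgt) > r2
        if not out.any():
            return tgt, vel
        p = cur[out]
        q = tgt[out]
        d = q - p
        aa = np.einsum("ij,ij->i", d, d)
        bb = 2.0 * np.einsum("ij,ij->i", p, d)
        cc = np.einsum("ij,ij->i", p, p) - r2
        # particles marginally outside from float round-off: project back
        disc = np.maximum(bb * bb - 4.0 * aa * cc, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (-bb + np.sqrt(disc)) / (2.0 * aa)
        s = np.clip(np.nan_to_num(s, nan=0.0), 0.0, 1.0)
        hit = p + s[:, None] * d
        # outward unit normal at the hit point
        norm = np.linalg.norm(hit, axis=1, keepdims=True)
        norm[norm == 0.0] = r_acc
        n_hat = hit / norm
        rem = q - hit
        rem -= 2.0 * np.einsum("ij,ij->i", rem, n_hat)[:, None] * n_hat
        cur[out] = hit
        tgt[out] = hit + rem
        if vel is not None:
            v = vel[out]
            v -= 2.0 * np.einsum("ij,ij->i", v, n_hat)[:, None] * n_hat
            vel[out] = v
    raise RuntimeError(
        f"cylindrical reflection did not converge within {_MAX_BOUNCES} bounces "
        f"(max |rho|/r_acc = {float(np.sqrt(np.einsum('ij,ij->i', tgt, tgt).max())) / r_acc:.3f})"
    )


def apply_boundaries(
    prev: np.ndarray,
    prop: np.ndarray,
    r_acc: float,
    length: float,
    absorbing_plane: Optional[float] = None,
    vel: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Apply capillary boundaries to proposed moves.

    Absorption is decided first, on the straight ``prev -> prop`` segment:
    any particle whose proposed axial coordinate reaches the absorbing plane
    is removed (axial motion is monotone along the segment, so crossing is
    equivalent to the endpoint test).  Survivors are then reflected
    specularly at the top plane z = 0 and the cylindrical wall rho = r_acc.

    Returns ``(new_positions, absorbed_mask, new_velocities)``; rows of
    ``new_positions`` where ``absorbed_mask`` is True are undefined.
    """
    if absorbing_plane is None:
        absorbing_plane = length
    prop = prop.copy()
    absorbed = prop[:, 2] >= absorbing_plane
    alive = ~absorbed
    z = prop[alive, 2]
    neg = z < 0
    z[neg] = -z[neg]
    if np.any(z >= absorbing_plane):
        raise RuntimeError("step spans the whole capillary; decrease dt")
    prop[alive, 2] = z
    vel_alive = None
    if vel is not None:
        vel_alive = vel[alive].copy()
        vel_alive[neg, 2] *= -1.0
    new_xy, new_vxy = _reflect_cylinder(
        prev[alive, :2],
        prop[alive, :2],
        r_acc,
        None if vel_alive is None else vel_alive[:, :2],
    )
    prop[alive, :2] = new_xy
    if vel is not None:
        vel = vel.copy()
        assert vel_alive is not None
        if new_vxy is not None:
            vel_alive[:, :2] = new_vxy
        vel[alive] = vel_alive
    return prop, absorbed, vel


def _initial_positions(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_particles
    r_acc = cfg.accessible_radius
    rho = r_acc * np.sqrt(rng.random(n))
    theta = 2.0 * math.pi * rng.random(n)
    pos = np.empty((n, 3))
    pos[:, 0] = rho * np.cos(theta)
    pos[:, 1] = rho * np.sin(theta)
    pos[:, 2] = cfg.release_offset
    return pos


def _run_reference(
    cfg: SimulationConfig, dt: float, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised numpy driver built from the public step/boundary ops."""
    D = cfg.diffusivity
    r_acc = cfg.accessible_radius if cfg.lateral_wall else math.inf
    plane = cfg.absorbing_plane
    pos = _initial_positions(cfg, rng)
    vel = np.zeros_like(pos) if cfg.scheme == "langevin" else None
    ids = np.arange(cfg.n_particles)
    t_abs = np.full(cfg.n_particles, np.inf)
    for step in range(n_steps):
        if ids.size == 0:
            break
        if cfg.scheme == "overdamped":
            prop = step_overdamped(pos, D, dt, rng)
        else:
            prop, vel = step_langevin(pos, vel, cfg.particle, cfg.fluid, dt, rng)
        new_pos, absorbed, vel = apply_boundaries(
            pos, prop, r_acc, cfg.capillary.length, plane, vel
        )
        if absorbed.any():
            t_abs[ids[absorbed]] = (step + 1) * dt
            keep = ~absorbed
            new_pos = new_pos[keep]
            ids = ids[keep]
            if vel is not None:
                vel = vel[keep]
        pos = new_pos
    return t_abs


def _run_compiled(
    cfg: SimulationConfig, dt: float, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """Numba per-particle driver (overdamped only); same law as reference."""
    from ._kernels import overdamped_passage_kernel

    pos = _initial_positions(cfg, rng)
    sigma = math.sqrt(2.0 * cfg.diffusivity * dt)
    r_acc2 = cfg.accessible_radius**2 if cfg.lateral_wall else math.inf
    steps = overdamped_passage_kernel(
        np.ascontiguousarray(pos[:, 0]),
        np.ascontiguousarray(pos[:, 1]),
        np.ascontiguousarray(pos[:, 2]),
        sigma,
        n_steps,
        r_acc2,
        cfg.absorbing_plane,
        cfg.seed % 2**32,
    )
    return np.where(steps >= 0, steps * dt, np.inf)


def run_simulation(cfg: SimulationConfig) -> PassageCurve:
    """Run one passage-curve simulation.

    Releases ``n_particles`` at depth ``release_offset`` with centres
    uniform over the accessible disk, advances them by the configured scheme
    with boundary handling each step, and records each particle's first
    crossing of the absorbing plane.  Stops early when all particles are
    absorbed.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.resolved_dt()
    D = cfg.diffusivity
    n_steps = int(math.ceil(cfg.t_end / dt))
    if cfg.engine == "compiled" and cfg.scheme == "overdamped":
        t_abs = _run_compiled(cfg, dt, n_steps, rng)
    else:
        t_abs = _run_reference(cfg, dt, n_steps, rng)

    if cfg.record_times is not None:
        times = np.asarray(cfg.record_times, dtype=float)
    else:
        times = np.unique(np.append(np.geomspace(dt, cfg.t_end, 200), cfg.t_end))
    sorted_abs = np.sort(t_abs[np.isfinite(t_abs)])
    n_passed = np.searchsorted(sorted_abs, times, side="right").astype(float)
    fraction = n_passed / cfg.n_particles
    meta = {
        "seed": cfg.seed,
        "scheme": cfg.scheme,
        "engine": cfg.engine,
        "dt_s": dt,
        "t_end": cfg.t_end,
        "n_steps": n_steps,
        "d_p_m": cfg.particle.d_p,
        "rho_p_kg_m3": cfg.particle.rho_p,
        "eta_Pa_s": cfg.fluid.eta,
        "T_K": cfg.fluid.T,
        "r_h_m": cfg.capillary.r_h,
        "capillary_length_m": cfg.capillary.length,
        "release_offset_m": cfg.release_offset,
        "point_particle": cfg.point_particle,
        "surface_contact": cfg.surface_contact,
        "diffusivity_m2_s": D,
    }
    t_out = np.where(np.isfinite(t_abs), t_abs, np.nan)
    return PassageCurve(
        times=times,
        n_passed=n_passed,
        fraction=fraction,
        n_p0=cfg.n_particles,
        meta=meta,
        first_passage_times=t_out,
    )


def first_passage_fraction(
    D: float, length: float, x0: float, t: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Exact passage fraction for 1-D diffusion, reflecting at 0, absorbing at L.

    The survival probability for a particle started at ``x0`` (measured from
    the reflecting end) is the eigenfunction series

        S(t) = sum_k [4(-1)^k / ((2k+1) pi)] cos((2k+1) pi x0 / (2L))
               exp(-D (2k+1)^2 pi^2 t / (4 L^2))

    truncated when the next term's envelope drops below 1e-12.  For short
    times (D*t/L^2 < 0.05) where the series converges slowly, the
    method-of-images form

        F(t) = erfc((L - x0)/(2 sqrt(D t))) + erfc((L + x0)/(2 sqrt(D t)))

    (direct path plus the single reflection off the top) is used instead;
    the first neglected image contributes less than 1e-20 at the crossover.
    Returns F(t) = 1 - S(t).
    """
    if not (D > 0 and length > 0 and 0 <= x0 < length):
        raise ValueError("require D > 0, length > 0, 0 <= x0 < length")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    out = np.zeros_like(t_arr)
    pos = t_arr > 0
    tau = D * t_arr[pos] / length**2
    short = tau < 0.05
    res = np.empty_like(tau)
    if short.any():
        ts = t_arr[pos][short]
        root = 2.0 * np.sqrt(D * ts)
        res[short] = erfc((length - x0) / root) + erfc((length + x0) / root)
    if (~short).any():
        tl = t_arr[pos][~short]
        s = np.zeros_like(tl)
        k = 0
        rate0 = math.pi**2 * D / (4.0 * length**2)
        while True:
            m = 2 * k + 1
            coeff = 4.0 * (-1.0) ** k / (m * math.pi)
            term = coeff * math.cos(m * math.pi * x0 / (2.0 * length)) * np.exp(
                -(m**2) * rate0 * tl
            )
            s += term
            # envelope of the *next* term at the smallest time in the block
            k += 1
            m_next = 2 * k + 1
            if 4.0 / (m_next * math.pi) * math.exp(-(m_next**2) * rate0 * tl.min()) < 1e-12:
                break
        res[~short] = 1.0 - s
    out[pos] = np.clip(res, 0.0, 1.0)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out[0])
    return out


def mean_first_passage_time(D: float, length: float, x0: float) -> float:
    """Closed-form mean first-passage time (L^2 - x0^2) / (2 D), s."""
    if not (D > 0 and length > 0 and 0 <= x0 < length):
        raise ValueError("require D > 0, length > 0, 0 <= x0 < length")
    return (length**2 - x0**2) / (2.0 * D)
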