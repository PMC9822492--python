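"""Brownian passage simulation against its closed-form first-passage law."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from dermadiff import (
    Fluid,
    ParticleSpec,
    SimulationConfig,
    apply_boundaries,
    auto_timestep,
    first_passage_fraction,
    free_diffusion_coefficient,
    mean_first_passage_time,
    momentum_relaxation_time,
    run_simulation,
    step_langevin,
    step_overdamped,
)


def curve_tolerance(f_exact: np.ndarray, n: int) -> np.ndarray:
    """3 binomial standard errors plus the 1/n discreteness allowance."""
    return 3.0 * np.sqrt(f_exact * (1.0 - f_exact) / n) + 1.0 / n


@pytest.fixture(scope="module")
def fast_config(short_capillary, water_like):
    """1 nm particle in the short capillary: passage in ~1 ms of model time."""
    return SimulationConfig(
        capillary=short_capillary,
        particle=ParticleSpec(d_p=1e-9, rho_p=2200.0),
        fluid=water_like,
        n_particles=400,
        t_end=8e-3,
        seed=11,
    )


class TestAutoTimestep:
    def test_rms_step_rule(self, ref_capillary):
        # d_p = 15 nm, eta = 50 mPa s: accessible radius 5 nm caps the RMS
        # step at 1 nm, so dt solves sqrt(2*D*dt) = 1e-9
        cfg = SimulationConfig(
            capillary=ref_capillary,
            particle=ParticleSpec(15e-9, 2200.0),
            fluid=Fluid(eta=0.05),
        )
        dt = auto_timestep(cfg)
        assert math.sqrt(2.0 * cfg.diffusivity * dt) == pytest.approx(1e-9, rel=1e-12)

    def test_monotone_in_viscosity(self, ref_capillary):
        def dt_at(eta):
            cfg = SimulationConfig(
                capillary=ref_capillary,
                particle=ParticleSpec(5e-9, 2200.0),
                fluid=Fluid(eta=eta),
            )
            return auto_timestep(cfg)

        assert dt_at(0.05) > dt_at(0.02) > dt_at(0.01)

    def test_always_beyond_momentum_relaxation(self, ref_capillary):
        for d_p in (1e-9, 5e-9, 10e-9, 15e-9):
            for eta in (0.01, 0.02, 0.05):
                cfg = SimulationConfig(
                    capillary=ref_capillary,
                    particle=ParticleSpec(d_p, 2200.0),
                    fluid=Fluid(eta=eta),
                )
                assert auto_timestep(cfg) >= 100.0 * momentum_relaxation_time(
                    cfg.particle, cfg.fluid
                )

    def test_infeasible_constraints_raise(self, ref_capillary):
        # a release sliver of 3e-13 m forces an RMS step of 1e-13 m and a dt
        # below 100*tau
        cfg = SimulationConfig(
            capillary=ref_capillary,
            particle=ParticleSpec(15e-9, 2200.0),
            fluid=Fluid(eta=0.001),
            release_offset=3e-13,
        )
        with pytest.raises(ValueError):
            auto_timestep(cfg)


class TestSteps:
    def test_overdamped_moments(self):
        rng = np.random.default_rng(5)
        D, dt = 8.7e-12, 1e-7
        pos = np.zeros((100_000, 3))
        new = step_overdamped(pos, D, dt, rng)
        disp = new - pos
        var = disp.var(axis=0)
        se_var = 2.0 * D * dt * math.sqrt(2.0 / 100_000)
        assert np.all(np.abs(var - 2.0 * D * dt) < 3.0 * se_var)
        se_mean = math.sqrt(2.0 * D * dt / 100_000)
        assert np.all(np.abs(disp.mean(axis=0)) < 3.0 * se_mean)

    def test_overdamped_zero_diffusivity_is_frozen(self):
        rng = np.random.default_rng(5)
        pos = np.ones((10, 3))
        assert np.array_equal(step_overdamped(pos, 0.0, 1e-7, rng), pos)

    def test_langevin_long_time_diffusivity(self, particle_5nm, water_like):
        # dt = 100*tau, 1e4 steps: displacement variance over the run gives
        # back the free diffusivity
        tau = momentum_relaxation_time(particle_5nm, water_like)
        dt = 100.0 * tau
        rng = np.random.default_rng(12)
        n, n_steps = 3000, 10_000
        pos = np.zeros((n, 3))
        vel = np.zeros((n, 3))
        for _ in range(n_steps):
            pos, vel = step_langevin(pos, vel, particle_5nm, water_like, dt, rng)
        d_hat = pos.var(axis=0).mean() / (2.0 * n_steps * dt)
        assert d_hat == pytest.approx(
            free_diffusion_coefficient(particle_5nm, water_like), rel=0.05
        )

    def test_langevin_pure_drag_decay(self, particle_5nm):
        # with the thermal force switched off an initial velocity decays by
        # 1/e every tau
        cold = Fluid(eta=0.01, T=1e-300)
        tau = momentum_relaxation_time(particle_5nm, cold)
        dt = tau / 100.0
        rng = np.random.default_rng(0)
        pos = np.zeros((1, 3))
        vel = np.full((1, 3), 1.0)
        for _ in range(100):
            pos, vel = step_langevin(pos, vel, particle_5nm, cold, dt, rng)
        assert vel[0, 0] == pytest.approx(math.exp(-1.0), rel=1e-2)


class TestBoundaries:
    R = 12.5e-9
    L = 1e-6

    def test_bottom_crossing_absorbs(self):
        prev = np.array([[0.0, 0.0, 0.9e-6]])
        prop = np.array([[0.0, 0.0, 1.1e-6]])
        _, absorbed, _ = apply_boundaries(prev, prop, self.R, self.L)
        assert absorbed[0]

    def test_top_plane_mirrors(self):
        prev = np.array([[0.0, 0.0, 2e-9]])
        prop = np.array([[0.0, 0.0, -3e-9]])
        new, absorbed, _ = apply_boundaries(prev, prop, self.R, self.L)
        assert not absorbed[0]
        assert new[0, 2] == pytest.approx(3e-9)

    def test_wall_reflection_is_specular(self):
        # head-on radial overshoot by 0.5 R comes back to 0.5 R
        prev = np.array([[0.0, 0.0, 5e-7]])
        prop = np.array([[1.5 * self.R, 0.0, 5e-7]])
        new, absorbed, _ = apply_boundaries(prev, prop, self.R, self.L)
        assert not absorbed[0]
        assert new[0, 0] == pytest.approx(0.5 * self.R, rel=1e-12)
        assert new[0, 1] == 0.0

    def test_reflecting_cylinder_preserves_uniform_density(self):
        # start everything on the axis, mix, and test rho^2 ~ U(0, R^2)
        rng = np.random.default_rng(3)
        n = 2000
        pos = np.zeros((n, 3))
        pos[:, 2] = 5e-7
        sigma = self.R / 5.0
        for _ in range(3000):
            prop = pos + sigma * rng.standard_normal((n, 3))
            pos, _, _ = apply_boundaries(pos, prop, self.R, self.L, absorbing_plane=math.inf)
        u = (pos[:, 0] ** 2 + pos[:, 1] ** 2) / self.R**2
        assert kstest(u, "uniform").pvalue > 0.01


class TestFirstPassageOracle:
    D, L, X0 = 8.73e-12, 1e-6, 3e-8

    def test_limits(self):
        assert first_passage_fraction(self.D, self.L, self.X0, 0.0) == 0.0
        assert first_passage_fraction(self.D, self.L, self.X0, 1e4) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_time_and_diffusivity(self):
        t = np.geomspace(1e-4, 10.0, 300)
        f = first_passage_fraction(self.D, self.L, self.X0, t)
        assert np.all(np.diff(f) >= 0)
        f_fast = first_passage_fraction(2.0 * self.D, self.L, self.X0, t)
        assert np.all(f_fast >= f)

    def test_mean_first_passage_time_by_quadrature(self):
        # integral of the survival from 0 to inf equals (L^2 - x0^2)/(2D)
        surv = lambda t: 1.0 - first_passage_fraction(self.D, self.L, self.X0, t)
        integral, _ = quad(surv, 0.0, math.inf, limit=400)
        assert integral == pytest.approx(
            mean_first_passage_time(self.D, self.L, self.X0), rel=1e-6
        )

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            first_passage_fraction(-1.0, self.L, self.X0, 1.0)
        with pytest.raises(ValueError):
            first_passage_fraction(self.D, self.L, 2e-6, 1.0)


class TestRunSimulation:
    def test_nothing_passes_immediately(self, fast_config):
        cfg = replace(fast_config, n_particles=50, t_end=5e-7)
        curve = run_simulation(cfg)
        assert np.all(curve.fraction == 0.0)

    def test_counts_conserved_and_monotone(self, fast_config):
        curve = run_simulation(replace(fast_config, n_particles=200))
        assert np.all(np.diff(curve.n_passed) >= 0)
        assert curve.n_passed[-1] <= curve.n_p0
        n_absorbed = np.isfinite(curve.first_passage_times).sum()
        assert n_absorbed == curve.n_passed[-1]

    def test_point_particle_matches_analytic_law(self, fast_config):
        cfg = replace(fast_config, n_particles=500, point_particle=True, seed=21)
        curve = run_simulation(cfg)
        f_exact = first_passage_fraction(
            cfg.diffusivity, cfg.capillary.length, cfg.release_offset, curve.times
        )
        assert np.all(np.abs(curve.fraction - f_exact) <= curve_tolerance(f_exact, 500))

    def test_finite_size_does_not_change_passage_law(self, fast_config):
        # axial motion is independent of lateral reflections, so a 10 nm
        # sphere follows the same passage law as a point (centre plane)
        cfg = replace(
            fast_config, n_particles=500, particle=ParticleSpec(10e-9, 2200.0), seed=22
        )
        curve = run_simulation(cfg)
        f_exact = first_passage_fraction(
            cfg.diffusivity, cfg.capillary.length, cfg.release_offset, curve.times
        )
        assert np.all(np.abs(curve.fraction - f_exact) <= curve_tolerance(f_exact, 500))

    def test_disabling_lateral_wall_preserves_law(self, fast_config):
        grid = np.geomspace(1e-5, 8e-3, 60)
        base = replace(fast_config, particle=ParticleSpec(10e-9, 2200.0),
                       record_times=grid, seed=31)
        walled = run_simulation(base)
        free = run_simulation(replace(base, lateral_wall=False, seed=32))
        f_exact = first_passage_fraction(
            base.diffusivity, base.capillary.length, base.release_offset, grid
        )
        tol = np.sqrt(2.0) * curve_tolerance(f_exact, base.n_particles)
        assert np.all(np.abs(walled.fraction - free.fraction) <= tol)

    def test_engines_agree_in_law(self, fast_config):
        grid = np.geomspace(1e-5, 8e-3, 60)
        cfg = replace(fast_config, record_times=grid, seed=41)
        compiled = run_simulation(cfg)
        reference = run_simulation(replace(cfg, engine="reference", seed=42))
        f_exact = first_passage_fraction(
            cfg.diffusivity, cfg.capillary.length, cfg.release_offset, grid
        )
        tol = np.sqrt(2.0) * curve_tolerance(f_exact, cfg.n_particles)
        assert np.all(np.abs(compiled.fraction - reference.fraction) <= tol)

    def test_langevin_agrees_with_overdamped(self, fast_config):
        grid = np.geomspace(1e-5, 8e-3, 60)
        cfg = replace(fast_config, record_times=grid, seed=51)
        over = run_simulation(cfg)
        lang = run_simulation(replace(cfg, scheme="langevin", seed=52))
        f_exact = first_passage_fraction(
            cfg.diffusivity, cfg.capillary.length, cfg.release_offset, grid
        )
        tol = np.sqrt(2.0) * curve_tolerance(f_exact, cfg.n_particles)
        assert np.all(np.abs(over.fraction - lang.fraction) <= tol)

    def test_passage_ordered_by_viscosity(self, short_capillary):
        grid = np.geomspace(1e-5, 0.04, 50)
        def run(eta, seed):
            cfg = SimulationConfig(
                capillary=short_capillary,
                particle=ParticleSpec(1e-9, 2200.0),
                fluid=Fluid(eta=eta),
                n_particles=400,
                t_end=0.04,
                record_times=grid,
                seed=seed,
            )
            return run_simulation(cfg)

        thin = run(0.01, 61)
        thick = run(0.05, 62)
        se = 3.0 * math.sqrt(0.25 / 400) + 1.0 / 400
        assert np.all(thin.fraction >= thick.fraction - 2.0 * se)
        assert thin.fraction.sum() > thick.fraction.sum()

    def test_bit_reproducible_and_seed_sensitive(self, fast_config):
        cfg = replace(fast_config, n_particles=100)
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert np.array_equal(a.n_passed, b.n_passed)
        c = run_simulation(replace(cfg, seed=99))
        assert not np.array_equal(a.n_passed, c.n_passed)

    def test_oversized_particle_rejected(self, short_capillary, water_like):
        with pytest.raises(ValueError, match="larger than capillary"):
            SimulationConfig(
                capillary=short_capillary,
                particle=ParticleSpec(30e-9, 2200.0),
                fluid=water_like,
            )

    def test_curve_round_trips_through_csv(self, fast_config, tmp_path):
        curve = run_simulation(replace(fast_config, n_particles=100))
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = type(curve).from_csv(path)
        assert back.n_p0 == curve.n_p0
        np.testing.assert_allclose(back.fraction, curve.fraction)
        assert back.meta["seed"] == curve.meta["seed"]
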