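"""Particle engine: initialisation, stepping, conservation, determinism,
free-diffusion calibration and the continuum cross-check."""

import dataclasses

import numpy as np
import pytest

import mexdiff as m
from mexdiff.exceptions import ConfigError
from mexdiff.simulator import _random_unit_vectors, sample_uniform_in_ellipsoid

import pde_oracle


def small_config(**kw):
    species, rates, fractions, cfg = m.default_mex6_params()
    defaults = dict(n_particles=2000, duration=30.0, rng_seed=7)
    defaults.update(kw)
    return species, rates, dataclasses.replace(cfg, **defaults)


class TestInitEnsemble:
    def test_uniform_half_states_and_containment(self, geometry):
        _, rates, cfg = small_config(n_particles=20_000)
        ens = m.init_ensemble(cfg, geometry, rates)
        assert geometry.contains(ens.positions).all()
        # binomial(n, 1/2): 4 sigma band
        n_slow = int(np.sum(ens.states == m.SLOW))
        assert abs(n_slow - 10_000) < 4 * np.sqrt(20_000 * 0.25)
        # no built-in gradient
        g = m.gradient_from_profile(m.concentration_profile(ens, geometry))
        assert abs(g.value) < 0.2

    def test_single_particle(self, geometry):
        _, rates, cfg = small_config(n_particles=1)
        ens = m.init_ensemble(cfg, geometry, rates)
        assert ens.n_particles == 1 and geometry.contains(ens.positions).all()

    def test_local_equilibrium_states_follow_rate_ratio(self, geometry):
        _, rates, cfg = small_config(
            n_particles=100_000, initial_state_rule="local_equilibrium"
        )
        ens = m.init_ensemble(cfg, geometry, rates)
        x_hat = geometry.normalized_ap(ens.positions[:, 0])
        for sel, lo, hi in [
            (x_hat <= 0.1, 0.79, 0.87),   # stationary occupancy ~0.83 anterior
            (x_hat >= 0.9, 0.47, 0.55),   # ~0.51 posterior
        ]:
            frac = float(np.mean(ens.states[sel] == m.SLOW))
            assert lo < frac < hi


class TestStep:
    def test_zero_rates_leave_states_untouched(self, geometry):
        species, _, cfg = small_config()
        rates = m.RateField(0.0, 0.0, 0.0)
        rng = np.random.default_rng(0)
        ens = m.init_ensemble(cfg, geometry, rates, rng=rng)
        out = m.step(ens, species.with_timestep(0.75), rates, geometry, 0.75, rng)
        assert np.array_equal(out.states, ens.states)
        assert out.time == pytest.approx(0.75)

    def test_step_length_is_fixed_per_state(self, geometry):
        """Interior particles move exactly v_state * dt per step."""
        species, rates, cfg = small_config(n_particles=5000)
        rng = np.random.default_rng(1)
        sp = species.with_timestep(0.75)
        ens = m.init_ensemble(cfg, geometry, rates, rng=rng)
        out = m.step(ens, sp, rates, geometry, 0.75, rng)
        disp = np.linalg.norm(out.positions - ens.positions, axis=1)
        expect = np.where(ens.states == m.FAST, sp.v_fast, sp.v_slow) * 0.75
        # reflected particles travel the same path length but a shorter
        # chord; everyone else moves exactly the step length
        moved_straight = np.isclose(disp, expect, rtol=1e-9)
        assert moved_straight.mean() > 0.8
        assert np.all(disp <= expect + 1e-9)

    def test_detailed_balance_with_uniform_rates(self, geometry):
        """Uniform kinase = phosphatase drives the slow fraction to 1/2."""
        species, _, cfg = small_config(n_particles=20_000, duration=1200.0)
        rates = m.RateField(0.01, 0.01, 0.01)
        rng = np.random.default_rng(3)
        ens = m.init_ensemble(dataclasses.replace(cfg, initial_state_rule="uniform_half"),
                              geometry, rates, rng=rng)
        # bias the initial states hard, then relax
        states = np.zeros(ens.n_particles, dtype=np.uint8)
        ens = m.Ensemble(ens.positions, states, 0.0, "test")
        sp = species.with_timestep(0.75)
        for _ in range(800):  # 600 s >> 1/(k+k) = 50 s
            ens = m.step(ens, sp, rates, geometry, 0.75, rng)
        frac = ens.slow_fraction
        assert abs(frac - 0.5) < 4 / np.sqrt(20_000)

    def test_containment_and_conservation_along_run(self, geometry):
        species, rates, cfg = small_config(n_particles=3000, duration=60.0)
        traj = m.run_simulation(cfg, geometry, species, rates,
                                output_times=[15.0, 30.0, 60.0])
        assert len(traj.snapshots) == 4
        for snap in traj.snapshots:
            assert snap.n_particles == 3000
            assert geometry.contains(snap.positions).all()
            n_slow = np.sum(snap.states == m.SLOW)
            n_fast = np.sum(snap.states == m.FAST)
            assert n_slow + n_fast == 3000


class TestDeterminism:
    def test_same_seed_identical_trajectories(self, geometry):
        species, rates, cfg = small_config()
        t1 = m.run_simulation(cfg, geometry, species, rates, output_times=[30.0])
        t2 = m.run_simulation(cfg, geometry, species, rates, output_times=[30.0])
        assert np.array_equal(t1.final.positions, t2.final.positions)
        assert np.array_equal(t1.final.states, t2.final.states)

    def test_replicates_use_distinct_seeds(self, geometry):
        species, rates, cfg = small_config()
        runs = m.run_replicates(cfg, geometry, species, rates,
                                output_times=[30.0], n_replicates=2)
        assert runs[0].seed != runs[1].seed
        assert not np.array_equal(runs[0].final.positions, runs[1].final.positions)

    def test_output_time_beyond_duration_rejected(self, geometry):
        species, rates, cfg = small_config(duration=30.0)
        with pytest.raises(ConfigError):
            m.run_simulation(cfg, geometry, species, rates, output_times=[60.0])


class TestFreeDiffusion:
    def test_msd_recovers_diffusivity(self):
        """Free fixed-speed walkers: MSD(t) / (6 t) = D within 5%.

        Uses a huge ellipsoid so no walker reaches the boundary within
        the observation window.
        """
        D, dt = 1.81, 0.75
        big = m.EmbryoGeometry(semi_axis_ap=5000, semi_axis_dv=5000,
                               semi_axis_lr=5000, slice_thickness=10.0)
        rng = np.random.default_rng(11)
        n = 20_000
        v = m.velocity_from_diffusivity(D, dt)
        pos = np.zeros((n, 3))
        for step_i in range(1, 101):
            pos = pos + _random_unit_vectors(rng, n) * v * dt
            t = step_i * dt
            if step_i in (20, 60, 100):
                msd = float(np.mean(np.sum(pos**2, axis=1)))
                assert msd / (6 * t) == pytest.approx(D, rel=0.05)


class TestBoundaryRule:
    def test_reflection_preserves_uniform_density(self, geometry):
        """A uniform free ensemble stays uniform under reflection.

        The outer 10%-shell occupancy (in scaled radius) must stay at its
        uniform value 1 - 0.9^3; biased wall handling depletes it.
        """
        rng = np.random.default_rng(5)
        n = 30_000
        pos = sample_uniform_in_ellipsoid(rng, n, geometry)
        species = m.SpeciesParams.from_diffusivities("free", 0.0, 1.81, 0.75)
        rates = m.RateField(0.0, 0.0, 0.0)
        ens = m.Ensemble(pos, np.ones(n, dtype=np.uint8), 0.0, "free")
        for _ in range(400):
            ens = m.step(ens, species, rates, geometry, 0.75, rng)
        semi = np.array([25.0, 15.0, 15.0])
        r = np.linalg.norm(ens.positions / semi, axis=1)
        shell = float(np.mean(r > 0.9))
        expected = 1 - 0.9**3
        assert shell == pytest.approx(expected, abs=4 * np.sqrt(expected / n) + 0.005)


class TestContinuumCrossCheck:
    def test_steady_gradient_matches_pde(self, geometry):
        """Monte Carlo steady gradient agrees with the independent
        finite-volume solution of the same two-state model."""
        species, rates, cfg = small_config(n_particles=10_000, duration=3600.0)
        traj = m.run_simulation(cfg, geometry, species, rates,
                                output_times=[3600.0])
        g_mc = m.gradient_from_profile(
            m.concentration_profile(traj.final, geometry)
        ).value
        ref = pde_oracle.solve_gradient(
            species.D_slow, species.D_fast,
            rates.k_kinase_low, rates.k_kinase_upp, rates.k_phosp,
            times=[3600.0],
        )
        assert g_mc == pytest.approx(ref["total"][-1], abs=0.15)
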