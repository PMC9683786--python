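import math

import numpy as np
import pytest

from swimtrap import (SimRun, SwimmerConfig, mean_tangential_flux,
                      occupancy_flux, simulate, simulate_raw, step, sweep)
from swimtrap.dumbbell import wall_overlap
from swimtrap.errors import ConfigError, NumericalError


class TestStep:
    def test_force_free_bulk_motion(self):
        """Without wall contact and noise the swimmer translates exactly
        dt*v0 along its heading, even with a nonzero offset angle."""
        cfg = SwimmerConfig(theta=1.5, v0=80.0, D_r=0.0, D_t=0.0)
        phi = 0.7
        dt = 1e-4
        x, y, p = step((0.0, 0.0, phi), cfg, trap_radius=200.0, dt=dt)
        assert x == pytest.approx(dt * 80.0 * math.cos(phi), abs=1e-15)
        assert y == pytest.approx(dt * 80.0 * math.sin(phi), abs=1e-15)
        assert p == phi

    def test_single_step_wall_toy_numbers(self):
        """Body sphere overlapping by 0.5 um with k_wall*mu_t = 10/s gives an
        inward displacement contribution of 0.5*10*dt."""
        cfg = SwimmerConfig(a1=7.0, a2=5.0, ell=7.5, theta=0.0, v0=0.0,
                            D_r=0.0, D_t=0.0, k_wall=10.0, mu_t=1.0)
        R = 60.0
        x0 = R - cfg.a2 + 0.5          # overlap exactly 0.5 um
        dt = 1e-3
        # heading points inward so the front sphere is clear of the wall
        x, y, phi = step((x0, 0.0, math.pi), cfg, R, dt)
        assert x0 - x == pytest.approx(0.5 * 10.0 * dt, rel=1e-12)
        assert y == pytest.approx(0.0, abs=1e-15)
        assert phi == pytest.approx(math.pi)  # radial force, no torque

    def test_nan_detected_with_step_index(self):
        cfg = SwimmerConfig()
        with pytest.raises(NumericalError) as err:
            step((0.0, 0.0, 0.0), cfg, 60.0, 1e-4,
                 noise=(float("nan"), 0.0, 0.0))
        assert err.value.step == 0


class TestMirrorSymmetry:
    def test_theta_zero_deterministic_mirror(self):
        """theta = 0 approach at normal incidence: the mirrored initial
        condition yields the mirrored trajectory (no chirality)."""
        cfg = SwimmerConfig(theta=0.0, D_r=0.0, D_t=0.0)
        run_a = SimRun(dt=1e-4, duration=5.0, seed=0, trap_radius=30.0,
                       initial=(0.0, 5.0, 0.3))
        run_b = SimRun(dt=1e-4, duration=5.0, seed=0, trap_radius=30.0,
                       initial=(0.0, -5.0, -0.3))
        _, xa, ya, pa = simulate_raw(cfg, run_a, output_dt=0.002)
        _, xb, yb, pb = simulate_raw(cfg, run_b, output_dt=0.002)
        np.testing.assert_allclose(xb, xa, atol=1e-9)
        np.testing.assert_allclose(yb, -ya, atol=1e-9)
        np.testing.assert_allclose(pb, -pa, atol=1e-9)

    def test_mirror_equivalence_with_noise_exact(self):
        """theta -> -theta with reflected pose and negated y/phi noise gives
        the exact mirror image at every step."""
        nsteps = 20_000
        rng = np.random.default_rng(5)
        noise = rng.standard_normal((nsteps, 3))
        mirrored = noise.copy()
        mirrored[:, 1] *= -1.0
        mirrored[:, 2] *= -1.0
        cfg_p = SwimmerConfig(theta=1.5, D_r=0.4, D_t=0.5)
        cfg_m = SwimmerConfig(theta=-1.5, D_r=0.4, D_t=0.5)
        run_p = SimRun(dt=1e-4, duration=2.0, seed=0, trap_radius=20.0,
                       initial=(3.0, 4.0, 1.0))
        run_m = SimRun(dt=1e-4, duration=2.0, seed=0, trap_radius=20.0,
                       initial=(3.0, -4.0, -1.0))
        _, xp, yp, pp = simulate_raw(cfg_p, run_p, output_dt=1e-4,
                                     noise=noise)
        _, xm, ym, pm = simulate_raw(cfg_m, run_m, output_dt=1e-4,
                                     noise=mirrored)
        np.testing.assert_allclose(xm, xp, rtol=0, atol=1e-12)
        np.testing.assert_allclose(ym, -yp, rtol=0, atol=1e-12)
        np.testing.assert_allclose(pm, -pp, rtol=0, atol=1e-12)


class TestSimulate:
    def test_identical_seeds_bit_identical(self):
        cfg = SwimmerConfig()
        a = simulate(cfg, SimRun(duration=2.0, seed=9, trap_radius=30.0))
        b = simulate(cfg, SimRun(duration=2.0, seed=9, trap_radius=30.0))
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_bulk_speed_equals_v0(self):
        """With D_t = 0 the instantaneous speed away from the wall is exactly
        v0 at every integration step."""
        cfg = SwimmerConfig(theta=1.5, v0=80.0, D_t=0.0)
        run = SimRun(dt=1e-4, duration=10.0, seed=1, trap_radius=100.0)
        _, x, y, phi = simulate_raw(cfg, run, output_dt=1e-4)
        ov = wall_overlap(cfg, x, y, phi, 100.0)
        bulk = (ov[:-1] <= 0) & (ov[1:] <= 0)
        speeds = np.hypot(np.diff(x), np.diff(y))[bulk] / 1e-4
        assert bulk.sum() > 1000
        np.testing.assert_allclose(speeds, 80.0, rtol=1e-9)

    def test_trap_too_small_rejected(self):
        cfg = SwimmerConfig()
        with pytest.raises(ConfigError):
            simulate(cfg, SimRun(trap_radius=10.0, duration=1.0))

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ConfigError):
            SwimmerConfig(a1=3.0, a2=5.0)

    def test_chirality_sign_small_sample(self):
        """theta > 0 circulates CCW in strong confinement (short check; the
        20-seed suite runs in the acceptance tests)."""
        vals = []
        for seed in range(5):
            traj = simulate(SwimmerConfig(theta=1.5),
                            SimRun(duration=30.0, seed=seed,
                                   trap_radius=20.0))
            vals.append(mean_tangential_flux(occupancy_flux(traj)))
        assert np.mean(vals) > 0

    def test_dt_halving_stability(self):
        """Halving dt changes the 60 s mean tangential flux by < 1 SE."""
        def fluxes(dt):
            out = []
            for seed in range(8):
                traj = simulate(SwimmerConfig(theta=1.5),
                                SimRun(dt=dt, duration=60.0, seed=seed,
                                       trap_radius=20.0))
                out.append(mean_tangential_flux(occupancy_flux(traj)))
            return np.array(out)

        coarse = fluxes(1e-4)
        fine = fluxes(5e-5)
        se = np.sqrt(coarse.var(ddof=1) / 8 + fine.var(ddof=1) / 8)
        assert abs(coarse.mean() - fine.mean()) < se


class TestSweep:
    def test_duplicate_cfgs_identical_summaries(self):
        cfg = SwimmerConfig(theta=1.5)
        df = sweep([cfg, cfg], [20.0], SimRun(duration=10.0), seeds=[1, 2])
        means = df[df.seed == -1]
        assert len(means) == 2
        a, b = means.iloc[0], means.iloc[1]
        assert a.mean_tangential_flux == b.mean_tangential_flux
        assert a.peak_Pr_radius == b.peak_Pr_radius

    def test_rl_vs_wl_opposite_circulation(self):
        """Red-light (theta=+1.5, v0=80) and white-light (theta=-1, v0=100)
        configurations circulate in opposite senses."""
        df = sweep([SwimmerConfig.rl_defaults(), SwimmerConfig.wl_defaults()],
                   [20.0], SimRun(duration=60.0), seeds=list(range(6)))
        means = df[df.seed == -1].set_index("theta_deg")
        assert means.loc[1.5, "mean_tangential_flux"] > 0
        assert means.loc[-1.0, "mean_tangential_flux"] < 0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ConfigError):
            sweep([], [20.0], SimRun(), seeds=[1])
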