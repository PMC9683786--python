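"""Chiral active-dumbbell microswimmer in a circular trap.

The swimmer is two unequal rigid spheres: a body sphere (radius a2) at the
tracked position x and a larger front sphere (radius a1, the envelope of the
ciliary beat) whose centre sits at x + ℓ·ê(φ+θ).  Self-propulsion acts along
the body axis ê(φ) at constant speed v0; the offset angle θ (CCW positive)
misaligns the front sphere from the propulsion direction and is the model's
only source of chirality.  In the bulk the swimmer is force- and torque-free,
so θ manifests exclusively through steric wall contacts: each sphere
overlapping the trap wall feels a radially inward harmonic force
F = k_wall·max(0, |c| + a − R)·(−ĉ), and the resulting torque about the
midpoint of the sphere centres reorients the swimmer.  Overdamped
Euler–Maruyama integration with translational/rotational diffusion closes the
Langevin dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from numba import njit

from .errors import ConfigError, NumericalError
from .trajectory_io import Trajectory, Trap

__all__ = ["SwimmerConfig", "SimRun", "step", "simulate", "simulate_raw",
           "sweep", "wall_overlap"]


@dataclass
class SwimmerConfig:
    """Dumbbell geometry, propulsion, noise and wall-interaction parameters.

    Units: lengths µm, speeds µm/s, D_r rad²/s, D_t µm²/s.  k_wall has units
    of force per µm overlap in the same arbitrary force units as 1/mu_t, so
    k_wall·mu_t (default 100 s⁻¹) is the wall relaxation rate; mu_r converts
    torque to angular velocity (units mu_t/µm²).
    """

    a1: float = 7.0        # front (cilia-envelope) sphere radius
    a2: float = 5.0        # body sphere radius
    ell: float = 7.5       # centre separation
    theta: float = 1.5     # offset angle, degrees; theta > 0 = CCW
    v0: float = 80.0       # self-propulsion speed along ê
    D_r: float = 0.4       # rotational diffusion
    D_t: float = 0.0       # translational diffusion
    k_wall: float = 100.0  # steric stiffness
    mu_t: float = 1.0      # translational mobility
    mu_r: float = 0.05     # rotational mobility

    #: visible cell diameter (µm): the cilia-envelope sphere sets the size of
    #: the tracked blob, so wall-proximity margins are measured against 2·a1
    @property
    def cell_diameter(self) -> float:
        return 2.0 * self.a1

    def __post_init__(self):
        if not (self.a1 > self.a2 > 0):
            raise ConfigError("require a1 > a2 > 0")
        if self.ell <= 0 or self.v0 < 0 or self.D_r < 0 or self.D_t < 0:
            raise ConfigError("require ell > 0, v0 >= 0, D_r, D_t >= 0")
        if self.k_wall <= 0:
            raise ConfigError("require k_wall > 0")

    @property
    def theta_rad(self) -> float:
        return math.radians(self.theta)

    @classmethod
    def rl_defaults(cls) -> "SwimmerConfig":
        """Red-light configuration: v0 = 80 µm/s, θ = +1.5° (CCW bias)."""
        return cls(theta=1.5, v0=80.0)

    @classmethod
    def wl_defaults(cls) -> "SwimmerConfig":
        """White-light configuration: v0 = 100 µm/s, θ = -1° (CW bias)."""
        return cls(theta=-1.0, v0=100.0)


@dataclass
class SimRun:
    """Integration plan: step size, duration, seed, trap and initial pose."""

    dt: float = 1e-4
    duration: float = 60.0
    seed: int = 0
    trap_radius: float = 60.0
    initial: Union[str, tuple] = "random-uniform"   # (x, y, phi) or keyword

    def validate(self, cfg: SwimmerConfig):
        if self.dt <= 0 or self.duration < self.dt:
            raise ConfigError("require dt > 0 and duration >= dt")
        if self.trap_radius <= cfg.a1 + cfg.a2:
            raise ConfigError("trap radius must exceed a1 + a2")


@njit(cache=True)
def _integrate_kernel(x, y, phi, dt, v0, theta, ell, a1, a2, k_wall,
                      mu_t, mu_r, amp_t, amp_r, R, noise, save_every,
                      xs, ys, phis):
    """Euler–Maruyama loop; returns the step index of the first NaN or -1."""
    nsteps = noise.shape[0]
    k = 0
    for n in range(nsteps):
        ex = math.cos(phi)
        ey = math.sin(phi)
        fang = phi + theta
        fcx = x + ell * math.cos(fang)
        fcy = y + ell * math.sin(fang)
        mx = 0.5 * (x + fcx)
        my = 0.5 * (y + fcy)
        Fx = 0.0
        Fy = 0.0
        tau = 0.0
        # body sphere wall contact
        r = math.sqrt(x * x + y * y)
        ov = r + a2 - R
        if ov > 0.0 and r > 0.0:
            f = -k_wall * ov / r
            bx = f * x
            by = f * y
            Fx += bx
            Fy += by
            tau += (x - mx) * by - (y - my) * bx
        # front sphere wall contact
        r = math.sqrt(fcx * fcx + fcy * fcy)
        ov = r + a1 - R
        if ov > 0.0 and r > 0.0:
            f = -k_wall * ov / r
            bx = f * fcx
            by = f * fcy
            Fx += bx
            Fy += by
            tau += (fcx - mx) * by - (fcy - my) * bx
        x = x + dt * (v0 * ex + mu_t * Fx) + amp_t * noise[n, 0]
        y = y + dt * (v0 * ey + mu_t * Fy) + amp_t * noise[n, 1]
        phi = phi + dt * mu_r * tau + amp_r * noise[n, 2]
        if not (x == x and y == y and phi == phi):
            return n
        if (n + 1) % save_every == 0:
            xs[k] = x
            ys[k] = y
            phis[k] = phi
            k += 1
    return -1


def wall_overlap(cfg: SwimmerConfig, x, y, phi, R: float) -> np.ndarray:
    """Largest wall overlap (µm) of either sphere; <= 0 means no contact."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    phi = np.asarray(phi, float)
    fang = phi + cfg.theta_rad
    fx = x + cfg.ell * np.cos(fang)
    fy = y + cfg.ell * np.sin(fang)
    ov_body = np.hypot(x, y) + cfg.a2 - R
    ov_front = np.hypot(fx, fy) + cfg.a1 - R
    return np.maximum(ov_body, ov_front)


def step(pose, cfg: SwimmerConfig, trap_radius: float, dt: float,
         noise=(0.0, 0.0, 0.0)):
    """Advance one Euler–Maruyama step; ``noise`` is 3 standard normals."""
    x, y, phi = pose
    noise_arr = np.asarray(noise, float).reshape(1, 3)
    xs = np.empty(1)
    ys = np.empty(1)
    phis = np.empty(1)
    bad = _integrate_kernel(x, y, phi, dt, cfg.v0, cfg.theta_rad, cfg.ell,
                            cfg.a1, cfg.a2, cfg.k_wall, cfg.mu_t, cfg.mu_r,
                            math.sqrt(2 * cfg.D_t * dt),
                            math.sqrt(2 * cfg.D_r * dt),
                            trap_radius, noise_arr, 1, xs, ys, phis)
    if bad >= 0:
        raise NumericalError("NaN in state", step=int(bad))
    return (float(xs[0]), float(ys[0]), float(phis[0]))


def _initial_pose(cfg: SwimmerConfig, run: SimRun,
                  rng: np.random.Generator) -> tuple:
    if run.initial != "random-uniform":
        return tuple(float(v) for v in run.initial)
    r_max = max(run.trap_radius - cfg.ell - cfg.a1, 0.0)
    u = rng.random()
    r = r_max * math.sqrt(u)
    ang = rng.random() * 2 * math.pi
    phi = rng.random() * 2 * math.pi
    return (r * math.cos(ang), r * math.sin(ang), phi)


def simulate_raw(cfg: SwimmerConfig, run: SimRun, output_dt: float = 0.002,
                 noise: Optional[np.ndarray] = None):
    """Integrate and return (times, x, y, phi) arrays at ``output_dt``
    resolution (pass ``output_dt=run.dt`` for every integration step).

    The initial pose is included as sample 0.  ``noise`` may supply the
    (nsteps, 3) standard-normal increments explicitly (used by symmetry
    tests); otherwise they are drawn from a generator seeded by ``run.seed``.
    """
    run.validate(cfg)
    save_every = max(1, int(round(output_dt / run.dt)))
    nsteps = int(round(run.duration / run.dt))
    nsteps = (nsteps // save_every) * save_every
    rng = np.random.default_rng(run.seed)
    x0, y0, phi0 = _initial_pose(cfg, run, rng)
    if noise is None:
        if cfg.D_t > 0 or cfg.D_r > 0:
            noise = rng.standard_normal((nsteps, 3))
        else:
            noise = np.zeros((nsteps, 3))
    nsave = nsteps // save_every
    xs = np.empty(nsave)
    ys = np.empty(nsave)
    phis = np.empty(nsave)
    bad = _integrate_kernel(x0, y0, phi0, run.dt, cfg.v0, cfg.theta_rad,
                            cfg.ell, cfg.a1, cfg.a2, cfg.k_wall, cfg.mu_t,
                            cfg.mu_r, math.sqrt(2 * cfg.D_t * run.dt),
                            math.sqrt(2 * cfg.D_r * run.dt),
                            run.trap_radius, noise, save_every, xs, ys, phis)
    if bad >= 0:
        raise NumericalError("NaN in simulation state", step=int(bad))
    times = np.arange(nsave + 1) * (save_every * run.dt)
    xs = np.concatenate([[x0], xs])
    ys = np.concatenate([[y0], ys])
    phis = np.concatenate([[phi0], phis])
    return times, xs, ys, phis


def simulate(cfg: SwimmerConfig, run: SimRun,
             output_dt: float = 0.002) -> Trajectory:
    """Simulate and package the track as a Trajectory (trap at the origin).

    Output is subsampled to ``output_dt`` (default 2 ms, the 500 fps frame
    interval of the recordings the model mimics).  Identical seeds give
    bit-identical trajectories.
    """
    times, xs, ys, _ = simulate_raw(cfg, run, output_dt=output_dt)
    return Trajectory(times, xs, ys, frame_interval=output_dt * 1.0
                      if len(times) > 1 else run.dt,
                      trap=Trap(0.0, 0.0, run.trap_radius),
                      meta={"theta_deg": cfg.theta, "v0": cfg.v0,
                            "seed": run.seed})


def sweep(cfgs: Sequence[SwimmerConfig], trap_radii: Sequence[float],
          run_template: SimRun, seeds: Sequence[int],
          n_bins: int = 15) -> pd.DataFrame:
    """Summary statistics per (config, trap, seed) plus seed-averaged rows.

    Columns: theta_deg, v0, trap_radius, seed, peak_Pr_radius (argmax of the
    radial density, µm), msd_plateau (µm²), mean_tangential_flux (µm/s, CCW
    positive).  Seed-averaged rows have seed = -1.
    """
    from .spatial import mean_tangential_flux, msd, occupancy_flux, \
        radial_density

    if not len(cfgs) or not len(trap_radii) or not len(seeds):
        raise ConfigError("sweep requires nonempty cfgs, traps and seeds")
    rows = []
    for ci, cfg in enumerate(cfgs):
        for R in trap_radii:
            for seed in seeds:
                run = SimRun(dt=run_template.dt,
                             duration=run_template.duration, seed=int(seed),
                             trap_radius=float(R),
                             initial=run_template.initial)
                traj = simulate(cfg, run)
                field = occupancy_flux(traj, n_bins=n_bins)
                dens = radial_density(traj)
                curve = msd(traj)
                rows.append({
                    "cfg_index": ci, "theta_deg": cfg.theta, "v0": cfg.v0,
                    "trap_radius": float(R), "seed": int(seed),
                    "peak_Pr_radius": dens.peak_radius(),
                    "msd_plateau": curve.plateau(),
                    "mean_tangential_flux": mean_tangential_flux(field),
                })
    df = pd.DataFrame(rows)
    means = (df.groupby(["cfg_index", "theta_deg", "v0", "trap_radius"],
                        as_index=False)
               .agg({"peak_Pr_radius": "mean", "msd_plateau": "mean",
                     "mean_tangential_flux": "mean"}))
    means["seed"] = -1
    return pd.concat([df, means], ignore_index=True)
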