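"""Labelled synthetic gait trajectories: CTMC switching + per-state kinematics.

This generator produces the statistical structure the analysis pipeline
assumes — exponential sojourns in three macrostates with state-specific
movement — for a biflagellate-like (CR) run/stop/tumble phenotype and an
octoflagellate-like (PO) run/stop/shock phenotype, inside a circular arena.
Every sample carries its ground-truth state label, so segmentation and
network estimation can be validated end to end without recordings.

Wall handling is a simple specular reflection of the heading with the
position clamped inside the arena: the generator tests the statistics
pipeline, not wall physics (boundary-following and chirality belong to the
dumbbell simulator, not here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .segmentation import EVENT, RUN, STOP, StateSequence
from .trajectory_io import Trajectory, Trap

__all__ = ["BehaviourConfig", "LabelledTrajectory", "generate",
           "generate_cohort"]


@dataclass
class BehaviourConfig:
    """Rates and state-specific kinematics of the synthetic swimmer.

    ``Q[i, j]`` are CTMC transition rates in 1/s (diagonal ignored) over
    states (0 stop, 1 run, 2 tumble/shock).  Run kinematics: mean/sd speed
    (µm/s), heading diffusion (rad²/s) and a transverse helical oscillation
    (amplitude µm at frequency Hz) riding on the path — the positional
    signature of the ciliary beat.  Event kinematics depend on ``mode``:
    "CR_tumble" rotates at ±tumble_omega with slow translation;
    "PO_shock" swims backwards at shock speed with erratic heading
    (shock_heading_diffusion), truncated at ``shock_cap`` seconds, then
    reorients by a uniform draw from ``reorient_range`` (radians, relative
    to the pre-shock heading, random sign).
    """

    Q: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    mode: str = "CR_tumble"
    run_speed_mean: float = 80.0
    run_speed_sd: float = 8.0
    run_heading_diffusion: float = 0.1
    osc_amplitude: float = 0.005
    osc_frequency: float = 52.0
    stop_jitter_sd: float = 0.005
    tumble_omega: float = 25.0
    tumble_speed: float = 25.0
    shock_speed_mean: float = 1300.0
    shock_speed_sd: float = 150.0
    shock_cap: float = 0.1
    shock_heading_diffusion: float = 20.0
    reorient_range: tuple = (math.pi / 2, 3 * math.pi / 2)
    trap_radius: float = 60.0
    frame_rate: float = 500.0
    seed: int = 0

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.shape != (3, 3) or np.any(self.Q < 0):
            raise ConfigError("Q must be a 3x3 matrix of nonnegative rates")
        if self.mode not in ("CR_tumble", "PO_shock"):
            raise ConfigError(f"unknown event mode {self.mode!r}")
        if self.frame_rate < 2 * self.osc_frequency:
            raise ConfigError(
                "frame rate below Nyquist for the configured oscillation")
        if self.shock_cap <= 0:
            raise ConfigError("shock duration cap must be > 0")

    @property
    def species(self) -> str:
        return "CR" if self.mode == "CR_tumble" else "PO"

    @classmethod
    def cr_defaults(cls) -> "BehaviourConfig":
        """Biflagellate-like continuous swimmer: ~80 µm/s runs with a 52 Hz
        beat signature, occasional stops and ~200 ms tumbles."""
        Q = np.array([
            [0.0, 1.0, 0.1],    # stop -> run, stop -> tumble
            [0.05, 0.0, 0.15],  # run -> stop, run -> tumble
            [0.5, 4.5, 0.0],    # tumble -> stop, tumble -> run
        ])
        return cls(Q=Q, mode="CR_tumble")

    @classmethod
    def po_defaults(cls) -> "BehaviourConfig":
        """Octoflagellate-like episodic swimmer: 300-400 µm/s runs, long
        quiescent stops, and millisecond-scale >1 mm/s backward shocks."""
        Q = np.array([
            [0.0, 0.5, 0.05],   # stop -> run, stop -> shock
            [0.2, 0.0, 0.2],    # run -> stop, run -> shock
            [2.0, 23.0, 0.0],   # shock -> stop, shock -> run
        ])
        return cls(Q=Q, mode="PO_shock", run_speed_mean=350.0,
                   run_speed_sd=25.0, run_heading_diffusion=0.2,
                   osc_amplitude=0.0)


@dataclass
class LabelledTrajectory:
    """A synthetic trajectory with sample-aligned ground-truth states."""

    trajectory: Trajectory
    states: StateSequence
    config: BehaviourConfig

    def __post_init__(self):
        if len(self.trajectory) != len(self.states):
            raise ValueError("labels must align sample-wise with trajectory")


def _reflect(phi: float, x: float, y: float) -> float:
    """Specular reflection of the heading about the wall tangent at (x, y)."""
    nx, ny = x, y
    nrm = math.hypot(nx, ny)
    if nrm == 0:
        return phi
    nx /= nrm
    ny /= nrm
    ex, ey = math.cos(phi), math.sin(phi)
    dot = ex * nx + ey * ny
    if dot <= 0:       # already moving inward
        return phi
    return math.atan2(ey - 2 * dot * ny, ex - 2 * dot * nx)


def generate(cfg: BehaviourConfig, duration: float,
             seed: Optional[int] = None,
             start_state: int = RUN) -> LabelledTrajectory:
    """Generate a labelled trajectory of the given duration (seconds).

    Sojourns are exponential with the configured exit rates (shock sojourns
    truncated at ``shock_cap``); a state with zero total exit rate is
    absorbing.  Positions integrate per-state kinematics at the frame rate;
    the run-state transverse oscillation is superposed on the output
    positions so the beat signature appears in the track without feeding
    back into the path.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    dt = 1.0 / cfg.frame_rate
    n_total = int(round(duration / dt))
    if n_total < 1:
        raise ConfigError("duration shorter than one frame")
    R_in = cfg.trap_radius - 1.0     # clamp radius just inside the wall

    labels = np.empty(n_total, dtype=np.int8)
    xs = np.empty(n_total)
    ys = np.empty(n_total)

    # start mid-arena with a random heading
    r0 = 0.5 * R_in * math.sqrt(rng.random())
    ang0 = rng.random() * 2 * math.pi
    x, y = r0 * math.cos(ang0), r0 * math.sin(ang0)
    phi = rng.random() * 2 * math.pi
    osc_phase = rng.random() * 2 * math.pi

    state = start_state
    i = 0
    while i < n_total:
        rates = cfg.Q[state].copy()
        rates[state] = 0.0
        total = rates.sum()
        if total > 0:
            T = rng.exponential(1.0 / total)
        else:
            T = (n_total - i) * dt
        if state == EVENT and cfg.mode == "PO_shock":
            T = min(T, cfg.shock_cap)
        n = min(max(1, int(round(T / dt))), n_total - i)
        sl = slice(i, i + n)
        labels[sl] = state

        if state == RUN:
            speeds = np.clip(rng.normal(cfg.run_speed_mean, cfg.run_speed_sd,
                                        n), 0.0, None)
            dphi = (math.sqrt(2 * cfg.run_heading_diffusion * dt)
                    * rng.standard_normal(n))
            phis = np.empty(n)
            for k in range(n):
                phi += dphi[k]
                x += speeds[k] * math.cos(phi) * dt
                y += speeds[k] * math.sin(phi) * dt
                if math.hypot(x, y) > R_in:
                    phi = _reflect(phi, x, y)
                    scale = R_in / math.hypot(x, y)
                    x *= scale
                    y *= scale
                xs[i + k] = x
                ys[i + k] = y
                phis[k] = phi
            if cfg.osc_amplitude > 0:
                tt = (np.arange(i, i + n) * dt)
                wob = cfg.osc_amplitude * np.sin(
                    2 * math.pi * cfg.osc_frequency * tt + osc_phase)
                xs[sl] += wob * (-np.sin(phis))
                ys[sl] += wob * np.cos(phis)
        elif state == STOP:
            xs[sl] = x + rng.normal(0.0, cfg.stop_jitter_sd, n)
            ys[sl] = y + rng.normal(0.0, cfg.stop_jitter_sd, n)
        elif cfg.mode == "CR_tumble":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            for k in range(n):
                phi += sign * cfg.tumble_omega * dt
                x += cfg.tumble_speed * math.cos(phi) * dt
                y += cfg.tumble_speed * math.sin(phi) * dt
                if math.hypot(x, y) > R_in:
                    phi = _reflect(phi, x, y)
                    scale = R_in / math.hypot(x, y)
                    x *= scale
                    y *= scale
                xs[i + k] = x
                ys[i + k] = y
        else:  # PO shock: backward swimming, erratic heading, reorientation
            speeds = np.clip(rng.normal(cfg.shock_speed_mean,
                                        cfg.shock_speed_sd, n), 0.0, None)
            dphi = (math.sqrt(2 * cfg.shock_heading_diffusion * dt)
                    * rng.standard_normal(n))
            for k in range(n):
                phi += dphi[k]
                x -= speeds[k] * math.cos(phi) * dt
                y -= speeds[k] * math.sin(phi) * dt
                if math.hypot(x, y) > R_in:
                    # reflect the direction of motion (-ê) about the tangent
                    phi = _reflect(phi + math.pi, x, y) - math.pi
                    scale = R_in / math.hypot(x, y)
                    x *= scale
                    y *= scale
                xs[i + k] = x
                ys[i + k] = y
            lo, hi = cfg.reorient_range
            turn = rng.uniform(lo, hi)
            phi += turn if rng.random() < 0.5 else -turn

        i += n
        if total > 0:
            state = int(rng.choice(3, p=rates / total))

    times = np.arange(n_total) * dt
    traj = Trajectory(times, xs, ys, frame_interval=dt,
                      trap=Trap(0.0, 0.0, cfg.trap_radius),
                      meta={"species": cfg.species, "synthetic": True})
    states = StateSequence(times=times, S=labels,
                           species_mode=cfg.species,
                           thresholds={"ground_truth": True})
    return LabelledTrajectory(trajectory=traj, states=states, config=cfg)


def generate_cohort(cfg: BehaviourConfig, n_cells: int, n_intervals: int,
                    drift: Optional[Sequence] = None,
                    duration: float = 300.0) -> list[LabelledTrajectory]:
    """Independent labelled cells over repeated recording intervals.

    ``drift`` scales the rate matrix per interval: an (n_intervals,) array of
    scalar multipliers, or (n_intervals, 3, 3) per-rate multipliers (e.g. to
    make run->stop switching more likely over time).  Per-(cell, interval)
    seeds derive deterministically from ``cfg.seed``; each result's
    trajectory meta records cell, interval and seed.  Returns the flat list
    ordered cell-major.
    """
    if n_cells < 1 or n_intervals < 1:
        raise ConfigError("n_cells and n_intervals must be >= 1")
    if drift is None:
        drift = np.ones(n_intervals)
    drift = np.asarray(drift, dtype=float)
    if drift.shape not in ((n_intervals,), (n_intervals, 3, 3)):
        raise ConfigError("drift must have shape (n_intervals,) or "
                          "(n_intervals, 3, 3)")
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(n_cells * n_intervals)
    out = []
    for c in range(n_cells):
        for t in range(n_intervals):
            mult = drift[t]
            icfg = replace(cfg, Q=cfg.Q * mult)
            child = children[c * n_intervals + t]
            seed = int(child.generate_state(1)[0] % (2 ** 31))
            lt = generate(icfg, duration, seed=seed)
            lt.trajectory.meta.update({"cell": c, "interval": t,
                                       "seed": seed})
            out.append(lt)
    return out
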