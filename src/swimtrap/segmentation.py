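"""Three-macrostate gait segmentation: stop (0), run (1), tumble/shock (2).

The classifier is a per-sample threshold rule followed by dwell-time
debouncing, mirroring how gait states are scored by eye from high-speed
recordings: a sample is a stop when the cell barely translates, a run when it
translates smoothly, and a reorientation event (biflagellate tumble or
octoflagellate shock) when the angular kinematics spike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigError, GeometryError, SizeError
from .kinematics import KinematicSeries
from .trajectory_io import AnalysisConfig, Trajectory

__all__ = ["StateSequence", "classify_states", "boundary_run_annotation",
           "STOP", "RUN", "EVENT"]

STOP, RUN, EVENT = 0, 1, 2


@dataclass
class StateSequence:
    """Per-sample discrete motility state aligned to a kinematic series."""

    times: np.ndarray
    S: np.ndarray                    # int in {0, 1, 2}
    species_mode: str = "CR"
    thresholds: dict = field(default_factory=dict)
    boundary: Optional[np.ndarray] = None   # per-sample boundary-run flag

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=np.int8)
        if not np.isin(self.S, (STOP, RUN, EVENT)).all():
            raise ValueError("states must be in {0, 1, 2}")

    def __len__(self) -> int:
        return self.times.size

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.times)))

    def segments(self) -> list[tuple[int, int, int]]:
        """Maximal constant-state segments as (start, stop, state) with
        half-open sample ranges."""
        return _run_length_segments(self.S)


def _run_length_segments(S: np.ndarray) -> list[tuple[int, int, int]]:
    if S.size == 0:
        return []
    change = np.flatnonzero(np.diff(S)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [S.size]])
    return [(int(a), int(b), int(S[a])) for a, b in zip(starts, stops)]


def _raw_classify(kin: KinematicSeries, cfg: AnalysisConfig) -> np.ndarray:
    v = kin.v
    if cfg.species_mode == "CR":
        S = np.where(v < cfg.v_c, STOP,
                     np.where(np.abs(kin.omega) > cfg.omega_c, EVENT, RUN))
    elif cfg.species_mode == "PO":
        shock = (v > cfg.v_shock) & (np.abs(kin.domega_dt) > cfg.domega_dt_c)
        S = np.where(v < cfg.v_c, STOP, np.where(shock, EVENT, RUN))
    else:  # pragma: no cover - AnalysisConfig already validates
        raise ConfigError(f"unknown species_mode {cfg.species_mode!r}")
    return S.astype(np.int8)


def _debounce(S: np.ndarray, dt: float, min_dwell: float) -> np.ndarray:
    """Merge interior segments shorter than ``min_dwell`` into the longer
    neighbouring segment (ties -> preceding segment).

    The first and last segments are exempt (they are censored by the
    observation window).  Merging relabels samples, so total duration is
    conserved.  Segments are processed shortest-first and recomputed after
    every merge, since merges can coalesce neighbours.
    """
    S = S.copy()
    while True:
        segs = _run_length_segments(S)
        if len(segs) <= 2:
            return S
        durations = [(b - a) * dt for a, b, _ in segs]
        interior = [k for k in range(1, len(segs) - 1)
                    if durations[k] < min_dwell]
        if not interior:
            return S
        k = min(interior, key=lambda i: (durations[i], i))
        a, b, _ = segs[k]
        prev_state = segs[k - 1][2]
        next_state = segs[k + 1][2]
        if durations[k + 1] > durations[k - 1]:
            S[a:b] = next_state
        else:  # ties go to the preceding segment
            S[a:b] = prev_state


def classify_states(kin: KinematicSeries, cfg: AnalysisConfig) -> StateSequence:
    """Map kinematics to macrostates with the species-specific rule.

    CR rule: stop if v < v_c; else tumble if |Ω| > Ω_c; else run.
    PO rule: stop if v < v_c; else shock if v > v_shock AND
    |dΩ/dt| > dΩdt_c (both are elevated during a shock); else run.
    Segments shorter than ``min_dwell`` are then debounced away.
    """
    if len(kin) == 0:
        raise SizeError("empty kinematic series")
    raw = _raw_classify(kin, cfg)
    dt = kin.frame_interval if len(kin) > 1 else cfg.min_dwell
    S = _debounce(raw, dt, cfg.min_dwell)
    thresholds = {"v_c": cfg.v_c, "omega_c": cfg.omega_c,
                  "v_shock": cfg.v_shock, "domega_dt_c": cfg.domega_dt_c,
                  "min_dwell": cfg.min_dwell,
                  "species_mode": cfg.species_mode}
    return StateSequence(times=kin.times.copy(), S=S,
                         species_mode=cfg.species_mode, thresholds=thresholds)


def boundary_run_annotation(states: StateSequence, traj: Trajectory,
                            wall_margin: float) -> np.ndarray:
    """Flag run samples within ``wall_margin`` µm of the trap wall.

    Interior runs (straight crossings) and boundary runs (wall-guided
    circling) are both runs; this annotation distinguishes them for
    downstream statistics.  Stop/event samples are never flagged.  The flag
    array is also stored on ``states.boundary``.
    """
    if traj.trap is None:
        raise GeometryError("boundary annotation requires trap geometry")
    r = np.hypot(traj.x - traj.trap.cx, traj.y - traj.trap.cy)
    dist_to_wall = traj.trap.radius - r
    flag = (states.S == RUN) & (dist_to_wall < wall_margin)
    states.boundary = flag
    return flag
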