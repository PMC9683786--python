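"""Continuous-time Markov reaction-network estimation from state sequences.

From a discrete gait sequence S(t) we estimate the state probabilities p_i,
per-state sojourn-time lists T_i, empirical survival curves P(T_i > τ),
transition counts and probabilities p_ij, and transition rates q_ij.  Rates
default to the exit-rate normalisation q_ij = n_ij / (time spent in i), which
makes the estimate directly comparable with the rate matrix of a generating
CTMC; q_ij = n_ij / total_time is available via ``rate_norm="total"``.

The first and last sojourns are censored by the observation window: they are
excluded from the sojourn lists (and hence survival and mean-residence
statistics) but counted in occupancies and rate denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SizeError
from .segmentation import StateSequence

__all__ = ["MotilityNetwork", "SurvivalCurve", "estimate_network",
           "survival_curve", "network_timecourse", "N_STATES"]

N_STATES = 3
log = logging.getLogger(__name__)


@dataclass
class MotilityNetwork:
    """Time-averaged three-state reaction network.

    p[i]               probability of being in state i (time fraction)
    sojourns[i]        uncensored sojourn durations in state i (s)
    mean_residence[i]  mean uncensored sojourn ⟨T_i⟩ (s); 0 if none observed
    P_trans[i, j]      transition probability p_ij (rows over j≠i sum to 1
                       for states with at least one exit; diagonal 0)
    Q[i, j]            transition rate q_ij in 1/s (diagonal 0)
    n_trans[i, j]      transition counts
    total_time         observation time (s)
    """

    p: np.ndarray
    sojourns: list
    mean_residence: np.ndarray
    P_trans: np.ndarray
    Q: np.ndarray
    n_trans: np.ndarray
    total_time: float

    def exit_rate(self, i: int) -> float:
        """Total exit rate from state i, Σ_j q_ij."""
        return float(self.Q[i].sum())


@dataclass
class SurvivalCurve:
    """Empirical survival function P(T > τ) as a right-continuous step
    function evaluated on the sorted unique sojourn grid (prepended τ=0)."""

    tau: np.ndarray
    P_survive: np.ndarray

    def __call__(self, tau) -> np.ndarray:
        """Evaluate P(T > τ) for arbitrary τ (vectorised)."""
        tau = np.asarray(tau, dtype=float)
        idx = np.searchsorted(self.tau, tau, side="right") - 1
        idx = np.clip(idx, 0, self.tau.size - 1)
        out = self.P_survive[idx]
        return out if out.ndim else float(out)


def estimate_network(states: StateSequence,
                     rate_norm: str = "state") -> MotilityNetwork:
    """Estimate the three-state network from a state sequence.

    Occupancy uses per-sample weights of one frame interval; sojourn lists
    exclude the censored first and last segments; transition counts come from
    segment boundaries.
    """
    if len(states) < 2:
        raise SizeError("estimate_network requires >= 2 samples")
    if rate_norm not in ("state", "total"):
        raise ValueError(f"unknown rate_norm {rate_norm!r}")
    dt = states.frame_interval
    S = states.S
    n = S.size
    total_time = n * dt

    time_in = np.array([np.count_nonzero(S == i) * dt
                        for i in range(N_STATES)])
    p = time_in / total_time

    segs = states.segments()
    sojourns = [[] for _ in range(N_STATES)]
    for a, b, s in segs[1:-1]:
        sojourns[s].append((b - a) * dt)
    sojourns = [np.array(sj, dtype=float) for sj in sojourns]

    n_trans = np.zeros((N_STATES, N_STATES), dtype=int)
    for (_, _, s_from), (_, _, s_to) in zip(segs[:-1], segs[1:]):
        n_trans[s_from, s_to] += 1

    exits = n_trans.sum(axis=1)
    P_trans = np.zeros((N_STATES, N_STATES))
    Q = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES):
        if exits[i] > 0:
            P_trans[i] = n_trans[i] / exits[i]
        if time_in[i] > 0:
            denom = time_in[i] if rate_norm == "state" else total_time
            Q[i] = n_trans[i] / denom
        elif exits[i] > 0:  # pragma: no cover - cannot exit an unvisited state
            log.warning("state %d has exits but zero occupancy", i)

    mean_residence = np.array([sj.mean() if sj.size else 0.0
                               for sj in sojourns])
    for i in range(N_STATES):
        if time_in[i] == 0:
            log.warning("state %d never visited; zero row in network", i)

    return MotilityNetwork(p=p, sojourns=sojourns,
                           mean_residence=mean_residence, P_trans=P_trans,
                           Q=Q, n_trans=n_trans, total_time=total_time)


def survival_curve(sojourns) -> SurvivalCurve:
    """Empirical survival function of a list of sojourn times."""
    sojourns = np.asarray(sojourns, dtype=float)
    if sojourns.size == 0:
        raise SizeError("survival_curve requires a nonempty sojourn list")
    if np.any(sojourns <= 0):
        raise ValueError("sojourn times must be > 0")
    grid = np.unique(sojourns)
    n = sojourns.size
    surv = np.array([(np.count_nonzero(sojourns > tau)) / n for tau in grid])
    tau = np.concatenate([[0.0], grid])
    P = np.concatenate([[1.0], surv])
    return SurvivalCurve(tau=tau, P_survive=P)


# scalar fields summarised across intervals by network_timecourse
_SCALARS = (["p0", "p1", "p2"]
            + [f"q{i}{j}" for i in range(3) for j in range(3) if i != j]
            + ["T0", "T1", "T2"])


def _scalars(net: MotilityNetwork) -> dict:
    out = {f"p{i}": net.p[i] for i in range(3)}
    out.update({f"q{i}{j}": net.Q[i, j]
                for i in range(3) for j in range(3) if i != j})
    out.update({f"T{i}": net.mean_residence[i] for i in range(3)})
    return out


def network_timecourse(per_interval: list[StateSequence],
                       rate_norm: str = "state",
                       ) -> tuple[list[MotilityNetwork], pd.DataFrame]:
    """One network per recording interval plus mean/SE of each scalar.

    Mirrors the repeated-recording assay design (e.g. 5-min recordings at
    5-min intervals): each interval's sequence is estimated independently and
    the summary frame carries the across-interval mean and standard error
    (sd/√N with ddof=1; NaN when N = 1) of every scalar network parameter.
    """
    if len(per_interval) < 1:
        raise SizeError("network_timecourse requires >= 1 interval")
    nets = [estimate_network(s, rate_norm=rate_norm) for s in per_interval]
    rows = pd.DataFrame([_scalars(n) for n in nets])
    N = len(nets)
    mean = rows.mean(axis=0)
    se = rows.std(axis=0, ddof=1) / np.sqrt(N) if N > 1 \
        else pd.Series(np.nan, index=rows.columns)
    summary = pd.DataFrame({"mean": mean, "se": se})
    return nets, summary
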