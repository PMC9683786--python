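"""Spatial statistics over the trap disk: occupancy, probability flux, P(r),
tangential-flux profiles and mean-squared displacement.

The flux estimator captures the "arrow of time" in a single cell's movement
history: for each spatial bin it accumulates the single-step displacement
vectors of all steps that start in the bin and divides by the time spent
there, yielding the conditional mean velocity at that position.  A
conservative (closed-loop) pattern of these vectors indicates a
non-equilibrium steady state with broken detailed balance; the tangential
projection quantifies the sense (CCW positive) and strength of circulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, SizeError
from .trajectory_io import Trajectory

__all__ = ["FluxField", "RadialDensity", "MsdCurve", "TangentialFluxProfile",
           "occupancy_flux", "tangential_flux_profile", "radial_density",
           "msd", "mean_tangential_flux"]

log = logging.getLogger(__name__)


@dataclass
class FluxField:
    """Binned occupancy and time-averaged flux over the trap-centred square.

    ``edges`` are shared x/y bin edges in µm relative to the trap centre,
    spanning [-R, R] (trap-size-scaled coordinates).  ``occupancy`` sums to 1
    over occupied bins; ``flux[i, j]`` is the conditional mean velocity
    (µm/s) for bins indexed [x-bin, y-bin]; zero where occupancy is zero.
    """

    edges: np.ndarray
    occupancy: np.ndarray
    flux: np.ndarray
    trap_radius: float
    total_time: float

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def bin_radii(self) -> np.ndarray:
        cx, cy = np.meshgrid(self.centers, self.centers, indexing="ij")
        return np.hypot(cx, cy)

    def tangential(self) -> np.ndarray:
        """Per-bin flux projected on the azimuthal unit vector (CCW +)."""
        cx, cy = np.meshgrid(self.centers, self.centers, indexing="ij")
        r = np.hypot(cx, cy)
        r = np.where(r == 0, 1.0, r)
        tx, ty = -cy / r, cx / r
        return self.flux[..., 0] * tx + self.flux[..., 1] * ty


@dataclass
class RadialDensity:
    """Line-normalised radial probability density: ∫ P(r) dr = 1, so uniform
    disk occupancy reads as P(r) ∝ r."""

    r: np.ndarray        # bin centres, µm from trap centre
    P: np.ndarray        # 1/µm
    edges: np.ndarray

    def peak_radius(self) -> float:
        return float(self.r[np.argmax(self.P)])


@dataclass
class MsdCurve:
    lags: np.ndarray     # s
    msd: np.ndarray      # µm²

    def plateau(self, tail_fraction: float = 0.5) -> float:
        """Mean MSD over the trailing fraction of available lags."""
        k = max(1, int(round(self.lags.size * (1 - tail_fraction))))
        return float(self.msd[k:].mean())


@dataclass
class TangentialFluxProfile:
    r: np.ndarray        # annulus centres, µm
    flux_t: np.ndarray   # µm/s, CCW positive; NaN where annulus unoccupied


def _require_trap(traj: Trajectory):
    if traj.trap is None:
        raise GeometryError("operation requires trap geometry")
    return traj.trap


def occupancy_flux(traj: Trajectory, n_bins: int = 15) -> FluxField:
    """Binned occupancy and conditional-mean-velocity flux field.

    Occupancy is the fraction of observation time spent in each bin (each of
    the N-1 steps contributes its starting sample); flux in a bin is the sum
    of step displacements starting there divided by the time spent there.
    The occupancy-weighted flux therefore telescopes exactly to
    (final - initial position) / total time.
    """
    trap = _require_trap(traj)
    if len(traj) < 2:
        raise SizeError("occupancy_flux requires >= 2 points")
    R = trap.radius
    x = traj.x - trap.cx
    y = traj.y - trap.cy
    dt = traj.frame_interval
    edges = np.linspace(-R, R, n_bins + 1)

    xs, ys = x[:-1], y[:-1]           # step starting points
    dx, dy = np.diff(x), np.diff(y)
    ix = np.clip(np.digitize(xs, edges) - 1, 0, n_bins - 1)
    iy = np.clip(np.digitize(ys, edges) - 1, 0, n_bins - 1)
    flat = ix * n_bins + iy
    counts = np.bincount(flat, minlength=n_bins * n_bins).astype(float)
    sx = np.bincount(flat, weights=dx, minlength=n_bins * n_bins)
    sy = np.bincount(flat, weights=dy, minlength=n_bins * n_bins)

    n_steps = xs.size
    total_time = n_steps * dt
    occupancy = (counts / n_steps).reshape(n_bins, n_bins)
    time_in = counts * dt
    with np.errstate(invalid="ignore", divide="ignore"):
        fx = np.where(time_in > 0, sx / np.where(time_in > 0, time_in, 1), 0.0)
        fy = np.where(time_in > 0, sy / np.where(time_in > 0, time_in, 1), 0.0)
    flux = np.stack([fx.reshape(n_bins, n_bins),
                     fy.reshape(n_bins, n_bins)], axis=-1)
    return FluxField(edges=edges, occupancy=occupancy, flux=flux,
                     trap_radius=R, total_time=total_time)


def mean_tangential_flux(field: FluxField) -> float:
    """Occupancy-weighted mean tangential flux over the trap (µm/s, CCW +)."""
    return float(np.sum(field.occupancy * field.tangential()))


def tangential_flux_profile(field: FluxField,
                            n_annuli: int = 10) -> TangentialFluxProfile:
    """Occupancy-weighted mean tangential flux per radial annulus.

    Annuli with zero occupancy yield NaN (flagged undefined) rather than 0.
    """
    R = field.trap_radius
    redges = np.linspace(0.0, R, n_annuli + 1)
    rads = field.bin_radii().ravel()
    occ = field.occupancy.ravel()
    tang = field.tangential().ravel()
    idx = np.clip(np.digitize(rads, redges) - 1, 0, n_annuli - 1)
    wsum = np.bincount(idx, weights=occ, minlength=n_annuli)
    fsum = np.bincount(idx, weights=occ * tang, minlength=n_annuli)
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = np.where(wsum > 0, fsum / np.where(wsum > 0, wsum, 1), np.nan)
    centers = 0.5 * (redges[:-1] + redges[1:])
    return TangentialFluxProfile(r=centers, flux_t=prof)


def radial_density(traj: Trajectory, n_bins: int = 30) -> RadialDensity:
    """Histogram of distance to the trap centre, normalised to ∫P dr = 1.

    Points more than 1 µm outside the trap raise a data warning in the log
    and are clipped to the wall radius.
    """
    trap = _require_trap(traj)
    r = np.hypot(traj.x - trap.cx, traj.y - trap.cy)
    n_out = int(np.count_nonzero(r > trap.radius + 1.0))
    if n_out:
        log.warning("%d samples lie > 1 µm outside the trap; clipped", n_out)
    r = np.minimum(r, trap.radius)
    edges = np.linspace(0.0, trap.radius, n_bins + 1)
    counts, _ = np.histogram(r, bins=edges)
    dr = edges[1] - edges[0]
    P = counts / (r.size * dr)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RadialDensity(r=centers, P=P, edges=edges)


def _msd_fft(pos: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged MSD over all start times via the FFT autocorrelation
    identity msd(m) = S1(m) - 2 S2(m)."""
    N = pos.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * N)))
    D = np.square(pos).sum(axis=1)
    S2 = np.zeros(N)
    for d in range(pos.shape[1]):
        F = np.fft.rfft(pos[:, d], nfft)
        ac = np.fft.irfft(F * np.conj(F), nfft)[:N]
        S2 += ac
    S2 /= np.arange(N, 0, -1)
    Dpad = np.concatenate([D, [0.0]])
    sumsq = 2.0 * D.sum()
    S1 = np.empty(N)
    for m in range(N):
        S1[m] = sumsq / (N - m)
        sumsq -= Dpad[m] + Dpad[N - 1 - m]
    out = S1 - 2.0 * S2
    return np.maximum(out[:max_lag + 1], 0.0)


def msd(traj: Trajectory, max_lag_fraction: float = 0.25) -> MsdCurve:
    """Time-averaged mean-squared displacement.

    Averages |x(t+τ) - x(t)|² over all start times t for each lag τ up to
    ``max_lag_fraction`` of the track duration (default 25%, bounding the
    estimator variance at long lags).
    """
    if len(traj) < 2:
        raise SizeError("msd requires >= 2 points")
    if not 0 < max_lag_fraction <= 1:
        raise ValueError("max_lag_fraction must be in (0, 1]")
    N = len(traj)
    max_lag = max(1, int(np.floor((N - 1) * max_lag_fraction)))
    curve = _msd_fft(traj.positions, max_lag)
    lags = np.arange(max_lag + 1) * traj.frame_interval
    return MsdCurve(lags=lags, msd=curve)
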