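"""Trajectory containers, CSV ingest (plain / TrackMate spots) and product serialization.

Coordinates are lab-frame micrometres viewed from above, with y increasing "up"
in the image as stored; counter-clockwise is the positive sense of rotation in
this frame and no axis flip is applied on ingest.  Times are seconds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataError, FormatError

__all__ = [
    "Trap",
    "Trajectory",
    "AnalysisConfig",
    "read_track_csv",
    "write_trajectory_csv",
    "write_products",
    "read_product",
]


@dataclass(frozen=True)
class Trap:
    """Circular arena: centre (µm) and radius (µm)."""

    cx: float
    cy: float
    radius: float

    def __post_init__(self):
        if not self.radius > 0:
            raise DataError(f"trap radius must be > 0, got {self.radius}")


@dataclass
class Trajectory:
    """A time-stamped 2D centroid track.

    Attributes
    ----------
    times : array of seconds, strictly increasing
    x, y : arrays of micrometres (lab frame)
    frame_interval : nominal sampling interval in seconds
    trap : optional circular-arena geometry
    meta : free-form labels (species tag, condition tag, cell id, ...)
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_interval: float
    trap: Optional[Trap] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.times.size
        if n < 1 or self.x.size != n or self.y.size != n:
            raise DataError(
                f"times/x/y must be equal-length and non-empty "
                f"(got {n}, {self.x.size}, {self.y.size})"
            )
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise DataError("times must be strictly increasing")
        if not self.frame_interval > 0:
            raise DataError("frame_interval must be > 0")
        if n > 1:
            med = float(np.median(np.diff(self.times)))
            if abs(med - self.frame_interval) > 0.01 * self.frame_interval:
                raise DataError(
                    f"frame_interval {self.frame_interval} inconsistent with "
                    f"median diff(times) {med}"
                )

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of positions in µm."""
        return np.column_stack([self.x, self.y])


# --------------------------------------------------------------------------
# analysis configuration


@dataclass
class AnalysisConfig:
    """Segmentation thresholds and analysis knobs.

    All thresholds are in physical units: v_c and v_shock in µm/s, omega_c in
    rad/s, domega_dt_c in rad/s², min_dwell and smoothing_window in seconds.
    ``species_mode`` selects the classification rule ("CR" biflagellate
    run/stop/tumble, or "PO" octoflagellate run/stop/shock).
    """

    species_mode: str = "CR"
    v_c: float = 10.0
    omega_c: float = 12.0
    v_shock: float = 500.0
    domega_dt_c: float = 300.0
    min_dwell: float = 0.020
    smoothing_window: float = 0.010
    flux_bins: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.species_mode not in ("CR", "PO"):
            raise ConfigError(f"unknown species_mode {self.species_mode!r}")
        for name in ("v_c", "omega_c", "v_shock", "domega_dt_c", "min_dwell",
                     "smoothing_window"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.flux_bins < 4:
            raise ConfigError("flux_bins must be >= 4")

    @classmethod
    def cr_defaults(cls) -> "AnalysisConfig":
        return cls(species_mode="CR", v_c=10.0, omega_c=12.0)

    @classmethod
    def po_defaults(cls) -> "AnalysisConfig":
        return cls(species_mode="PO", v_c=20.0, v_shock=500.0,
                   domega_dt_c=300.0)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# --------------------------------------------------------------------------
# CSV ingest

_TRACKMATE_REQUIRED = ("TRACK_ID", "POSITION_X", "POSITION_Y")


def _numeric_or_nan(series: pd.Series) -> pd.Series:
    return pd.to_numeric(series, errors="coerce")


def read_track_csv(path, dialect: str = "plain3col", *,
                   frame_interval: Optional[float] = None,
                   trap: Optional[Trap] = None) -> list[Trajectory]:
    """Read trajectories from a CSV file.

    dialect "plain3col": columns t,x,y (header optional), seconds / µm.
    dialect "trackmate_spots": TrackMate spot export with one row per spot;
    requires TRACK_ID, POSITION_X, POSITION_Y and either POSITION_T (seconds)
    or FRAME (index, in which case ``frame_interval`` must be given).  Extra
    columns and TrackMate's repeated sub-header rows are ignored.

    Returns one Trajectory per track id, each sorted by time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "plain3col":
        return [_read_plain3col(path, trap)]
    if dialect == "trackmate_spots":
        return _read_trackmate(path, frame_interval, trap)
    raise FormatError(f"unknown dialect {dialect!r}")


def _read_plain3col(path: Path, trap: Optional[Trap]) -> Trajectory:
    first = path.read_text().splitlines()
    if not first:
        raise FormatError(f"{path}: empty file")
    try:
        [float(tok) for tok in first[0].split(",")]
        header = None
    except ValueError:
        header = 0
    df = pd.read_csv(path, header=header)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: expected 3 columns t,x,y, got {df.shape[1]}")
    t = df.iloc[:, 0].to_numpy(float)
    x = df.iloc[:, 1].to_numpy(float)
    y = df.iloc[:, 2].to_numpy(float)
    order = np.argsort(t, kind="stable")
    t, x, y = t[order], x[order], y[order]
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: non-monotone (repeated) time stamps")
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    return Trajectory(t, x, y, frame_interval=dt, trap=trap,
                      meta={"source": str(path)})


def _read_trackmate(path: Path, frame_interval: Optional[float],
                    trap: Optional[Trap]) -> list[Trajectory]:
    df = pd.read_csv(path)
    for col in _TRACKMATE_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col}")
    has_t = "POSITION_T" in df.columns
    has_frame = "FRAME" in df.columns
    if not has_t and not has_frame:
        raise FormatError(f"{path}: missing required column POSITION_T (or FRAME)")
    if not has_t and frame_interval is None:
        raise ConfigError(
            "FRAME-based TrackMate export requires an explicit frame_interval")
    # TrackMate >= v7 emits extra non-numeric sub-header rows; drop them.
    work = df.copy()
    for col in df.columns:
        work[col] = _numeric_or_nan(df[col])
    tcol = "POSITION_T" if has_t else "FRAME"
    work = work.dropna(subset=[*(_TRACKMATE_REQUIRED), tcol])

    out = []
    for tid, grp in work.groupby("TRACK_ID", sort=True):
        t = grp[tcol].to_numpy(float)
        if not has_t:
            t = t * frame_interval
        x = grp["POSITION_X"].to_numpy(float)
        y = grp["POSITION_Y"].to_numpy(float)
        order = np.argsort(t, kind="stable")
        t, x, y = t[order], x[order], y[order]
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise DataError(
                f"{path}: non-monotone time within track {int(tid)}")
        dt = (float(np.median(np.diff(t))) if t.size > 1
              else (frame_interval or 1.0))
        out.append(Trajectory(t, x, y, frame_interval=dt, trap=trap,
                              meta={"track_id": int(tid), "source": str(path)}))
    return out


def write_trajectory_csv(traj: Trajectory, path) -> Path:
    """Write the plain trajectory dialect: header ``t,x,y``, units s and µm."""
    path = Path(path)
    df = pd.DataFrame({"t": traj.times, "x": traj.x, "y": traj.y})
    df.to_csv(path, index=False, float_format="%.12g")
    return path


# --------------------------------------------------------------------------
# product serialization
#
# Per-sample series go to CSV; networks and flux fields go to JSON documents.
# JSON floats round-trip exactly in Python, satisfying the 12-significant-digit
# read-back contract; CSVs are written at %.12g.


def _serialize_array(a):
    return np.asarray(a).tolist()


def write_products(obj, path) -> Path:
    """Serialize an analysis product; dispatches on type.

    KinematicSeries / StateSequence -> CSV; MotilityNetwork / FluxField ->
    structured JSON with a ``kind`` tag for read-back.
    """
    # local imports avoid an import cycle (analysis modules import Trajectory)
    from .kinematics import KinematicSeries
    from .network import MotilityNetwork
    from .segmentation import StateSequence
    from .spatial import FluxField

    path = Path(path)
    if isinstance(obj, KinematicSeries):
        df = pd.DataFrame({"t": obj.times, "v": obj.v, "heading": obj.heading,
                           "omega": obj.omega, "domega_dt": obj.domega_dt})
        df.to_csv(path, index=False, float_format="%.12g")
        return path
    if isinstance(obj, StateSequence):
        cols = {"t": obj.times, "S": obj.S}
        if obj.boundary is not None:
            cols["boundary_flag"] = obj.boundary.astype(int)
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
        return path
    if isinstance(obj, MotilityNetwork):
        doc = {
            "kind": "MotilityNetwork",
            "p": _serialize_array(obj.p),
            "P_trans": _serialize_array(obj.P_trans),
            "Q": _serialize_array(obj.Q),
            "n_trans": np.asarray(obj.n_trans, dtype=int).tolist(),
            "mean_residence": _serialize_array(obj.mean_residence),
            "sojourns": [list(map(float, s)) for s in obj.sojourns],
            "total_time": float(obj.total_time),
        }
        path.write_text(json.dumps(doc, indent=1))
        return path
    if isinstance(obj, FluxField):
        doc = {
            "kind": "FluxField",
            "edges": _serialize_array(obj.edges),
            "occupancy": _serialize_array(obj.occupancy),
            "flux_x": _serialize_array(obj.flux[..., 0]),
            "flux_y": _serialize_array(obj.flux[..., 1]),
            "trap_radius": float(obj.trap_radius),
            "total_time": float(obj.total_time),
        }
        path.write_text(json.dumps(doc, indent=1))
        return path
    raise TypeError(f"cannot serialize object of type {type(obj).__name__}")


def read_product(path):
    """Read back a JSON product written by :func:`write_products`."""
    from .network import MotilityNetwork
    from .spatial import FluxField

    doc = json.loads(Path(path).read_text())
    kind = doc.get("kind")
    if kind == "MotilityNetwork":
        return MotilityNetwork(
            p=np.array(doc["p"]),
            sojourns=[np.array(s, dtype=float) for s in doc["sojourns"]],
            mean_residence=np.array(doc["mean_residence"]),
            P_trans=np.array(doc["P_trans"]),
            Q=np.array(doc["Q"]),
            n_trans=np.array(doc["n_trans"], dtype=int),
            total_time=doc["total_time"],
        )
    if kind == "FluxField":
        flux = np.stack([np.array(doc["flux_x"]), np.array(doc["flux_y"])],
                        axis=-1)
        return FluxField(edges=np.array(doc["edges"]),
                         occupancy=np.array(doc["occupancy"]),
                         flux=flux, trap_radius=doc["trap_radius"],
                         total_time=doc["total_time"])
    raise FormatError(f"{path}: unknown product kind {kind!r}")
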