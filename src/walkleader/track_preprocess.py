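"""Reading, projecting, smoothing and differentiating raw GPS tracks.

Raw fixes (5 Hz GPS positions of several individuals walking together) are
assembled into a :class:`Walk`: all tracks resampled onto one uniform 0.2 s
grid in local planar metres.  Positions are then smoothed with a truncated
Gaussian kernel and differentiated to obtain velocities, speeds and unit
heading vectors.  Headings are only defined while an individual is actually
moving (speed >= ``v_min``); at GPS-noise speeds the direction of the
velocity vector is meaningless.

Conventions: x east, y north, metres; time in seconds from walk start on a
closed-open uniform grid.
"""

from __future__ import annotations

import json
import math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_M",
    "PreprocessConfig",
    "Walk",
    "HeadingSeries",
    "TrackFormatError",
    "load_tracks",
    "assemble_walk",
    "smooth_positions",
    "derive_motion",
    "gaussian_smooth_series",
]

#: WGS84 equatorial radius, used by the equirectangular projection.
EARTH_RADIUS_M = 6378137.0

_CSV_XY = ["walk_id", "individual_id", "role", "time_s", "x_m", "y_m"]
_CSV_LL = ["walk_id", "individual_id", "role", "timestamp", "lat", "lon"]
_ROLES = {"dog", "owner"}


class TrackFormatError(ValueError):
    """Raised when an input track file does not match a known dialect."""


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    smooth_sd : s
        Standard deviation of the Gaussian position-smoothing kernel.
    v_min : m/s
        Minimum speed for a heading to be considered defined.
    max_gap : s
        Longest gap filled by linear interpolation without a warning.
    grid_dt : s
        Step of the common resampling grid.
    projection_origin : (lat, lon) or None
        Reference point of the planar projection; walk centroid if None.
    """

    smooth_sd: float = 1.0
    v_min: float = 0.5
    max_gap: float = 2.0
    grid_dt: float = 0.2
    projection_origin: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.smooth_sd < 0:
            raise ValueError("smooth_sd must be >= 0")
        if self.v_min <= 0:
            raise ValueError("v_min must be > 0")
        if self.grid_dt <= 0:
            raise ValueError("grid_dt must be > 0")


@dataclass
class Walk:
    """One session: synchronized per-individual tracks on a uniform grid."""

    walk_id: str
    t: np.ndarray  # (n,) seconds from walk start, uniform
    positions: dict[str, np.ndarray]  # id -> (n, 2) [x east, y north] metres
    roles: dict[str, str]  # id -> "dog" | "owner"
    long_gaps: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) + self.dt

    @property
    def individuals(self) -> list[str]:
        return list(self.positions)

    @property
    def owner_id(self) -> str:
        return next(i for i, r in self.roles.items() if r == "owner")

    @property
    def dog_ids(self) -> list[str]:
        return [i for i, r in self.roles.items() if r == "dog"]

    def validate(self) -> None:
        steps = np.diff(self.t)
        if len(self.t) < 2 or not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("walk grid must be uniform with >= 2 samples")
        owners = [i for i, r in self.roles.items() if r == "owner"]
        if len(owners) != 1:
            raise ValueError(f"walk must have exactly one owner, found {len(owners)}")
        for ind, pos in self.positions.items():
            if pos.shape != (len(self.t), 2):
                raise ValueError(f"track of {ind!r} not aligned to the grid")
            if not np.all(np.isfinite(pos)):
                raise ValueError(f"track of {ind!r} contains non-finite positions")

    def to_frame(self) -> pd.DataFrame:
        """Long-format track table in the package's CSV dialect."""
        rows = []
        for ind, pos in self.positions.items():
            rows.append(
                pd.DataFrame(
                    {
                        "walk_id": self.walk_id,
                        "individual_id": ind,
                        "role": self.roles[ind],
                        "time_s": self.t,
                        "x_m": pos[:, 0],
                        "y_m": pos[:, 1],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class HeadingSeries:
    """Velocity, speed and unit heading of one individual on the walk grid."""

    velocity: np.ndarray  # (n, 2) m/s
    speed: np.ndarray  # (n,) m/s
    heading: np.ndarray  # (n, 2) unit vectors, NaN where not moving
    moving: np.ndarray  # (n,) bool, speed >= v_min


def load_tracks(path: str | Path, dialect: str = "csv",
                sidecar: str | Path | None = None) -> pd.DataFrame:
    """Read raw fixes into a tidy table, one row per fix.

    Returns a DataFrame with columns ``walk_id, individual_id, role`` plus
    either ``time_s, x_m, y_m`` or ``time_s, lat, lon`` (timestamps are
    converted to seconds from the first fix of the walk).  Fixes are sorted
    by time within each individual; malformed rows are dropped with a
    warning naming their line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        fixes = _load_csv(path)
    elif dialect == "gpx":
        fixes = _load_gpx(path, sidecar)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    fixes = fixes.sort_values(["walk_id", "individual_id", "time_s"], kind="stable")
    fixes = fixes.reset_index(drop=True)
    for (wid, ind), grp in fixes.groupby(["walk_id", "individual_id"]):
        tv = grp["time_s"].to_numpy()
        dts = np.diff(tv)
        if np.any(dts == 0):
            raise ValueError(
                f"duplicated timestamp in walk {wid!r}, individual {ind!r}, "
                f"t = {tv[1:][dts == 0][0]}"
            )
        if np.any(dts < 0):
            raise ValueError(
                f"non-monotone time for individual {ind!r} in walk {wid!r} "
                f"at t = {tv[1:][dts < 0][0]}"
            )
    return fixes


def _load_csv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    cols = set(df.columns)
    if set(_CSV_XY) <= cols:
        use, value_cols = _CSV_XY, ["time_s", "x_m", "y_m"]
    elif set(_CSV_LL) <= cols:
        use, value_cols = _CSV_LL, ["lat", "lon"]
    else:
        raise TrackFormatError(
            f"unknown columns {sorted(cols)}; expected {_CSV_XY} or {_CSV_LL}"
        )
    if set(_CSV_XY[3:]) <= cols and set(_CSV_LL[3:]) <= cols:
        raise TrackFormatError("mixed coordinate conventions in one file")
    df = df[use].copy()
    if "timestamp" in df.columns:
        ts = pd.to_datetime(df.pop("timestamp"), errors="coerce", format="ISO8601")
        df["time_s"] = (ts - ts.min()).dt.total_seconds()
    df[value_cols] = df[value_cols].apply(pd.to_numeric, errors="coerce")
    bad = df[value_cols + ["time_s"]].isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # header is line 1
        warnings.warn(f"dropped {bad.sum()} malformed rows at lines {lines}")
        df = df[~bad]
    bad_role = ~df["role"].isin(_ROLES)
    if bad_role.any():
        raise TrackFormatError(f"unknown roles {sorted(df['role'][bad_role].unique())}")
    return df


def _load_gpx(path: Path, sidecar: str | Path | None) -> pd.DataFrame:
    """GPX 1.1: one <trk> per individual, identity from a JSON sidecar."""
    if sidecar is None:
        raise TrackFormatError("GPX input requires a sidecar mapping file")
    mapping = json.loads(Path(sidecar).read_text())
    ns = {"g": "http://www.topografix.com/GPX/1/1"}
    root = ET.parse(path).getroot()
    rows = []
    for trk in root.findall("g:trk", ns):
        name_el = trk.find("g:name", ns)
        name = name_el.text.strip() if name_el is not None and name_el.text else ""
        if name not in mapping:
            raise TrackFormatError(f"GPX track {name!r} missing from sidecar mapping")
        meta = mapping[name]
        for pt in trk.iter(f"{{{ns['g']}}}trkpt"):
            time_el = pt.find("g:time", ns)
            rows.append(
                {
                    "walk_id": mapping.get("_walk_id", path.stem),
                    "individual_id": meta["individual_id"],
                    "role": meta["role"],
                    "timestamp": time_el.text if time_el is not None else None,
                    "lat": float(pt.attrib["lat"]),
                    "lon": float(pt.attrib["lon"]),
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        raise TrackFormatError(f"no track points in {path}")
    ts = pd.to_datetime(df.pop("timestamp"))
    df["time_s"] = (ts - ts.min()).dt.total_seconds()
    return df


def project_equirectangular(lat: np.ndarray, lon: np.ndarray,
                            origin: tuple[float, float]) -> np.ndarray:
    """(lat, lon) degrees -> (x east, y north) metres about ``origin``.

    Over a ~1 km field the curvature error of this projection is far below
    GPS noise.
    """
    lat0, lon0 = origin
    x = EARTH_RADIUS_M * math.cos(math.radians(lat0)) * np.radians(lon - lon0)
    y = EARTH_RADIUS_M * np.radians(lat - lat0)
    return np.column_stack([x, y])


def assemble_walk(fixes: pd.DataFrame, cfg: PreprocessConfig = PreprocessConfig()) -> Walk:
    """Project, align and resample one walk's fixes onto the common grid.

    Gaps longer than ``cfg.max_gap`` are still filled linearly but are
    recorded in ``Walk.long_gaps`` and flagged with a warning rather than
    passed off silently.
    """
    wids = fixes["walk_id"].unique()
    if len(wids) != 1:
        raise ValueError(f"fixes span several walks: {wids.tolist()}")
    wid = str(wids[0])

    fixes = fixes.copy()
    if {"lat", "lon"} <= set(fixes.columns):
        origin = cfg.projection_origin or (
            float(fixes["lat"].mean()), float(fixes["lon"].mean()))
        xy = project_equirectangular(
            fixes["lat"].to_numpy(float), fixes["lon"].to_numpy(float), origin)
        fixes["x_m"], fixes["y_m"] = xy[:, 0], xy[:, 1]

    roles = {}
    spans = {}
    groups = {}
    for ind, grp in fixes.groupby("individual_id"):
        ind = str(ind)
        t = grp["time_s"].to_numpy(float)
        if np.any(np.diff(t) == 0):
            tdup = t[1:][np.diff(t) == 0][0]
            raise ValueError(
                f"duplicated timestamp in walk {wid!r}, individual {ind!r}, "
                f"t = {tdup}")
        roles[ind] = str(grp["role"].iloc[0])
        spans[ind] = (t[0], t[-1])
        groups[ind] = (t, grp[["x_m", "y_m"]].to_numpy(float))

    if "owner" not in roles.values():
        raise ValueError("no owner among the individuals of this walk")

    t_lo = max(s[0] for s in spans.values())
    t_hi = min(s[1] for s in spans.values())
    full_lo = min(s[0] for s in spans.values())
    full_hi = max(s[1] for s in spans.values())
    if full_hi > full_lo and (t_hi - t_lo) < 0.5 * (full_hi - full_lo):
        raise ValueError("individuals' time spans overlap by less than 50% of the walk")

    dt = cfg.grid_dt
    grid = np.arange(math.ceil(t_lo / dt), math.floor(t_hi / dt) + 1) * dt
    grid = grid - grid[0]  # seconds from walk start
    abs_grid = grid + math.ceil(t_lo / dt) * dt

    positions = {}
    long_gaps: dict[str, list[tuple[float, float]]] = {}
    for ind, (t, xy) in groups.items():
        x = np.interp(abs_grid, t, xy[:, 0])
        y = np.interp(abs_grid, t, xy[:, 1])
        positions[ind] = np.column_stack([x, y])
        gaps = [
            (float(t[k] - abs_grid[0]), float(t[k + 1] - abs_grid[0]))
            for k in np.flatnonzero(np.diff(t) > cfg.max_gap)
        ]
        if gaps:
            long_gaps[ind] = gaps
            warnings.warn(
                f"walk {wid!r}, individual {ind!r}: {len(gaps)} gap(s) longer "
                f"than {cfg.max_gap} s interpolated and flagged")

    walk = Walk(wid, grid, positions, roles, long_gaps)
    walk.validate()
    return walk


def _truncated_gaussian_kernel(sd_samples: float) -> np.ndarray:
    half = int(math.ceil(3 * sd_samples))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sd_samples) ** 2)
    return k / k.sum()


def gaussian_smooth_series(x: np.ndarray, sd_samples: float) -> np.ndarray:
    """Convolve with a +-3 sd truncated Gaussian, renormalized at the edges."""
    if sd_samples <= 0:
        return np.asarray(x, float).copy()
    k = _truncated_gaussian_kernel(sd_samples)
    num = np.convolve(x, k, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), k, mode="same")
    return num / den


def smooth_positions(walk: Walk, cfg: PreprocessConfig = PreprocessConfig()) -> Walk:
    """Gaussian-smooth each coordinate series; the grid is unchanged."""
    if cfg.smooth_sd == 0:
        return walk
    sd_samples = cfg.smooth_sd / walk.dt
    positions = {
        ind: np.column_stack(
            [gaussian_smooth_series(pos[:, 0], sd_samples),
             gaussian_smooth_series(pos[:, 1], sd_samples)]
        )
        for ind, pos in walk.positions.items()
    }
    return Walk(walk.walk_id, walk.t, positions, dict(walk.roles), dict(walk.long_gaps))


def derive_motion(walk: Walk, cfg: PreprocessConfig = PreprocessConfig()
                  ) -> dict[str, HeadingSeries]:
    """Velocities by central differences; headings where speed >= v_min."""
    if walk.n_samples < 3:
        raise ValueError("track shorter than 3 samples")
    out = {}
    for ind, pos in walk.positions.items():
        vel = np.gradient(pos, walk.dt, axis=0)
        speed = np.linalg.norm(vel, axis=1)
        moving = speed >= cfg.v_min
        heading = np.full_like(vel, np.nan)
        heading[moving] = vel[moving] / speed[moving, None]
        out[ind] = HeadingSeries(vel, speed, heading, moving)
    return out
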