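"""Fixes, trajectories, and dyad alignment for paired-follow telemetry.

Coordinates are planar meters on a local study grid (no geodesy). Times are
seconds (float) on an arbitrary but shared epoch; the CSV interface speaks
ISO-8601. A :class:`Trajectory` is the fix stream of one individual for one
night (or pooled across nights); a :class:`DyadSeries` holds the time-aligned
simultaneous fixes of a male-female pair followed by two observers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Fix",
    "Trajectory",
    "DyadSeries",
    "subsample",
    "align_dyad",
    "path_length",
    "pool_nights",
    "read_trajectories_csv",
    "write_trajectories_csv",
    "DEFAULT_ALIGN_TOL_S",
]

log = logging.getLogger(__name__)

#: Default tolerance (s) for matching "simultaneous" fixes of the two
#: observers: half of the 5-min analysis grid.
DEFAULT_ALIGN_TOL_S = 150.0

TRAJECTORY_COLUMNS = ["individual_id", "sex", "night_id", "timestamp", "x", "y", "in_sight"]


@dataclass(frozen=True)
class Fix:
    """One time-stamped planar location of one individual."""

    individual_id: str
    t: float
    x: float
    y: float
    in_sight: bool = True


@dataclass
class Trajectory:
    """Ordered fix series of a single individual.

    Parameters
    ----------
    t, x, y
        Equal-length arrays; ``t`` in seconds, strictly increasing;
        coordinates in meters and finite.
    in_sight
        Boolean per-fix visibility flag; defaults to all-True when absent
        from input data.
    night_id
        Identifier of the focal-follow night, or ``"pooled"`` for data
        merged across nights.
    """

    individual_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sex: str = "?"
    night_id: str = "pooled"
    in_sight: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.t.size
        if self.x.size != n or self.y.size != n:
            raise ValueError("t, x, y must have equal length")
        if self.in_sight is None:
            self.in_sight = np.ones(n, dtype=bool)
        else:
            self.in_sight = np.asarray(self.in_sight, dtype=bool)
            if self.in_sight.size != n:
                raise ValueError("in_sight must match fix count")
        if n:
            if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()
                    and np.isfinite(self.t).all()):
                raise ValueError(f"{self.individual_id}: non-finite fix values")
            if np.any(np.diff(self.t) <= 0):
                raise ValueError(f"{self.individual_id}: timestamps not strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @property
    def n_fixes(self) -> int:
        return self.t.size

    @property
    def xy(self) -> np.ndarray:
        """Fix coordinates as an (n, 2) array."""
        return np.column_stack([self.x, self.y])

    def fixes(self) -> list[Fix]:
        return [
            Fix(self.individual_id, float(t), float(x), float(y), bool(s))
            for t, x, y, s in zip(self.t, self.x, self.y, self.in_sight)
        ]


@dataclass
class DyadSeries:
    """Time-aligned simultaneous fix pairs for one male-female dyad."""

    male_id: str
    female_id: str
    t: np.ndarray
    male_xy: np.ndarray    # (n, 2)
    female_xy: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.male_xy = np.asarray(self.male_xy, dtype=float).reshape(-1, 2)
        self.female_xy = np.asarray(self.female_xy, dtype=float).reshape(-1, 2)
        if not (self.t.size == len(self.male_xy) == len(self.female_xy)):
            raise ValueError("misaligned dyad arrays")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("dyad times not strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    def distances(self) -> np.ndarray:
        """Euclidean inter-partner distance (m) at each aligned time point."""
        return np.hypot(*(self.male_xy - self.female_xy).T)

    @staticmethod
    def concat(parts: list["DyadSeries"]) -> "DyadSeries":
        """Concatenate per-night series (in chronological order) into one."""
        if not parts:
            raise ValueError("nothing to concatenate")
        parts = sorted(parts, key=lambda s: s.t[0] if len(s) else np.inf)
        return DyadSeries(
            parts[0].male_id,
            parts[0].female_id,
            np.concatenate([p.t for p in parts]),
            np.vstack([p.male_xy for p in parts]),
            np.vstack([p.female_xy for p in parts]),
        )


def subsample(traj: Trajectory, interval: float) -> Trajectory:
    """Thin a trajectory to fixes spaced at least ``interval`` seconds apart.

    Greedy forward scan: the first fix is always kept, and a subsequent fix
    is kept iff its time is >= ``interval`` after the last kept fix.
    Idempotent. An empty trajectory passes through unchanged.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    n = len(traj)
    if n == 0:
        return traj
    keep = np.zeros(n, dtype=bool)
    keep[0] = True
    last = traj.t[0]
    for i in range(1, n):
        if traj.t[i] - last >= interval:
            keep[i] = True
            last = traj.t[i]
    return replace(
        traj, t=traj.t[keep], x=traj.x[keep], y=traj.y[keep], in_sight=traj.in_sight[keep]
    )


def align_dyad(a: Trajectory, b: Trajectory, tol: float = DEFAULT_ALIGN_TOL_S) -> DyadSeries:
    """Pair each fix of ``a`` with the nearest-in-time unused fix of ``b``.

    Fixes are scanned in time order; a fix of ``a`` is retained iff some
    not-yet-used fix of ``b`` lies within ``tol`` seconds, and the nearest
    such fix is chosen (earlier fix wins ties). Each ``b`` fix is used at
    most once, so the output length is at most ``min(len(a), len(b))``.

    By convention ``a`` is the male and ``b`` the female; the roles only
    label the output columns.
    """
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    ts, mxy, fxy = [], [], []
    j = 0
    nb = len(b)
    for i in range(len(a)):
        ta = a.t[i]
        # advance past b fixes that are no longer the nearest candidate
        while j + 1 < nb and abs(b.t[j + 1] - ta) < abs(b.t[j] - ta):
            j += 1
        if j < nb and abs(b.t[j] - ta) <= tol:
            ts.append(ta)
            mxy.append((a.x[i], a.y[i]))
            fxy.append((b.x[j], b.y[j]))
            j += 1
        if j >= nb:
            break
    return DyadSeries(
        a.individual_id,
        b.individual_id,
        np.asarray(ts, dtype=float),
        np.asarray(mxy, dtype=float).reshape(-1, 2),
        np.asarray(fxy, dtype=float).reshape(-1, 2),
    )


def path_length(traj: Trajectory) -> float:
    """Total Euclidean path length (m) of the fix sequence; 0 for one fix."""
    if len(traj) == 0:
        raise ValueError("path_length of an empty trajectory")
    return float(np.hypot(np.diff(traj.x), np.diff(traj.y)).sum())


def pool_nights(trajectories: list[Trajectory]) -> Trajectory:
    """Merge the per-night trajectories of one individual into a pooled one."""
    if not trajectories:
        raise ValueError("no trajectories to pool")
    ind = trajectories[0].individual_id
    if any(tr.individual_id != ind for tr in trajectories):
        raise ValueError("pooling requires a single individual")
    parts = sorted(trajectories, key=lambda tr: tr.t[0] if len(tr) else np.inf)
    return Trajectory(
        ind,
        np.concatenate([tr.t for tr in parts]),
        np.concatenate([tr.x for tr in parts]),
        np.concatenate([tr.y for tr in parts]),
        sex=parts[0].sex,
        night_id="pooled",
        in_sight=np.concatenate([tr.in_sight for tr in parts]),
    )


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

def read_trajectories_csv(path) -> list[Trajectory]:
    """Read trajectories from the standard CSV layout.

    Required columns: ``individual_id, sex, night_id, timestamp, x, y``.
    ``in_sight`` is optional and defaults to True. Rows with unparseable
    timestamps or non-finite coordinates are rejected with a logged warning
    naming their (1-based, header-inclusive) line numbers.
    """
    df = pd.read_csv(path)
    required = ["individual_id", "sex", "night_id", "timestamp", "x", "y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    xy_ok = np.isfinite(pd.to_numeric(df["x"], errors="coerce")) & np.isfinite(
        pd.to_numeric(df["y"], errors="coerce")
    )
    bad = ts.isna() | ~xy_ok
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        log.warning("rejected %d malformed row(s) at line(s) %s", bad.sum(), lines)
        df = df[~bad]
    if "in_sight" not in df.columns:
        df = df.assign(in_sight=True)
    df = df.assign(_t=ts[~bad] if bad.any() else ts)
    out: list[Trajectory] = []
    for (ind, night), grp in df.groupby(["individual_id", "night_id"], sort=True):
        grp = grp.sort_values("_t")
        out.append(
            Trajectory(
                str(ind),
                grp["_t"].astype("int64").to_numpy() / 1e9,
                grp["x"].to_numpy(dtype=float),
                grp["y"].to_numpy(dtype=float),
                sex=str(grp["sex"].iloc[0]),
                night_id=str(night),
                in_sight=grp["in_sight"].astype(bool).to_numpy(),
            )
        )
    return out


def write_trajectories_csv(trajectories: list[Trajectory], path) -> None:
    frames = []
    for tr in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": tr.individual_id,
                    "sex": tr.sex,
                    "night_id": tr.night_id,
                    "timestamp": pd.to_datetime((tr.t * 1e9).astype("int64")).strftime(
                        "%Y-%m-%dT%H:%M:%S"
                    ),
                    "x": np.round(tr.x, 3),
                    "y": np.round(tr.y, 3),
                    "in_sight": tr.in_sight,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
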