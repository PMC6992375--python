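"""Gliding-cell velocimetry: path length, mean velocity and strain comparison.

Centroids come from simulator ground truth or a manually clicked CSV
(automated rod tracking is out of scope — blob detectors handle fringed
rod shapes poorly). A track's mean velocity is its along-path displacement
divided by elapsed time (μm/min); tracks are screened for approximately
linear trajectories before strain groups are compared with a Welch
unequal-variance two-sample test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Track",
    "VelocityStats",
    "mean_velocity",
    "path_length",
    "linearity_filter",
    "compare_strains",
    "tracks_from_frame",
    "read_tracks_csv",
    "write_tracks_csv",
]

logger = logging.getLogger(__name__)


@dataclass
class Track:
    """Time-stamped centroid positions of one cell."""

    cell_id: int
    times: np.ndarray        # s, strictly increasing
    x: np.ndarray            # μm
    y: np.ndarray            # μm
    strain: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times, x and y must have equal length")
        if len(self.times) < 2:
            raise ValueError("a track needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def path_length(track: Track) -> float:
    """Sum of consecutive Euclidean segment lengths (μm) — the along-path
    distance, which is >= the end-to-end displacement."""
    return float(np.sum(np.hypot(np.diff(track.x), np.diff(track.y))))


def mean_velocity(track: Track) -> float:
    """Along-path displacement over elapsed time, in μm/min."""
    elapsed = track.times[-1] - track.times[0]
    if elapsed <= 0:
        raise ValueError("track has zero elapsed time")
    return path_length(track) / elapsed * 60.0


def linearity_filter(track: Track, r2_min: float = 0.9) -> bool:
    """True iff the trajectory is approximately linear.

    Linearity is the fraction of positional variance explained by the
    best-fit (total-least-squares) line through the centroids — the leading
    eigenvalue share of the 2x2 position covariance. Collinear points score
    exactly 1. Requires >= 3 points.
    """
    if len(track) < 3:
        raise ValueError("linearity requires at least 3 points")
    pts = np.stack([track.x, track.y], axis=1)
    cov = np.cov(pts.T)
    eig = np.sort(np.linalg.eigvalsh(cov))
    total = eig.sum()
    if total == 0:
        return False  # stationary cluster: no direction at all
    return bool(eig[-1] / total >= r2_min)


@dataclass
class VelocityStats:
    """Two-group velocity comparison summary (units μm/min)."""

    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    percent_decrease: float     # 100 (mean_a - mean_b) / mean_a
    p_value: float              # Welch two-sided
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean_a_um_per_min": self.mean_a, "sem_a": self.sem_a, "n_a": self.n_a,
            "mean_b_um_per_min": self.mean_b, "sem_b": self.sem_b, "n_b": self.n_b,
            "percent_decrease": self.percent_decrease, "p_value": self.p_value,
            "flags": self.flags,
        }


def _group_stats(velocities: np.ndarray) -> tuple[float, float]:
    mean = float(velocities.mean())
    if len(velocities) < 2:
        return mean, float("nan")
    return mean, float(velocities.std(ddof=1) / np.sqrt(len(velocities)))


def compare_strains(a: list, b: list, r2_min: float = 0.9,
                    apply_linearity: bool = True) -> VelocityStats:
    """Compare mean gliding velocities of two strain groups.

    Tracks failing the linearity screen are dropped (with a log message);
    percent decrease is 100·(mean_a − mean_b)/mean_a and the p-value comes
    from a two-sided Welch unequal-variance comparison. Single-track groups
    get an undefined (NaN) SEM and a flag.
    """
    if not a or not b:
        raise ValueError("both groups must be nonempty")
    if apply_linearity:
        kept_a = [t for t in a if len(t) < 3 or linearity_filter(t, r2_min)]
        kept_b = [t for t in b if len(t) < 3 or linearity_filter(t, r2_min)]
        if len(kept_a) < len(a) or len(kept_b) < len(b):
            logger.info("linearity screen dropped %d/%d and %d/%d tracks",
                        len(a) - len(kept_a), len(a), len(b) - len(kept_b), len(b))
        a, b = kept_a, kept_b
        if not a or not b:
            raise ValueError("linearity screen removed an entire group")
    va = np.array([mean_velocity(t) for t in a])
    vb = np.array([mean_velocity(t) for t in b])
    mean_a, sem_a = _group_stats(va)
    mean_b, sem_b = _group_stats(vb)
    flags = []
    if len(va) < 2 or len(vb) < 2:
        flags.append("group of size 1: SEM and p-value undefined")
        p = float("nan")
    else:
        p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
    if mean_a == 0:
        raise ValueError("reference group has zero mean velocity")
    decrease = 100.0 * (mean_a - mean_b) / mean_a
    return VelocityStats(mean_a, sem_a, len(va), mean_b, sem_b, len(vb), decrease, p, flags)


# ---------------------------------------------------------------------------
# CSV plumbing: frame, time_s, cell_id, x_um, y_um, strain
# ---------------------------------------------------------------------------

def tracks_from_frame(df: pd.DataFrame, strain_col: str | None = "strain") -> list:
    """Assemble Track objects from a long-format centroid table."""
    required = {"time_s", "cell_id", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"centroid table missing columns {sorted(missing)}")
    tracks = []
    for cid, grp in df.sort_values("time_s").groupby("cell_id"):
        strain = None
        if strain_col and strain_col in df.columns:
            strain = str(grp[strain_col].iloc[0])
        tracks.append(Track(int(cid), grp["time_s"].to_numpy(),
                            grp["x_um"].to_numpy(), grp["y_um"].to_numpy(), strain))
    return tracks


def read_tracks_csv(path: str) -> list:
    return tracks_from_frame(pd.read_csv(path))


def write_tracks_csv(tracks: list, path: str) -> None:
    rows = []
    for t in tracks:
        for i in range(len(t)):
            rows.append({"frame": i, "time_s": t.times[i], "cell_id": t.cell_id,
                         "x_um": t.x[i], "y_um": t.y[i], "strain": t.strain or ""})
    pd.DataFrame(rows).to_csv(path, index=False)
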