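"""Single-cell migration statistics.

Velocity is the mean of per-interval speeds (displacement over interval
duration for each consecutive frame pair), reported in µm/min.  The
directionality ratio d/D compares the straight-line start-to-end distance
``d`` with the total path length ``D``; 1 means perfectly straight migration.
Mean squared displacement (MSD) is time-averaged over all overlapping frame
pairs at each lag.  For wound-directed migration, tracks are rigidly
transformed so every cell starts at the origin and the wound direction is the
positive x axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from fadyn.errors import InvalidParameterError

__all__ = [
    "Track",
    "MotilityMetrics",
    "mean_velocity",
    "path_velocity",
    "directionality_ratio",
    "msd",
    "cohort_msd",
    "align_tracks",
    "compute_metrics",
]


@dataclass(frozen=True)
class Track:
    """A cell's (t, x, y) path, positions in µm."""

    cell_id: str
    frame_times: np.ndarray  # s, strictly increasing
    positions: np.ndarray  # (n, 2) µm

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_times, dtype=float)
        p = np.asarray(self.positions, dtype=float)
        if t.ndim != 1 or p.shape != (t.size, 2):
            raise InvalidParameterError("positions must be (n_frames, 2) matching frame_times")
        if t.size < 2:
            raise InvalidParameterError("a track needs >= 2 frames")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("frame_times must be strictly increasing (no duplicate timestamps)")
        object.__setattr__(self, "frame_times", t)
        object.__setattr__(self, "positions", p)


@dataclass(frozen=True)
class MotilityMetrics:
    """Per-cell summary statistics."""

    cell_id: str
    mean_velocity_um_min: float  # mean of per-interval speeds
    path_velocity_um_min: float  # total path length / total time (auxiliary)
    d_um: float  # straight-line start-to-end distance
    D_um: float  # total path length
    directionality_ratio: float  # d/D, NaN when D == 0
    msd_um2: dict[float, float]  # lag (s) -> mean squared displacement


def _segment_lengths(track: Track) -> np.ndarray:
    return np.linalg.norm(np.diff(track.positions, axis=0), axis=1)


def mean_velocity(track: Track) -> float:
    """Mean of per-interval velocities, µm/min.

    Each consecutive frame pair contributes Euclidean displacement / Δt; the
    final velocity is the average of these per-timepoint velocities.
    """
    seg = _segment_lengths(track)
    dt = np.diff(track.frame_times)
    return float(np.mean(seg / dt) * 60.0)


def path_velocity(track: Track) -> float:
    """Total path length over total elapsed time, µm/min (auxiliary summary)."""
    total = float(_segment_lengths(track).sum())
    elapsed = float(track.frame_times[-1] - track.frame_times[0])
    return total / elapsed * 60.0


def directionality_ratio(track: Track) -> tuple[float, float, float]:
    """Return (d, D, d/D).

    ``d`` is the straight-line distance between start and end points; ``D``
    is the total distance migrated.  A track that never moves (D == 0) has an
    undefined ratio, reported as NaN with a warning.
    """
    d = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    big_d = float(_segment_lengths(track).sum())
    if big_d == 0.0:
        warnings.warn(f"track {track.cell_id}: no movement, directionality ratio undefined", stacklevel=2)
        return d, big_d, float("nan")
    return d, big_d, d / big_d


def msd(track: Track, max_lag_frames: int, dt_rtol: float = 1e-6) -> dict[float, float]:
    """Time-averaged MSD per lag, µm².

    For lag ``k`` frames the MSD is the mean over all overlapping pairs
    (i, i+k) of the squared displacement.  Requires uniform frame intervals
    (within ``dt_rtol`` relative tolerance); non-uniformly sampled tracks must
    be resampled first.  The lag-0 entry is included and is exactly 0.
    """
    dt = np.diff(track.frame_times)
    dt0 = float(dt[0])
    if np.any(np.abs(dt - dt0) > dt_rtol * dt0):
        raise InvalidParameterError(
            "non-uniform frame interval; resample the track onto a uniform grid before MSD"
        )
    n = track.frame_times.size
    if not 0 < max_lag_frames < n:
        raise InvalidParameterError("max_lag_frames must be in [1, n_frames)")
    out: dict[float, float] = {0.0: 0.0}
    p = track.positions
    for k in range(1, max_lag_frames + 1):
        disp = p[k:] - p[:-k]
        out[k * dt0] = float(np.mean(np.sum(disp**2, axis=1)))
    return out


def cohort_msd(tracks: list[Track], max_lag_frames: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Average per-track MSD across cells; returns (lags_s, mean, sd, n).

    Per-track MSDs are computed first (time average), then averaged across
    tracks at each lag with the population SD.
    """
    if not tracks:
        raise InvalidParameterError("cohort_msd requires at least one track")
    per_track = [msd(tr, max_lag_frames) for tr in tracks]
    lags = np.array(sorted(per_track[0]))
    for m in per_track[1:]:
        if sorted(m) != list(lags):
            raise InvalidParameterError("tracks have differing frame intervals; cannot pool MSD")
    mat = np.array([[m[lag] for lag in lags] for m in per_track])
    return lags, mat.mean(axis=0), mat.std(axis=0, ddof=0), len(tracks)


def align_tracks(tracks: list[Track], wound_point: tuple[float, float]) -> list[Track]:
    """Translate each track to start at (0,0) and rotate so the start-to-wound
    direction is the +x axis.

    The transform is rigid (proper rotation + translation): all pairwise
    inter-frame distances are preserved.  The wound point must be distinct
    from every track's starting position.
    """
    wound = np.asarray(wound_point, dtype=float)
    out = []
    for tr in tracks:
        start = tr.positions[0]
        u = wound - start
        norm = float(np.linalg.norm(u))
        if norm == 0.0:
            raise InvalidParameterError(f"track {tr.cell_id}: wound point coincides with start position")
        c, s = u / norm
        rot = np.array([[c, s], [-s, c]])  # maps u/|u| -> (1, 0)
        out.append(
            Track(
                cell_id=tr.cell_id,
                frame_times=tr.frame_times.copy(),
                positions=(tr.positions - start) @ rot.T,
            )
        )
    return out


def compute_metrics(track: Track, max_lag_frames: int | None = None) -> MotilityMetrics:
    """All per-cell metrics in one record.

    ``max_lag_frames`` defaults to half the track length (a common MSD cutoff
    to limit estimator variance at long lags).
    """
    if max_lag_frames is None:
        max_lag_frames = max(1, track.frame_times.size // 2)
    d, big_d, ratio = directionality_ratio(track)
    return MotilityMetrics(
        cell_id=track.cell_id,
        mean_velocity_um_min=mean_velocity(track),
        path_velocity_um_min=path_velocity(track),
        d_um=d,
        D_um=big_d,
        directionality_ratio=ratio,
        msd_um2=msd(track, max_lag_frames),
    )
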