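"""FRAP normalization and exponential-recovery fitting.

A FRAP experiment bleaches a fluorescent structure (here, a Paxillin-positive
focal adhesion) and records the return of fluorescence as unbleached molecules
exchange in from the cytosol.  Raw ROI intensities are converted to relative
fluorescence intensity (RFI),

    RFI_t = (I_t - I_bgt) / (I_pre - I_bgpre),

where ``I_t`` is the mean bleached-ROI intensity at time ``t``, ``I_bgt`` the
mean background intensity at ``t``, and ``I_pre`` / ``I_bgpre`` the means of
the same quantities over the prebleach frames.  The recovery curve is then fit
with a single-exponential model

    RFI(t) = floor + (plateau - floor) * (1 - exp(-k t)),

whose rate constant gives the half-time ``t_half = ln 2 / k`` and whose
plateau gives the mobile fraction ``(plateau - floor) / (1 - floor)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from fadyn.errors import DegenerateTraceError, InvalidParameterError

__all__ = [
    "FrapTrace",
    "RecoveryCurve",
    "RecoveryFit",
    "CohortCurve",
    "normalize_frap",
    "fit_recovery",
    "aggregate_recovery",
]

#: k below which a recovery is treated as unidentifiable (no resolvable rise).
_K_LOWER = 1e-6
#: upper bound on the recovery rate constant, 1/s.
_K_UPPER = 10.0


@dataclass(frozen=True)
class FrapTrace:
    """Raw ROI and background intensities around a single bleach event.

    Frames ``0 .. n_prebleach-1`` are prebleach; frame ``n_prebleach`` is the
    first postbleach frame.
    """

    frame_times: np.ndarray  # s, strictly increasing
    roi_intensity: np.ndarray  # a.u.
    background_intensity: np.ndarray  # a.u.
    n_prebleach: int

    def __post_init__(self) -> None:
        t = np.asarray(self.frame_times, dtype=float)
        roi = np.asarray(self.roi_intensity, dtype=float)
        bg = np.asarray(self.background_intensity, dtype=float)
        if not (t.shape == roi.shape == bg.shape) or t.ndim != 1:
            raise InvalidParameterError("frame_times, roi and background must be equal-length 1D arrays")
        if np.any(np.diff(t) <= 0):
            raise InvalidParameterError("frame_times must be strictly increasing")
        if self.n_prebleach < 1:
            raise InvalidParameterError("n_prebleach must be >= 1")
        if t.size - self.n_prebleach < 3:
            raise InvalidParameterError("need at least 3 postbleach frames")
        object.__setattr__(self, "frame_times", t)
        object.__setattr__(self, "roi_intensity", roi)
        object.__setattr__(self, "background_intensity", bg)


@dataclass(frozen=True)
class RecoveryCurve:
    """Normalized postbleach recovery: time re-zeroed at the first postbleach frame."""

    time_post_bleach: np.ndarray  # s, starts at 0
    rfi: np.ndarray  # unitless

    def __post_init__(self) -> None:
        t = np.asarray(self.time_post_bleach, dtype=float)
        r = np.asarray(self.rfi, dtype=float)
        if t.shape != r.shape or t.ndim != 1:
            raise InvalidParameterError("time and rfi must be equal-length 1D arrays")
        if t.size and t[0] != 0.0:
            raise InvalidParameterError("time_post_bleach must start at 0")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise InvalidParameterError("recovery curve contains non-finite values")
        object.__setattr__(self, "time_post_bleach", t)
        object.__setattr__(self, "rfi", r)


@dataclass(frozen=True)
class RecoveryFit:
    """Single-exponential recovery fit.

    ``t_half`` is defined from the fitted rate as ``ln 2 / k`` (NaN when the
    rate is unidentifiable).  ``flag`` is empty for a clean fit, otherwise one
    of ``"k_unidentifiable"`` / ``"k_at_bound"``.
    """

    floor: float
    plateau: float
    k: float  # 1/s
    t_half: float  # s
    mobile_fraction_est: float
    residual_rms: float
    converged: bool
    flag: str = ""


@dataclass(frozen=True)
class CohortCurve:
    """Mean +/- SD recovery over a cohort of cells on a common time grid."""

    grid: np.ndarray  # s
    mean_rfi: np.ndarray
    sd_rfi: np.ndarray
    n: int


def normalize_frap(trace: FrapTrace) -> RecoveryCurve:
    """Background-subtract and normalize a FRAP trace to prebleach levels.

    ``I_pre`` and ``I_bgpre`` are means over all prebleach frames.  Returns
    RFI for every postbleach frame with time re-zeroed at the first postbleach
    frame; the mean prebleach RFI equals 1 by construction.

    Raises
    ------
    DegenerateTraceError
        If the prebleach ROI signal does not exceed the prebleach background.
    """
    n_pre = trace.n_prebleach
    i_pre = float(np.mean(trace.roi_intensity[:n_pre]))
    i_bgpre = float(np.mean(trace.background_intensity[:n_pre]))
    denom = i_pre - i_bgpre
    if denom <= 0:
        raise DegenerateTraceError(
            f"prebleach ROI mean ({i_pre:g}) must exceed prebleach background mean ({i_bgpre:g})"
        )
    t_post = trace.frame_times[n_pre:]
    rfi = (trace.roi_intensity[n_pre:] - trace.background_intensity[n_pre:]) / denom
    if np.any(rfi < 0):
        warnings.warn("negative RFI values in postbleach frames (noise below background)", stacklevel=2)
    return RecoveryCurve(time_post_bleach=t_post - t_post[0], rfi=rfi)


def _recovery_model(t: np.ndarray, floor: float, delta: float, k: float) -> np.ndarray:
    return floor + delta * (1.0 - np.exp(-k * t))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """floor = first point; plateau = mean of last 10% of frames; k from the
    interpolated time to reach halfway between them."""
    floor0 = float(y[0])
    n_tail = max(1, int(round(0.1 * y.size)))
    plateau0 = float(np.mean(y[-n_tail:]))
    half_level = 0.5 * (floor0 + plateau0)
    k0 = 0.1
    if plateau0 > floor0:
        above = np.nonzero(y >= half_level)[0]
        above = above[above > 0]
        if above.size:
            j = int(above[0])
            # linear interpolation between frames j-1 and j
            y0, y1 = y[j - 1], y[j]
            t_half_guess = t[j - 1] + (half_level - y0) / (y1 - y0) * (t[j] - t[j - 1]) if y1 != y0 else t[j]
            if t_half_guess > 0:
                k0 = float(np.log(2.0) / t_half_guess)
    return floor0, max(plateau0 - floor0, 0.0), float(np.clip(k0, _K_LOWER, _K_UPPER))


def fit_recovery(curve: RecoveryCurve) -> RecoveryFit:
    """Fit ``RFI(t) = floor + (plateau - floor)(1 - exp(-k t))`` by bounded
    least squares.

    The fit is parameterized as (floor, delta, k) with delta = plateau - floor
    >= 0, which enforces floor <= plateau.  Bounds: floor in [-0.2, 1],
    plateau <= 1.5, k in (0, 10] 1/s.  Non-convergence is reported through the
    ``converged`` flag, never raised, so cohort pipelines can skip-and-log.
    A flat curve yields plateau == floor with ``flag="k_unidentifiable"``.
    """
    t = curve.time_post_bleach
    y = curve.rfi
    if t.size < 4:
        raise InvalidParameterError("fit_recovery requires >= 4 postbleach points")

    floor0, delta0, k0 = _initial_guess(t, y)
    floor0 = float(np.clip(floor0, -0.2, 1.0))
    delta0 = float(np.clip(delta0, 0.0, 1.5 - floor0))

    def resid(p: np.ndarray) -> np.ndarray:
        return _recovery_model(t, p[0], p[1], p[2]) - y

    try:
        sol = least_squares(
            resid,
            x0=[floor0, delta0, k0],
            bounds=([-0.2, 0.0, _K_LOWER], [1.0, 1.7, _K_UPPER]),
            method="trf",
            x_scale=[1.0, 1.0, max(k0, 0.01)],
        )
        ok = bool(sol.success)
        floor, delta, k = (float(v) for v in sol.x)
    except Exception:  # pragma: no cover - scipy failure path
        ok = False
        floor, delta, k = floor0, delta0, k0

    plateau = floor + delta
    rms = float(np.sqrt(np.mean((_recovery_model(t, floor, delta, k) - y) ** 2)))

    flag = ""
    # delta ~ 0 (flat curve) leaves k unconstrained by the data
    span = max(float(np.ptp(y)), 1e-12)
    if delta <= max(1e-8, 1e-3 * span):
        flag = "k_unidentifiable"
        k = float("nan")
    elif k >= _K_UPPER * (1 - 1e-6) or k <= _K_LOWER * (1 + 1e-6):
        flag = "k_at_bound"

    t_half = float(np.log(2.0) / k) if np.isfinite(k) and k > 0 else float("nan")
    mobile = (plateau - floor) / (1.0 - floor) if abs(1.0 - floor) > 1e-12 else float("nan")
    return RecoveryFit(
        floor=floor,
        plateau=plateau,
        k=k,
        t_half=t_half,
        mobile_fraction_est=float(mobile),
        residual_rms=rms,
        converged=ok,
        flag=flag,
    )


def aggregate_recovery(curves: list[RecoveryCurve], grid: np.ndarray) -> CohortCurve:
    """Interpolate each curve onto ``grid`` and return per-time mean and SD.

    SD is the population standard deviation across cells (0 for a single
    curve).  The grid must lie within the time span of every curve.
    """
    if not curves:
        raise InvalidParameterError("aggregate_recovery requires at least one curve")
    grid = np.asarray(grid, dtype=float)
    rows = []
    for c in curves:
        if grid[0] < c.time_post_bleach[0] or grid[-1] > c.time_post_bleach[-1]:
            raise InvalidParameterError("grid extends beyond the span of a curve")
        rows.append(np.interp(grid, c.time_post_bleach, c.rfi))
    mat = np.vstack(rows)
    return CohortCurve(
        grid=grid,
        mean_rfi=mat.mean(axis=0),
        sd_rfi=mat.std(axis=0, ddof=0),
        n=len(curves),
    )
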