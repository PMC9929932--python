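"""Adhesion lifetime kinetics: logistic assembly and exponential disassembly.

An adhesion's intensity life history — from first appearance through growth,
a plateau, and disappearance — is background-subtracted, smoothed with a
three-frame running average, and split at the smoothed-intensity peak.  The
assembly phase (up to and including the peak frame) is fit with a logistic

    I(t) = A_a / (1 + exp(-r_a (t - t_a))),

and the disassembly phase (from the peak frame) with a single-exponential
decay with a free onset,

    I(t) = A_d * exp(-r_d * max(t - t_d, 0)),   t_d >= t_peak,

which is flat at ``A_d`` while the adhesion dwells at its plateau and decays
once disassembly begins; for a trace that starts decaying at the peak the fit
collapses to a decay anchored at the peak time.

"Steepness" rates are the logistic rate constant ``r_a`` and decay constant
``r_d``; the maximum logistic slope ``A_a r_a / 4`` is reported as an
auxiliary quantity.  The lifetime is the interval between the two half-times:
half-maximal assembly at ``t_a`` and half-amplitude decay at
``t_peak + ln 2 / r_d``.

The running average determines the phase split (peak frame); the least-squares
fits themselves run on the unsmoothed background-subtracted intensities by
default, because a running average systematically flattens exponential and
logistic curvature (a ~(r Δt)²/6 relative rate bias at 30-s frames) and
correlates adjacent noise.  Pass ``source="smooth"`` to fit the smoothed
curve instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from fadyn.errors import InvalidParameterError

__all__ = [
    "AdhesionTrace",
    "KineticsFit",
    "DisassemblyFit",
    "preprocess_trace",
    "fit_lifetime",
    "fit_disassembly_from_peak",
]

_R_LOWER = 1e-8  # 1/s, effective zero for rate constants
_R_UPPER = 10.0


@dataclass(frozen=True)
class AdhesionTrace:
    """One adhesion's intensity life history, preprocessed for fitting."""

    frame_times: np.ndarray  # s, strictly increasing
    intensity_raw: np.ndarray  # a.u.
    background: np.ndarray  # a.u.
    intensity_bgsub: np.ndarray  # raw - background
    intensity_smooth: np.ndarray  # running average of intensity_bgsub
    peak_index: int  # argmax of intensity_smooth, earliest on ties
    smooth_window: int = 3  # running-average window used


@dataclass(frozen=True)
class DisassemblyFit:
    """Plateau-then-exponential-decay fit starting at the peak frame."""

    amplitude: float  # a.u.
    rate: float  # 1/s
    onset: float  # t_d, s; decay begins here (>= peak time)
    start_index: int
    residual_rms: float
    converged: bool
    flag: str = ""  # "", "rate_unidentifiable", "non_decaying"


@dataclass(frozen=True)
class KineticsFit:
    """Joint assembly + disassembly fit of one adhesion trace."""

    assembly_amplitude: float  # A_a, a.u.
    assembly_rate: float  # r_a, 1/s
    assembly_midpoint: float  # t_a, s
    disassembly_amplitude: float  # A_d, a.u.
    disassembly_rate: float  # r_d, 1/s
    disassembly_onset: float  # t_d, s; fitted decay onset (>= peak time)
    t_half_assembly: float  # s (= t_a)
    t_half_disassembly: float  # s (= t_d + ln2/r_d)
    lifetime: float  # s
    max_assembly_slope: float  # A_a r_a / 4, a.u./s
    residual_rms: float
    converged_assembly: bool
    converged_disassembly: bool


def preprocess_trace(
    frame_times: np.ndarray,
    intensity_raw: np.ndarray,
    background: np.ndarray,
    window: int = 3,
) -> AdhesionTrace:
    """Background-subtract and smooth an intensity trace.

    The running average is centered with the stated odd ``window``; at the
    edges the window is truncated to the available frames (the first smoothed
    value of a window-3 trace is the mean of frames 0 and 1).  The peak index
    is the argmax of the smoothed trace, earliest frame on ties.
    """
    if window % 2 == 0 or window < 1:
        raise InvalidParameterError("smoothing window must be odd and >= 1")
    t = np.asarray(frame_times, dtype=float)
    raw = np.asarray(intensity_raw, dtype=float)
    bg = np.asarray(background, dtype=float)
    if not (t.shape == raw.shape == bg.shape) or t.ndim != 1:
        raise InvalidParameterError("frame_times, intensity and background must be equal-length 1D arrays")
    if t.size < window:
        raise InvalidParameterError(f"trace length {t.size} shorter than window {window}")
    if np.any(np.diff(t) <= 0):
        raise InvalidParameterError("frame_times must be strictly increasing")
    bgsub = raw - bg
    smooth = (
        pd.Series(bgsub).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return AdhesionTrace(
        frame_times=t,
        intensity_raw=raw,
        background=bg,
        intensity_bgsub=bgsub,
        intensity_smooth=smooth,
        peak_index=int(np.argmax(smooth)),
        smooth_window=window,
    )


def _split_index(trace: AdhesionTrace, source: str) -> int:
    """Frame at which the assembly/disassembly phases are split and anchored.

    The smoothed peak locates the maximum robustly, but a running average can
    displace the argmax by up to half a window on an asymmetric peak, which
    would put rising frames into the decay segment.  The anchor is therefore
    refined to the argmax of the fit-source values within one smoothing
    half-window of the smoothed peak (earliest frame on ties).
    """
    y = _fit_values(trace, source)
    hw = trace.smooth_window // 2
    lo = max(0, trace.peak_index - hw)
    hi = min(y.size, trace.peak_index + hw + 1)
    return lo + int(np.argmax(y[lo:hi]))


def _fit_logistic(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    """Bounded least-squares logistic fit with 3 starts; returns (A, r, t_mid, ok)."""
    a_max = float(np.max(y))
    if a_max <= 0:
        return a_max, float("nan"), float("nan"), False
    span = float(t[-1] - t[0]) or 1.0
    # midpoint guess: first crossing of half-max
    half_idx = int(np.argmax(y >= 0.5 * a_max))
    t_mid0 = float(t[half_idx])
    r0 = 4.0 / span  # slope-matched scale guess
    best = None
    for r_start in (r0 / 3, r0, 3 * r0):
        def resid(p: np.ndarray) -> np.ndarray:
            return p[0] / (1.0 + np.exp(-p[1] * (t - p[2]))) - y

        try:
            sol = least_squares(
                resid,
                x0=[a_max, float(np.clip(r_start, _R_LOWER, _R_UPPER)), t_mid0],
                bounds=([1e-12, _R_LOWER, t[0] - span], [2.5 * a_max, _R_UPPER, t[-1] + span]),
                method="trf",
                x_scale=[max(a_max, 1e-6), max(r_start, 1e-4), max(span, 1.0)],
            )
            cost = float(sol.cost)
            if best is None or cost < best[0]:
                best = (cost, sol)
        except Exception:  # pragma: no cover
            continue
    if best is None:  # pragma: no cover
        return a_max, float("nan"), float("nan"), False
    sol = best[1]
    a, r, t_mid = (float(v) for v in sol.x)
    return a, r, t_mid, bool(sol.success)


def _fit_decay(t: np.ndarray, y: np.ndarray, t0: float) -> tuple[float, float, float, bool, str]:
    """Fit ``A exp(-r max(t - t_d, 0))`` with t_d in [t0, t_end].

    Returns (A, r, t_d, ok, flag).  The free onset absorbs any dwell at the
    plateau before decay begins; for data decaying from the first frame the
    onset fits to t0 and the model reduces to an anchored decay.
    """
    a0 = float(y[0]) if y[0] > 0 else max(float(np.max(y)), 1e-12)
    t_end = float(t[-1])
    # rate guess from log-linear regression on positive values
    pos = y > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos] - t0, np.log(y[pos]), 1)[0]
        r0 = float(np.clip(-slope, 1e-4, _R_UPPER))
    else:
        r0 = 0.01

    def resid(p: np.ndarray) -> np.ndarray:
        return p[0] * np.exp(-p[1] * np.clip(t - p[2], 0.0, None)) - y

    span = max(t_end - t0, 1e-9)
    best = None
    for td_start in (t0, t0 + 0.25 * span):
        try:
            sol = least_squares(
                resid,
                x0=[a0, r0, td_start],
                bounds=([1e-12, _R_LOWER, t0], [2.5 * max(a0, 1e-12), _R_UPPER, t_end]),
                method="trf",
                x_scale=[max(a0, 1e-6), max(r0, 1e-4), span],
            )
            if best is None or float(sol.cost) < best[0]:
                best = (float(sol.cost), sol)
        except Exception:  # pragma: no cover
            continue
    if best is None:  # pragma: no cover
        return a0, float("nan"), t0, False, "non_decaying"
    sol = best[1]
    a, r, td = (float(v) for v in sol.x)
    ok = bool(sol.success)

    flag = ""
    scale = max(float(np.max(np.abs(y))), 1e-12)
    # no resolvable decay across the observed span (< 0.01%): flat segment
    if r * (t_end - td) < 1e-4 or td >= t_end - 1e-6 * span:
        if np.all(np.diff(y) >= -1e-9 * scale):
            flag = "rate_unidentifiable"
            r = 0.0
    if y.size >= 2 and y[-1] > y[0] and np.all(np.diff(y) >= -1e-9 * scale):
        flag = "non_decaying"
        ok = False
    return a, r, td, ok, flag


def _fit_values(trace: AdhesionTrace, source: str) -> np.ndarray:
    if source == "bgsub":
        return trace.intensity_bgsub
    if source == "smooth":
        return trace.intensity_smooth
    raise InvalidParameterError(f"source must be 'bgsub' or 'smooth', got {source!r}")


def fit_disassembly_from_peak(trace: AdhesionTrace, source: str = "bgsub") -> DisassemblyFit:
    """Exponential decay fit from the peak frame onward, ignoring assembly.

    Used when the initial assembly phase is undetectable (low signal-to-noise)
    and only the decrease from maximum intensity can be quantified.  Identical
    to the disassembly phase of :func:`fit_lifetime` when the full trace is
    available.
    """
    i0 = _split_index(trace, source)
    t = trace.frame_times[i0:]
    y = _fit_values(trace, source)[i0:]
    if t.size < 4:
        raise InvalidParameterError("need >= 4 frames at/after the peak")
    a, r, td, ok, flag = _fit_decay(t, y, float(t[0]))
    if np.isfinite(r):
        rms = float(np.sqrt(np.mean((a * np.exp(-r * np.clip(t - td, 0, None)) - y) ** 2)))
    else:
        rms = float("nan")
    return DisassemblyFit(
        amplitude=a, rate=r, onset=td, start_index=i0, residual_rms=rms,
        converged=ok and flag == "", flag=flag,
    )


def fit_lifetime(
    trace: AdhesionTrace, completeness_frac: float = 0.25, source: str = "bgsub"
) -> KineticsFit:
    """Fit assembly (logistic) and disassembly (exponential decay) phases.

    The trace is split at the smoothed-peak frame, which is included in both
    phases so each fit is anchored there.  A phase with fewer than 4 frames is
    flagged not-fit (NaN parameters).  The trace is expected to span assembly
    through full disassembly: if the first or last smoothed value is not below
    ``completeness_frac`` of the peak a warning is emitted (the fit proceeds).

    Lifetime = (t_peak + ln2/r_d) - t_a, the interval between half-maximal
    assembly and half-amplitude disassembly.
    """
    i_pk = _split_index(trace, source)
    t = trace.frame_times
    y = _fit_values(trace, source)
    peak_val = float(trace.intensity_smooth[trace.peak_index])
    sm = trace.intensity_smooth
    if peak_val > 0 and (sm[0] > completeness_frac * peak_val or sm[-1] > completeness_frac * peak_val):
        warnings.warn(
            "trace does not span full assembly/disassembly "
            f"(ends above {completeness_frac:.0%} of peak); fits may be biased",
            stacklevel=2,
        )

    t_asm, y_asm = t[: i_pk + 1], y[: i_pk + 1]
    t_dis, y_dis = t[i_pk:], y[i_pk:]

    if t_asm.size >= 4:
        a_a, r_a, t_a, ok_a = _fit_logistic(t_asm, y_asm)
    else:
        a_a, r_a, t_a, ok_a = float("nan"), float("nan"), float("nan"), False

    if t_dis.size >= 4:
        a_d, r_d, t_d, ok_d, flag_d = _fit_decay(t_dis, y_dis, float(t[i_pk]))
        ok_d = ok_d and flag_d == ""
    else:
        a_d, r_d, t_d, ok_d = float("nan"), float("nan"), float("nan"), False

    t_half_asm = t_a
    t_half_dis = t_d + np.log(2.0) / r_d if ok_d and r_d > 0 else float("nan")
    lifetime = t_half_dis - t_half_asm if ok_a and ok_d else float("nan")

    # joint residual over both phases (peak frame counted once)
    parts = []
    if ok_a:
        parts.append(a_a / (1.0 + np.exp(-r_a * (t_asm - t_a))) - y_asm)
    if ok_d:
        parts.append(a_d * np.exp(-r_d * np.clip(t_dis[1:] - t_d, 0, None)) - y_dis[1:])
    rms = float(np.sqrt(np.mean(np.concatenate(parts) ** 2))) if parts else float("nan")

    return KineticsFit(
        assembly_amplitude=a_a,
        assembly_rate=r_a,
        assembly_midpoint=t_a,
        disassembly_amplitude=a_d,
        disassembly_rate=r_d,
        disassembly_onset=t_d,
        t_half_assembly=t_half_asm,
        t_half_disassembly=t_half_dis,
        lifetime=lifetime,
        max_assembly_slope=a_a * r_a / 4.0 if ok_a else float("nan"),
        residual_rms=rms,
        converged_assembly=ok_a,
        converged_disassembly=ok_d,
    )
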