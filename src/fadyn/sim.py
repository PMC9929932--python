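"""Synthetic data with known ground truth.

Every generator mirrors one of the acquisition regimes used for the real
measurements:

- FRAP: single z-plane, 2-s frames, 3 prebleach frames, 5 min postbleach;
  instantaneous bleach of a ~2 µm ROI.
- Adhesion lifetime: frames every 20 or 30 s for up to 1 h, one adhesion
  followed from assembly to full disassembly.
- Macrophage wound response: frames every 30 s for 10 min, biased persistent
  random walks toward a wound point.
- ZMEL random migration: frames every 5 min for 10 h (use
  :func:`TrackSimParams.zmel_random` defaults).
- Spot images: Gaussian puncta on a constant background, for segmentation
  and centroid-tracking tests.

All outputs are bit-reproducible for a fixed seed, carry exactly one
:class:`GroundTruth` record holding the generative parameters, and are
labeled as model stand-ins: the distributional choices (additive truncated
Gaussian noise, folded-normal step lengths) are the simplest forms adequate
for parameter-recovery testing, not measured properties of any instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any

import numpy as np

from fadyn.errors import InvalidParameterError
from fadyn.frap import FrapTrace
from fadyn.kinetics import AdhesionTrace, preprocess_trace
from fadyn.motility import Track

__all__ = [
    "FrapSimParams",
    "LifetimeSimParams",
    "TrackSimParams",
    "SpotImageParams",
    "GroundTruth",
    "simulate_frap_trace",
    "simulate_adhesion_trace",
    "simulate_tracks",
    "simulate_spot_image",
]

#: fraction of plateau at which the generated logistic assembly is truncated
#: and the dwell begins (fixed; keeps the trace continuous at the handoff).
LOGISTIC_CUTOFF = 0.995
#: fraction of the held level at which the generated decay is cut off.
DECAY_CUTOFF = 0.005


@dataclass(frozen=True)
class GroundTruth:
    """True generative parameters for one simulated object.

    ``params`` always includes ``"model"``, naming the generative stand-in
    used (these are modeling choices, not measured properties of real data).
    """

    object_id: str
    params: dict[str, Any]
    seed: int


@dataclass(frozen=True)
class FrapSimParams:
    """FRAP acquisition + recovery model parameters.

    Defaults follow the experimental regime: 3 prebleach frames, 2-s
    intervals, 5 min of postbleach imaging.  ``bleach_depth`` is the fraction
    of prebleach signal remaining immediately after the bleach;
    ``mobile_fraction`` the fraction of the bleached signal that recovers with
    rate ``k`` (true half-time ln2/k).
    """

    n_prebleach: int = 3
    frame_interval: float = 2.0  # s
    duration_post: float = 300.0  # s
    prebleach_level: float = 1000.0  # a.u., above background
    bleach_depth: float = 0.2
    mobile_fraction: float = 0.8
    k: float = 0.1  # 1/s
    background_level: float = 100.0  # a.u.
    noise_sd: float = 0.0  # a.u.
    seed: int = 0

    def validate(self) -> None:
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be > 0")
        if self.k <= 0:
            raise InvalidParameterError("k must be > 0")
        if not 0 <= self.bleach_depth < 1:
            raise InvalidParameterError("bleach_depth must be in [0, 1)")
        if not 0 <= self.mobile_fraction <= 1:
            raise InvalidParameterError("mobile_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.n_prebleach < 1:
            raise InvalidParameterError("n_prebleach must be >= 1")


@dataclass(frozen=True)
class LifetimeSimParams:
    """Adhesion lifetime trace parameters (logistic rise, dwell, exponential decay).

    Defaults describe an adhesion assembling over minutes (logistic rate
    0.01/s, midpoint 300 s), holding its plateau for 2 min, and disassembling
    with decay constant 0.005/s — a life history comfortably inside a 1-h
    acquisition at 30-s frames.
    """

    frame_interval: float = 30.0  # s (20 or 30 in the imaging regimes)
    assembly_rate_true: float = 0.01  # 1/s
    assembly_midpoint: float = 300.0  # s
    plateau_intensity: float = 1000.0  # a.u., above background
    dwell_time: float = 60.0  # s at plateau
    disassembly_rate_true: float = 0.005  # 1/s
    background_level: float = 100.0  # a.u.
    noise_sd: float = 0.0  # a.u.
    seed: int = 0

    def validate(self) -> None:
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be > 0")
        if self.assembly_rate_true <= 0 or self.disassembly_rate_true <= 0:
            raise InvalidParameterError("rates must be > 0")
        if self.dwell_time < 0:
            raise InvalidParameterError("dwell_time must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TrackSimParams:
    """Biased persistent random walk parameters.

    Defaults follow the macrophage wound-response regime (30-s frames for
    10 min); :meth:`zmel_random` switches to the in-culture random-migration
    regime (5-min frames for 10 h).  ``persistence`` weights the previous
    step direction, ``bias_strength`` the wound direction; the residual
    weight (1-persistence)(1-bias_strength) goes to an isotropic random unit
    vector, and the sum is renormalized.
    """

    n_cells: int = 20
    n_frames: int = 21  # 10 min at 30-s frames
    frame_interval: float = 30.0  # s
    speed_mean: float = 5.0  # µm/min
    persistence: float = 0.5
    bias_strength: float = 0.0
    wound_direction: tuple[float, float] = (1.0, 0.0)
    positional_noise_sd: float = 0.0  # µm
    seed: int = 0

    @classmethod
    def zmel_random(cls, **overrides: Any) -> "TrackSimParams":
        """In-vitro random-migration regime: 5-min frames for 10 h, no bias."""
        base = cls(n_frames=121, frame_interval=300.0, speed_mean=1.0, bias_strength=0.0)
        return replace(base, **overrides)

    def validate(self) -> None:
        if self.n_cells < 1:
            raise InvalidParameterError("n_cells must be >= 1")
        if self.n_frames < 2:
            raise InvalidParameterError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be > 0")
        if self.speed_mean < 0:
            raise InvalidParameterError("speed_mean must be >= 0")
        if not 0 <= self.persistence <= 1:
            raise InvalidParameterError("persistence must be in [0, 1]")
        if not 0 <= self.bias_strength <= 1:
            raise InvalidParameterError("bias_strength must be in [0, 1]")
        if np.linalg.norm(self.wound_direction) == 0:
            raise InvalidParameterError("wound_direction must be non-zero")
        if self.positional_noise_sd < 0:
            raise InvalidParameterError("positional_noise_sd must be >= 0")


@dataclass(frozen=True)
class SpotImageParams:
    """Gaussian-spot image parameters.

    ``spots`` is a list of (row_px, col_px, peak_au, sigma_px).
    """

    image_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.1  # µm/pixel
    spots: tuple[tuple[float, float, float, float], ...] = ()
    background_level: float = 10.0  # a.u.
    noise_sd: float = 0.0  # a.u.
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.image_shape
        if rows < 1 or cols < 1:
            raise InvalidParameterError("image_shape must be positive")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")
        for r, c, peak, sigma in self.spots:
            if sigma <= 0:
                raise InvalidParameterError("spot sigma must be > 0")
            if not (0 <= r < rows and 0 <= c < cols):
                raise InvalidParameterError(f"spot center ({r}, {c}) outside image {self.image_shape}")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")


def _add_noise(values: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Additive Gaussian intensity noise, truncated at 0 (intensities are non-negative)."""
    if sd == 0:
        return values
    return np.clip(values + rng.normal(0.0, sd, size=values.shape), 0.0, None)


def simulate_frap_trace(params: FrapSimParams) -> tuple[FrapTrace, GroundTruth]:
    """Generate one FRAP trace.

    Prebleach frames sit at ``background + prebleach_level``; the bleach is
    instantaneous between the last prebleach frame and the first postbleach
    frame, which drops to ``background + bleach_depth * prebleach_level``.
    Subsequent frames follow the single-exponential recovery

        ROI(t) = background + prebleach_level * (bleach_depth
                 + mobile_fraction * (1 - bleach_depth) * (1 - exp(-k t))),

    with t measured from the bleach (first postbleach) frame.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_post = int(round(params.duration_post / params.frame_interval)) + 1
    n = params.n_prebleach + n_post
    times = np.arange(n) * params.frame_interval
    t_post = times[params.n_prebleach :] - times[params.n_prebleach]

    roi = np.empty(n)
    roi[: params.n_prebleach] = params.background_level + params.prebleach_level
    recovered = params.bleach_depth + params.mobile_fraction * (1 - params.bleach_depth) * (
        1 - np.exp(-params.k * t_post)
    )
    roi[params.n_prebleach :] = params.background_level + params.prebleach_level * recovered

    bg = np.full(n, params.background_level)
    roi = _add_noise(roi, params.noise_sd, rng)
    bg = _add_noise(bg, params.noise_sd, rng)

    trace = FrapTrace(
        frame_times=times, roi_intensity=roi, background_intensity=bg, n_prebleach=params.n_prebleach
    )
    truth = GroundTruth(
        object_id=f"frap-{params.seed}",
        params={
            "model": "single-exponential recovery with immobile fraction (stand-in)",
            "k": params.k,
            "t_half": float(np.log(2.0) / params.k),
            "mobile_fraction": params.mobile_fraction,
            "bleach_depth": params.bleach_depth,
            "prebleach_level": params.prebleach_level,
            "background_level": params.background_level,
            "noise_sd": params.noise_sd,
        },
        seed=params.seed,
    )
    return trace, truth


def simulate_adhesion_trace(params: LifetimeSimParams) -> tuple[AdhesionTrace, GroundTruth]:
    """Generate one adhesion lifetime trace (returned preprocessed).

    The background-subtracted signal rises along a logistic
    ``plateau / (1 + exp(-r_a (t - t_a)))`` until the first frame at which it
    reaches ``LOGISTIC_CUTOFF`` of plateau, holds that frame's value for
    ``dwell_time``, then decays exponentially with rate ``r_d`` until
    ``DECAY_CUTOFF`` of the held level.  Phase boundaries are snapped to the
    frame grid so the noiseless trace is continuous and its maximum is the
    last assembly frame (first held frame).  The true lifetime recorded in
    GroundTruth is ``(t_onset + ln2/r_d) - t_a``: the interval between
    half-maximal assembly and half-amplitude disassembly.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    r_a, r_d = params.assembly_rate_true, params.disassembly_rate_true
    t_a = params.assembly_midpoint
    p = params.plateau_intensity
    # continuous-time estimate of the rise end, used only to size the grid
    t_rise_cont = t_a + np.log(LOGISTIC_CUTOFF / (1 - LOGISTIC_CUTOFF)) / r_a
    t_end = t_rise_cont + params.dwell_time + np.log(1.0 / DECAY_CUTOFF) / r_d
    times = np.arange(0.0, t_end + 2 * params.frame_interval, params.frame_interval)

    logistic = p / (1.0 + np.exp(-r_a * (times - t_a)))
    i_rise = int(np.argmax(logistic >= LOGISTIC_CUTOFF * p))
    held = float(logistic[i_rise])
    # last frame of the dwell; decay starts from it
    i_onset = int(np.searchsorted(times, times[i_rise] + params.dwell_time, side="right")) - 1
    t_onset = float(times[i_onset])
    signal = logistic.copy()
    signal[i_rise:i_onset + 1] = held
    signal[i_onset + 1 :] = held * np.exp(-r_d * (times[i_onset + 1 :] - t_onset))
    raw = _add_noise(params.background_level + signal, params.noise_sd, rng)
    bg = _add_noise(np.full_like(times, params.background_level), params.noise_sd, rng)

    trace = preprocess_trace(times, raw, bg)
    truth = GroundTruth(
        object_id=f"adhesion-{params.seed}",
        params={
            "model": "logistic rise + dwell + exponential decay (stand-in)",
            "assembly_rate": r_a,
            "assembly_midpoint": t_a,
            "disassembly_rate": r_d,
            "disassembly_onset": float(t_onset),
            "plateau_intensity": params.plateau_intensity,
            "dwell_time": params.dwell_time,
            "lifetime": float(t_onset + np.log(2.0) / r_d - t_a),
            "background_level": params.background_level,
            "noise_sd": params.noise_sd,
        },
        seed=params.seed,
    )
    return trace, truth


def simulate_tracks(params: TrackSimParams) -> tuple[list[Track], GroundTruth]:
    """Generate biased persistent random walks.

    Step length per frame is folded-normal with mean ``speed_mean *
    frame_interval`` (sigma = mean/3); step direction is the renormalized sum
    of persistence * previous direction, bias_strength * wound direction, and
    (1-persistence)(1-bias_strength) * an isotropic random unit vector.
    GroundTruth records the per-cell realized mean speed alongside the
    generative parameters.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval
    mean_step = params.speed_mean / 60.0 * dt  # µm per frame
    wound = np.asarray(params.wound_direction, dtype=float)
    wound = wound / np.linalg.norm(wound)
    w_rand = (1.0 - params.persistence) * (1.0 - params.bias_strength)

    tracks: list[Track] = []
    realized_speeds = []
    times = np.arange(params.n_frames) * dt
    for ci in range(params.n_cells):
        pos = np.zeros((params.n_frames, 2))
        pos[0] = rng.uniform(-50.0, 50.0, size=2)  # scatter starts over the field
        theta0 = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(theta0), np.sin(theta0)])
        for i in range(1, params.n_frames):
            theta = rng.uniform(0, 2 * np.pi)
            rand_u = np.array([np.cos(theta), np.sin(theta)])
            v = params.persistence * direction + params.bias_strength * wound + w_rand * rand_u
            norm = np.linalg.norm(v)
            direction = v / norm if norm > 0 else rand_u
            step = abs(rng.normal(mean_step, mean_step / 3.0)) if mean_step > 0 else 0.0
            pos[i] = pos[i - 1] + step * direction
        observed = pos
        if params.positional_noise_sd > 0:
            observed = pos + rng.normal(0.0, params.positional_noise_sd, size=pos.shape)
        tracks.append(Track(cell_id=f"cell{ci}", frame_times=times.copy(), positions=observed))
        seg = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        realized_speeds.append(float(seg.mean() / dt * 60.0))  # µm/min, noise-free path

    truth = GroundTruth(
        object_id=f"tracks-{params.seed}",
        params={
            "model": "biased persistent random walk, folded-normal steps (stand-in)",
            "speed_mean": params.speed_mean,
            "persistence": params.persistence,
            "bias_strength": params.bias_strength,
            "wound_direction": tuple(wound.tolist()),
            "per_cell_mean_speed": realized_speeds,
            "positional_noise_sd": params.positional_noise_sd,
        },
        seed=params.seed,
    )
    return tracks, truth


def simulate_spot_image(params: SpotImageParams) -> tuple[np.ndarray, GroundTruth]:
    """Generate a 2D image of Gaussian spots on a constant background.

    GroundTruth records each spot's center, peak and sigma, and the analytic
    above-threshold area of an isolated spot is available through
    :func:`analytic_spot_area_px`.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    rows, cols = params.image_shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    img = np.full((rows, cols), float(params.background_level))
    for r0, c0, peak, sigma in params.spots:
        img += peak * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma**2))
    img = _add_noise(img, params.noise_sd, rng)
    truth = GroundTruth(
        object_id=f"spots-{params.seed}",
        params={
            "model": "isotropic Gaussian spots + constant background (stand-in)",
            "spots": [tuple(map(float, s)) for s in params.spots],
            "background_level": params.background_level,
            "pixel_size": params.pixel_size,
            "noise_sd": params.noise_sd,
        },
        seed=params.seed,
    )
    return img, truth


def analytic_spot_area_px(peak: float, sigma: float, background: float, threshold: float) -> float:
    """Continuous-domain area (px²) of one isolated Gaussian spot above ``threshold``.

    The disk where ``background + peak * exp(-r²/2σ²) >= threshold`` has
    radius² = 2σ² ln(peak / (threshold - background)); returns 0 when the
    threshold exceeds the spot's peak and infinity when it is at or below
    background.
    """
    excess = threshold - background
    if excess <= 0:
        return float("inf")
    if excess >= peak:
        return 0.0
    return float(2.0 * np.pi * sigma**2 * np.log(peak / excess))
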