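"""Threshold-based spot segmentation and single-object centroid tracking.

Adhesion (spot) sizes are measured by thresholding fluorescent puncta on
maximum-intensity projections: pixels at or above the threshold are grouped
into 8-connected components, components below a minimum pixel count are
discarded, and each surviving component's area (pixel count x pixel_size²)
and intensity-weighted centroid are reported.  For cell tracking, the largest
thresholded object per frame yields a centroid series that is linked across
frames by nearest neighbor into a track consumable by :mod:`fadyn.motility`.

Coordinate convention: pixel (0, 0) at the image top-left, 0-based indices,
x = column * pixel_size, y = row * pixel_size (µm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from fadyn.errors import InvalidParameterError
from fadyn.motility import Track

__all__ = [
    "LabeledSpots",
    "CentroidSeries",
    "max_project",
    "segment_spots",
    "track_centroid",
]


@dataclass(frozen=True)
class LabeledSpots:
    """Connected-component segmentation result.

    ``label_image`` holds an integer per pixel (0 = background); labels are
    assigned in raster-scan order of each component's first pixel, so output
    is deterministic for a fixed input.
    """

    label_image: np.ndarray  # int, 0 = background
    areas_um2: np.ndarray  # per label, µm²
    centroids_um: np.ndarray  # (n, 2) as (x, y), intensity-weighted
    threshold: float  # a.u., the value actually applied
    pixel_size: float  # µm/pixel

    @property
    def n_spots(self) -> int:
        return len(self.areas_um2)


@dataclass(frozen=True)
class CentroidSeries:
    """Per-frame centroid of the tracked object, with gap bookkeeping."""

    frame_times: np.ndarray  # s
    centroids_um: np.ndarray  # (n, 2) as (x, y); NaN rows at gaps
    gap_frames: np.ndarray  # indices of frames with no usable object
    usable: bool  # False when > 50% of frames are gaps

    def to_track(self, cell_id: str = "cell0") -> Track:
        """Drop gap frames and return a Track for motility analysis."""
        good = ~np.isnan(self.centroids_um[:, 0])
        if good.sum() < 2:
            raise InvalidParameterError("fewer than 2 linked centroids; cannot form a track")
        return Track(
            cell_id=cell_id,
            frame_times=self.frame_times[good],
            positions=self.centroids_um[good],
        )


def max_project(stack: np.ndarray, z_range: tuple[int, int] | None = None) -> np.ndarray:
    """Per-pixel maximum over the selected z slices of a (z, rows, cols) stack."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise InvalidParameterError("stack must be 3D (z, rows, cols)")
    if z_range is None:
        z_range = (0, stack.shape[0])
    z0, z1 = z_range
    if not (0 <= z0 < z1 <= stack.shape[0]):
        raise InvalidParameterError(f"z_range {z_range} invalid for stack with {stack.shape[0]} slices")
    return stack[z0:z1].max(axis=0)


def _resolve_threshold(image: np.ndarray, threshold: float | str) -> float:
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise InvalidParameterError(f"unknown threshold method {threshold!r}")
        return float(threshold_otsu(image))
    return float(threshold)


def segment_spots(
    image: np.ndarray,
    threshold: float | str = "otsu",
    min_area_px: int = 4,
    pixel_size: float = 1.0,
) -> LabeledSpots:
    """Threshold, label 8-connected components, and measure size and centroid.

    ``threshold`` is either an absolute intensity or ``"otsu"`` (Otsu's
    method on the image histogram, invariant to affine intensity rescaling).
    Components smaller than ``min_area_px`` pixels are removed (suppresses
    single-pixel noise).  An all-background mask yields an empty result, not
    an error.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise InvalidParameterError("segment_spots expects a 2D image")
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be > 0")
    thr = _resolve_threshold(image, threshold)
    mask = image >= thr
    lbl = label(mask, connectivity=2)  # 8-connectivity; raster-scan label order

    areas, centroids = [], []
    keep = np.zeros(lbl.max() + 1, dtype=int)
    next_id = 1
    for rp in regionprops(lbl, intensity_image=image):
        if rp.area < min_area_px:
            continue
        keep[rp.label] = next_id
        next_id += 1
        areas.append(rp.area * pixel_size**2)
        row, col = rp.centroid_weighted
        centroids.append((col * pixel_size, row * pixel_size))
    relabeled = keep[lbl]
    return LabeledSpots(
        label_image=relabeled,
        areas_um2=np.asarray(areas, dtype=float),
        centroids_um=np.asarray(centroids, dtype=float).reshape(-1, 2),
        threshold=thr,
        pixel_size=pixel_size,
    )


def track_centroid(
    frames: list[np.ndarray] | np.ndarray,
    threshold: float | str,
    pixel_size: float,
    frame_interval: float,
    max_link_dist_um: float = np.inf,
    min_area_px: int = 4,
) -> CentroidSeries:
    """Track a single object across frames by thresholded-centroid linking.

    Per frame, the largest above-threshold component's intensity-weighted
    centroid is taken; consecutive centroids are linked when within
    ``max_link_dist_um`` of the previous linked position.  Frames with no
    object, or with a centroid beyond the linking distance, are recorded as
    gaps; a series with more than 50% gaps is flagged unusable.  Assumes one
    object of interest per movie.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    if len(frames) < 2:
        raise InvalidParameterError("need >= 2 frames to track")
    times = np.arange(len(frames)) * float(frame_interval)
    cents = np.full((len(frames), 2), np.nan)
    gaps: list[int] = []
    prev: np.ndarray | None = None
    for i, fr in enumerate(frames):
        spots = segment_spots(fr, threshold=threshold, min_area_px=min_area_px, pixel_size=pixel_size)
        if spots.n_spots == 0:
            gaps.append(i)
            continue
        counts = np.bincount(spots.label_image.ravel())[1:]
        cand = spots.centroids_um[int(np.argmax(counts))]
        if prev is not None and np.linalg.norm(cand - prev) > max_link_dist_um:
            gaps.append(i)
            continue
        cents[i] = cand
        prev = cand
    gap_arr = np.asarray(gaps, dtype=int)
    return CentroidSeries(
        frame_times=times,
        centroids_um=cents,
        gap_frames=gap_arr,
        usable=gap_arr.size <= 0.5 * len(frames),
    )
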