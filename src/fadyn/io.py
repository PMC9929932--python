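"""File formats: trace/track CSV dialects, TIFF images, YAML sidecars.

Trace CSV columns: ``frame_index, time_s, roi_intensity, background_intensity``
with optional ``# key=value`` header comment lines (e.g. ``# n_prebleach=3``).
Track CSV columns: ``cell_id, time_s, x_um, y_um`` with optional
``# wound_x_um=...`` / ``# wound_y_um=...`` header comments.  Ground truth and
acquisition metadata travel in sidecar YAML files next to the data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from fadyn.errors import InvalidParameterError
from fadyn.frap import FrapTrace
from fadyn.motility import Track
from fadyn.sim import GroundTruth

__all__ = [
    "read_header_metadata",
    "write_trace_csv",
    "read_frap_trace_csv",
    "read_trace_csv",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_image_tiff",
    "read_image_tiff",
    "write_ground_truth_yaml",
    "read_ground_truth_yaml",
]

_FLOAT_FMT = "%.9g"  # pinned formatting so fixed seeds give byte-identical files


def read_header_metadata(path: str | Path) -> dict[str, str]:
    """Parse leading ``# key=value`` comment lines of a CSV file."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _write_csv_with_header(path: Path, df: pd.DataFrame, meta: dict[str, Any]) -> None:
    with open(path, "w", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def write_trace_csv(
    path: str | Path,
    frame_times: np.ndarray,
    roi_intensity: np.ndarray,
    background_intensity: np.ndarray,
    **meta: Any,
) -> None:
    """Write an intensity trace with optional header metadata (e.g. n_prebleach)."""
    df = pd.DataFrame(
        {
            "frame_index": np.arange(len(frame_times)),
            "time_s": np.asarray(frame_times, dtype=float),
            "roi_intensity": np.asarray(roi_intensity, dtype=float),
            "background_intensity": np.asarray(background_intensity, dtype=float),
        }
    )
    _write_csv_with_header(Path(path), df, meta)


def read_trace_csv(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a trace CSV; returns (dataframe, header metadata)."""
    meta = read_header_metadata(path)
    df = pd.read_csv(path, comment="#")
    required = {"time_s", "roi_intensity", "background_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"{path}: missing columns {sorted(missing)}")
    return df, meta


def read_frap_trace_csv(path: str | Path, n_prebleach: int | None = None) -> FrapTrace:
    """Read a FRAP trace; ``n_prebleach`` comes from the header unless given."""
    df, meta = read_trace_csv(path)
    if n_prebleach is None:
        if "n_prebleach" not in meta:
            raise InvalidParameterError(f"{path}: n_prebleach not in header and not supplied")
        n_prebleach = int(meta["n_prebleach"])
    return FrapTrace(
        frame_times=df["time_s"].to_numpy(),
        roi_intensity=df["roi_intensity"].to_numpy(),
        background_intensity=df["background_intensity"].to_numpy(),
        n_prebleach=n_prebleach,
    )


def write_tracks_csv(
    path: str | Path, tracks: list[Track], wound_point: tuple[float, float] | None = None
) -> None:
    meta: dict[str, Any] = {}
    if wound_point is not None:
        meta["wound_x_um"] = wound_point[0]
        meta["wound_y_um"] = wound_point[1]
    rows = pd.concat(
        [
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "time_s": tr.frame_times,
                    "x_um": tr.positions[:, 0],
                    "y_um": tr.positions[:, 1],
                }
            )
            for tr in tracks
        ],
        ignore_index=True,
    )
    _write_csv_with_header(Path(path), rows, meta)


def read_tracks_csv(path: str | Path) -> tuple[list[Track], tuple[float, float] | None]:
    """Read a track table; returns (tracks, wound_point or None)."""
    meta = read_header_metadata(path)
    df = pd.read_csv(path, comment="#")
    required = {"cell_id", "time_s", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidParameterError(f"{path}: missing columns {sorted(missing)}")
    tracks = []
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("time_s")
        tracks.append(
            Track(
                cell_id=str(cid),
                frame_times=grp["time_s"].to_numpy(),
                positions=grp[["x_um", "y_um"]].to_numpy(),
            )
        )
    wound = None
    if "wound_x_um" in meta and "wound_y_um" in meta:
        wound = (float(meta["wound_x_um"]), float(meta["wound_y_um"]))
    return tracks, wound


def write_image_tiff(path: str | Path, image: np.ndarray, pixel_size: float | None = None) -> None:
    """Write a 2D frame or 3D stack as 32-bit float TIFF, pixel size in a YAML sidecar."""
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))
    if pixel_size is not None:
        sidecar = Path(path).with_suffix(".yaml")
        with open(sidecar, "w") as fh:
            yaml.safe_dump({"pixel_size_um": float(pixel_size)}, fh)


def read_image_tiff(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    """Read a TIFF; returns (array, sidecar metadata if a .yaml sits next to it)."""
    img = tifffile.imread(str(path))
    sidecar = Path(path).with_suffix(".yaml")
    meta: dict[str, Any] = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    return img, meta


def write_ground_truth_yaml(path: str | Path, truth: GroundTruth | list[GroundTruth]) -> None:
    items = truth if isinstance(truth, list) else [truth]
    payload = [dataclasses.asdict(t) for t in items]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_ground_truth_yaml(path: str | Path) -> list[GroundTruth]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [GroundTruth(**item) for item in payload]
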