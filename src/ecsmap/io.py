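"""Readers and writers for localization tables, bilevel images and result
tables, plus the minimum-length trajectory filter.

Localization tables are comma-separated UTF-8 text with a header row and
mandatory columns ``track, frame, x_um, y_um`` (optional: ``recording,
region, condition``).  Images are TIFF; the pixel pitch travels either as an
argument or in a JSON sidecar.  Result tables carry a ``#``-prefixed metadata
header (tool version, configuration hash).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import BinarizedImage, Trajectory, TrajectorySet

__all__ = [
    "TrajectoryParseError",
    "read_trajectories",
    "write_trajectories",
    "filter_trajectories",
    "read_image",
    "write_image",
    "threshold_binarize",
    "write_results",
    "read_results",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("track", "frame", "x_um", "y_um")
OPTIONAL_COLUMNS = ("recording", "region", "condition")


class TrajectoryParseError(ValueError):
    """Raised when a localization table violates the format contract."""


def read_trajectories(path: str | Path, dt: float = 0.03) -> TrajectorySet:
    """Parse a localization table into a :class:`TrajectorySet`.

    Rows are grouped by (recording, track) and sorted by frame; duplicated
    (track, frame) pairs are rejected with the offending key named.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path.name}: missing mandatory column(s) {missing}")
    for col, default in zip(OPTIONAL_COLUMNS, ("rec0", "", "")):
        if col not in df.columns:
            df[col] = default
        df[col] = df[col].fillna(default)
    for col in ("frame", "x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))
        if bad.size:
            raise TrajectoryParseError(
                f"{path.name}: non-numeric {col!r} at data row {int(bad[0])}"
            )
        df[col] = vals
    trajectories: list[Trajectory] = []
    for (rec, track), g in df.groupby(["recording", "track"], sort=False):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy(dtype=np.int64)
        if np.any(np.diff(frames) == 0):
            dup = int(frames[np.flatnonzero(np.diff(frames) == 0)[0]])
            raise TrajectoryParseError(
                f"{path.name}: duplicate frame {dup} for (recording={str(rec)!r}, "
                f"track={str(track)!r})"
            )
        trajectories.append(
            Trajectory(
                track_id=str(track),
                frames=frames,
                x=g["x_um"].to_numpy(dtype=float),
                y=g["y_um"].to_numpy(dtype=float),
                recording=str(rec),
                region=str(g["region"].iloc[0]),
                condition=str(g["condition"].iloc[0]),
            )
        )
    return TrajectorySet(trajectories, dt=dt)


def write_trajectories(ts: TrajectorySet, path: str | Path) -> None:
    rows = []
    for t in ts:
        for f, x, y in zip(t.frames, t.x, t.y):
            rows.append(
                {
                    "track": t.track_id,
                    "frame": int(f),
                    "x_um": x,
                    "y_um": y,
                    "recording": t.recording,
                    "region": t.region,
                    "condition": t.condition,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def filter_trajectories(ts: TrajectorySet, min_points: int = 12) -> TrajectorySet:
    """Keep trajectories with at least ``min_points`` localizations.

    The default of 12 reproduces the tracking QC rule that short tracks give
    unreliable diffusion-coefficient fits.  "Points" counts localizations, not
    frame span, so blinking gaps do not inflate a track's length.
    """
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    kept = [t for t in ts if t.n_points >= min_points]
    removed = len(ts) - len(kept)
    logger.info("filter_trajectories: kept %d, removed %d (< %d points)",
                len(kept), removed, min_points)
    meta = dict(ts.metadata)
    meta["filtered_out"] = meta.get("filtered_out", 0) + removed
    meta["min_points"] = min_points
    return TrajectorySet(kept, dt=ts.dt, metadata=meta)


def read_image(
    path: str | Path, pitch_nm: float | None = None, threshold: float | None = None
) -> BinarizedImage:
    """Read a bilevel (or thresholded 8-bit) TIFF as a :class:`BinarizedImage`.

    Pitch comes from ``pitch_nm`` or from a ``<stem>.json`` sidecar with a
    ``pitch_nm`` key.  Images with more than two gray levels require an
    explicit ``threshold``.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if pitch_nm is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(f"{path.name}: pixel pitch not given and no sidecar found")
        pitch_nm = float(json.loads(sidecar.read_text())["pitch_nm"])
    values = np.unique(arr)
    if threshold is not None:
        data = arr >= threshold
    elif values.size <= 2:
        data = arr == values.max() if values.size == 2 else arr > 0
    else:
        raise ValueError(
            f"{path.name}: {values.size} distinct pixel values; pass an explicit "
            "threshold to binarize"
        )
    return BinarizedImage(data, pitch_nm=pitch_nm)


def write_image(img: BinarizedImage, path: str | Path, sidecar: bool = True) -> None:
    path = Path(path)
    tifffile.imwrite(path, img.data.astype(np.uint8) * 255)
    if sidecar:
        path.with_suffix(".json").write_text(json.dumps({"pitch_nm": img.pitch_nm}))


def threshold_binarize(arr: np.ndarray, threshold: float, pitch_nm: float) -> BinarizedImage:
    """Plain intensity-threshold binarizer (convenience plumbing only; the
    study's wavelet-based segmentation is out of scope here)."""
    return BinarizedImage(np.asarray(arr) >= threshold, pitch_nm=pitch_nm)


def write_results(
    df: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> None:
    """Write a result table with a ``#``-prefixed metadata header."""
    from . import __version__

    path = Path(path)
    lines = [f"# ecsmap {__version__}"]
    for k, v in (metadata or {}).items():
        lines.append(f"# {k} = {v}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
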