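"""File I/O: track/spot CSV tables, TIFF stacks, fit JSON, configs.

Track CSV schema: track_id, frame, x_um, y_um, source — round-trips
losslessly (positions to float precision). Spot CSV schema: frame,
x_um, y_um, amplitude, sigma_px, quality.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import ImageStack, SchemaError, Spot, Track, TrackSet

__all__ = [
    "write_tracks_csv",
    "read_tracks_csv",
    "write_spots_csv",
    "read_spots_csv",
    "write_image_stack",
    "read_image_stack",
    "write_json",
]

_TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um", "source"]
_SPOT_COLUMNS = ["frame", "x_um", "y_um", "amplitude", "sigma_px", "quality"]


def write_tracks_csv(tracks: TrackSet, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "track_id": t.id,
            "frame": int(f),
            "x_um": p[0],
            "y_um": p[1],
            "source": t.source,
        }
        for t in tracks
        for f, p in zip(t.frames, t.positions)
    ]
    df = pd.DataFrame(rows, columns=_TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_tracks_csv(path: str | Path, dt: float = 0.06, pixel_size: float = 0.065) -> TrackSet:
    df = pd.read_csv(path)
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"track table missing columns {missing}")
    tracks = []
    for tid, group in df.groupby("track_id", sort=True):
        frames = group["frame"].to_numpy()
        if len(frames) >= 2 and not np.all(np.diff(frames) > 0):
            bad = int(np.where(np.diff(frames) <= 0)[0][0])
            raise SchemaError(
                f"track {tid}: frame column not strictly increasing at row {bad}"
            )
        tracks.append(
            Track(
                id=int(tid),
                frames=frames,
                positions=group[["x_um", "y_um"]].to_numpy(),
                source=str(group["source"].iloc[0]),
            )
        )
    return TrackSet(tracks=tracks, dt=dt, pixel_size=pixel_size)


def write_spots_csv(spots: list[Spot], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "frame": s.frame,
                "x_um": s.x,
                "y_um": s.y,
                "amplitude": s.amplitude,
                "sigma_px": s.sigma,
                "quality": s.quality,
            }
            for s in spots
        ],
        columns=_SPOT_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_spots_csv(path: str | Path) -> list[Spot]:
    df = pd.read_csv(path)
    missing = [c for c in _SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"spot table missing columns {missing}")
    return [
        Spot(
            frame=int(r.frame),
            x=float(r.x_um),
            y=float(r.y_um),
            amplitude=float(r.amplitude),
            sigma=float(r.sigma_px),
            quality=float(r.quality),
        )
        for r in df.itertuples()
    ]


def write_image_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a movie as multi-page 16-bit TIFF (counts clipped to uint16)."""
    path = Path(path)
    data = np.clip(np.round(stack.pixels), 0, 2**16 - 1).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        metadata={
            "pixel_size_um": stack.pixel_size,
            "frame_interval_s": stack.frame_interval,
        },
    )
    return path


def read_image_stack(
    path: str | Path, pixel_size: float = 0.065, frame_interval: float = 0.06
) -> ImageStack:
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return ImageStack(
        pixels=data.astype(float), pixel_size=pixel_size, frame_interval=frame_interval
    )


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default) + "\n")
    return path
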