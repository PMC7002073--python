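"""Shared data containers for tracks, spots, images and fits.

Physical coordinates are in micrometres with the origin at the image
corner; pixel (i, j) has its centre at ((j + 0.5) * px, (i + 0.5) * px)
where ``px`` is the pixel size (default 0.065 um). Times are in seconds
for imaging data and minutes for plate-reader/kinetic data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

DEFAULT_PIXEL_SIZE_UM = 0.065


class ParameterError(ValueError):
    """An argument violates its documented constraint."""


class GeometryError(ValueError):
    """A cell geometry is incompatible with the requested simulation."""


class SchemaError(ValueError):
    """A table does not conform to the expected file schema."""


@dataclass(frozen=True)
class TwoStateParams:
    """Parameters of the two-state (bound/free) lateral-diffusion model.

    f_bound   -- fraction of molecules in the near-immobile state, in [0, 1]
    d_free    -- diffusion coefficient of the mobile state, um^2/s
    d_bound   -- diffusion coefficient of the bound state, um^2/s
    sigma_loc -- localization error std per coordinate, um
    dt        -- frame interval, s
    """

    f_bound: float
    d_free: float
    d_bound: float = 0.0
    sigma_loc: float = 0.0
    dt: float = 0.06

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_bound <= 1.0:
            raise ParameterError(f"f_bound must be in [0, 1], got {self.f_bound}")
        if self.d_bound < 0 or self.d_free < self.d_bound:
            raise ParameterError("require d_free >= d_bound >= 0")
        if self.sigma_loc < 0:
            raise ParameterError("sigma_loc must be >= 0")
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")


@dataclass(frozen=True)
class CellGeometry:
    """Rod-shaped cell footprint: a rectangle of the given length and
    diameter centred at ``center`` and rotated by ``orientation``."""

    length: float
    diameter: float
    center: tuple[float, float] = (0.0, 0.0)
    orientation: float = 0.0

    def __post_init__(self) -> None:
        if not self.length >= self.diameter > 0:
            raise ParameterError("require length >= diameter > 0")


@dataclass
class Track:
    """One particle's (or cell's) trajectory.

    frames are strictly increasing integer indices; positions is an
    (n, 2) array of (x, y) in micrometres.
    """

    id: int
    frames: np.ndarray
    positions: np.ndarray
    source: str = "spt"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.frames.ndim != 1 or self.positions.shape != (len(self.frames), 2):
            raise ParameterError("frames must be 1-D and positions (n, 2)")
        if len(self.frames) >= 2 and not np.all(np.diff(self.frames) > 0):
            raise ParameterError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def end_to_end(self) -> float:
        return float(np.linalg.norm(self.positions[-1] - self.positions[0]))


@dataclass
class TrackSet:
    """A collection of tracks sharing acquisition metadata."""

    tracks: list[Track]
    dt: float = 0.06
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)


@dataclass
class GroundTruth:
    """Generating parameters and per-particle truth for a simulation.

    states holds one label per track ('bound'/'free' or 'directed');
    true_positions holds the noiseless trajectory of each track.
    """

    params: object
    states: list[str]
    true_positions: list[np.ndarray]
    seed: int


@dataclass(frozen=True)
class Spot:
    """One subpixel localization in one frame; x, y in micrometres."""

    frame: int
    x: float
    y: float
    amplitude: float = 0.0
    sigma: float = 0.0
    quality: float = 0.0


@dataclass
class ImageStack:
    """frames x H x W intensity array with physical calibration."""

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval: float = 0.06

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3:
            raise ParameterError("pixels must be frames x H x W")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ParameterError("pixel_size and frame_interval must be > 0")


@dataclass
class GrowthCurve:
    """Background-subtracted OD600 versus time (minutes)."""

    times: np.ndarray
    od: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.od.shape != self.times.shape:
            raise ParameterError("times and od must be matching 1-D arrays")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("times must be strictly increasing")


@dataclass
class IncorporationSeries:
    """Radiolabel counts per OD versus time (minutes) for one culture."""

    times: np.ndarray
    signal: np.ndarray
    gamma: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.shape != self.times.shape:
            raise ParameterError("times and signal must match")
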