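"""Nearest-neighbour linking, detection capping, smoothing and track filters.

Linking is a greedy globally-nearest assignment per frame transition:
candidate (track, spot) pairs are sorted by distance and accepted while
both endpoints are free and the distance does not exceed the maximum
step length. A track may bridge up to ``max_gap`` missing frames (the
distance test is against the last known position; positions are never
interpolated across gaps).
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .containers import DEFAULT_PIXEL_SIZE_UM, ParameterError, Spot, Track, TrackSet

__all__ = [
    "cap_detections",
    "link_spots",
    "smooth_track_gaussian",
    "smooth_tracks",
    "filter_tracks",
]


def cap_detections(spots: list[Spot], n_last: int = 15000) -> list[Spot]:
    """Keep the ``n_last`` spots with the highest frame indices.

    Early frames of a movie are the densest (before photobleaching has
    thinned the emitters), so tracking mistakes are limited by keeping
    only the latest peaks. Relative input order is preserved.
    """
    if n_last < 1:
        raise ParameterError("n_last must be >= 1")
    if len(spots) <= n_last:
        return list(spots)
    frames = np.array([s.frame for s in spots])
    # threshold frame such that all later frames plus part of this one fill n_last
    order = np.argsort(frames, kind="stable")
    keep_idx = set(order[len(spots) - n_last :].tolist())
    return [s for i, s in enumerate(spots) if i in keep_idx]


def _group_by_frame(spots: list[Spot]) -> dict[int, list[tuple[int, Spot]]]:
    by_frame: dict[int, list[tuple[int, Spot]]] = defaultdict(list)
    for idx, s in enumerate(spots):
        by_frame[s.frame].append((idx, s))
    return by_frame


def link_spots(
    spots: list[Spot],
    max_disp: float = 0.3,
    max_gap: int = 2,
    dt: float = 0.06,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
) -> TrackSet:
    """Link per-frame spots into trajectories (max_disp in um).

    Defaults match single-particle tracking of membrane proteins: a
    maximum step length of 0.3 um and an allowance of two gap frames.
    For directed MreB linking use ``max_disp=3 * pixel_size`` and
    ``max_gap=0``. Tracks with fewer than 2 localizations are discarded.
    """
    if max_disp <= 0:
        raise ParameterError("max_disp must be > 0")
    if max_gap < 0:
        raise ParameterError("max_gap must be >= 0")
    by_frame = _group_by_frame(spots)
    if not by_frame:
        return TrackSet(tracks=[], dt=dt, pixel_size=pixel_size)
    frames_sorted = sorted(by_frame)

    # active track state: list of dicts with last position/frame and members
    active: list[dict] = []
    finished: list[dict] = []

    for frame in frames_sorted:
        entries = by_frame[frame]
        # retire tracks whose gap allowance is exhausted
        still = []
        for tr in active:
            if frame - tr["last_frame"] > max_gap + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still

        candidates = []
        for ti, tr in enumerate(active):
            lx, ly = tr["last_pos"]
            for si, (spot_idx, s) in enumerate(entries):
                d = np.hypot(s.x - lx, s.y - ly)
                if d <= max_disp:
                    candidates.append((d, tr["last_frame"], ti, si))
        candidates.sort()

        assigned_tracks: set[int] = set()
        assigned_spots: set[int] = set()
        for d, _, ti, si in candidates:
            if ti in assigned_tracks or si in assigned_spots:
                continue
            assigned_tracks.add(ti)
            assigned_spots.add(si)
            spot_idx, s = entries[si]
            tr = active[ti]
            tr["members"].append((frame, s))
            tr["last_pos"] = (s.x, s.y)
            tr["last_frame"] = frame

        for si, (spot_idx, s) in enumerate(entries):
            if si not in assigned_spots:
                active.append(
                    {"members": [(frame, s)], "last_pos": (s.x, s.y), "last_frame": frame}
                )

    finished.extend(active)

    tracks: list[Track] = []
    next_id = 0
    for tr in finished:
        if len(tr["members"]) < 2:
            continue
        frames = np.array([f for f, _ in tr["members"]])
        pos = np.array([[s.x, s.y] for _, s in tr["members"]])
        tracks.append(Track(id=next_id, frames=frames, positions=pos, source="spt"))
        next_id += 1
    return TrackSet(tracks=tracks, dt=dt, pixel_size=pixel_size)


def _partial_gaussian_weights(sigma: float, n: int) -> np.ndarray:
    """n x n weight matrix: row i holds the renormalized truncated kernel
    centred on sample i (edge rows use renormalized partial kernels)."""
    half = int(np.ceil(3 * sigma))
    offsets = np.arange(-half, half + 1)
    kernel = np.exp(-(offsets**2) / (2.0 * sigma**2))
    weights = np.zeros((n, n))
    for i in range(n):
        js = i + offsets
        valid = (js >= 0) & (js < n)
        w = kernel[valid]
        weights[i, js[valid]] = w / w.sum()
    return weights


def smooth_track_gaussian(track: Track, sigma: float = 1.5) -> Track:
    """Gaussian-smooth a track's coordinates in time (sigma in time steps).

    The kernel is truncated at +/-3 sigma and renormalized; endpoints
    use renormalized partial kernels so constant tracks are unchanged.
    Tracks with frame gaps are smoothed per contiguous segment.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    positions = track.positions.copy()
    # contiguous runs of consecutive frames
    breaks = np.where(np.diff(track.frames) != 1)[0] + 1
    for segment in np.split(np.arange(len(track)), breaks):
        n = len(segment)
        if n < 2:
            continue
        weights = _partial_gaussian_weights(sigma, n)
        positions[segment] = weights @ track.positions[segment]
    return Track(id=track.id, frames=track.frames.copy(), positions=positions, source=track.source)


def smooth_tracks(tracks: TrackSet, sigma: float = 1.5) -> TrackSet:
    """Apply :func:`smooth_track_gaussian` to every track in the set."""
    return TrackSet(
        tracks=[smooth_track_gaussian(t, sigma) for t in tracks],
        dt=tracks.dt,
        pixel_size=tracks.pixel_size,
        provenance=tracks.provenance,
    )


def filter_tracks(
    tracks: TrackSet,
    min_localizations: int = 8,
    min_end_to_end: float | None = None,
) -> TrackSet:
    """Keep tracks with enough localizations and (optionally) net displacement.

    The default of 8 localizations reads the "more than seven
    localizations" criterion strictly; ``min_end_to_end`` (um) keeps
    only tracks whose start-to-end distance reaches the threshold.
    """
    if min_localizations < 2:
        raise ParameterError("min_localizations must be >= 2")
    kept = [
        t
        for t in tracks
        if len(t) >= min_localizations
        and (min_end_to_end is None or t.end_to_end >= min_end_to_end)
    ]
    return TrackSet(
        tracks=kept, dt=tracks.dt, pixel_size=tracks.pixel_size, provenance=tracks.provenance
    )
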