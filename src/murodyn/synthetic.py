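"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (detection, linking, two-state
fitting, flux, growth/incorporation kinetics, osmotic-shock statistics)
can be exercised against data produced here, so estimator quality is
always measurable as parameter recovery. All generators are
deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    CellGeometry,
    GeometryError,
    GroundTruth,
    GrowthCurve,
    ImageStack,
    IncorporationSeries,
    ParameterError,
    Spot,
    Track,
    TrackSet,
    TwoStateParams,
)

__all__ = [
    "simulate_two_state_tracks",
    "simulate_directed_tracks",
    "render_spot_movie",
    "simulate_growth_curve",
    "simulate_incorporation_series",
    "simulate_shock_dimensions",
]


def _fold(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Specular reflection of coordinates into [lo, hi].

    Equivalent to reflecting a Brownian path at the interval walls; exact
    for arbitrarily large excursions (triangle-wave folding).
    """
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return y + lo


def _rotate(xy: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return xy @ rot.T


def _geometric_lengths(rng, n: int, mean_len: float) -> np.ndarray:
    """Track lengths: 2 + geometric tail so the mean equals mean_len."""
    if mean_len <= 2:
        return np.full(n, 2, dtype=int)
    p = 1.0 / (mean_len - 1.0)
    return 2 + rng.geometric(p, size=n) - 1


def simulate_two_state_tracks(
    params: TwoStateParams,
    n_tracks: int,
    mean_track_len: float = 8.0,
    geometry: CellGeometry | None = None,
    seed: int = 0,
) -> tuple[TrackSet, GroundTruth]:
    """Simulate two-state (bound/free) membrane-protein trajectories.

    Each particle keeps a single state for its whole (photobleaching
    limited) lifetime; true positions are Brownian with the state's
    diffusion coefficient and the observed positions add independent
    Gaussian localization error of std ``sigma_loc`` per coordinate.
    Track lengths are geometric with the given mean, minimum 2 frames.
    With a geometry, true positions are confined to the rod footprint by
    specular reflection.
    """
    if n_tracks < 1:
        raise ParameterError("n_tracks must be >= 1")
    if mean_track_len < 2:
        raise ParameterError("mean_track_len must be >= 2")
    rng = np.random.default_rng(seed)

    step_scale = np.sqrt(2.0 * params.d_free * params.dt)
    if geometry is not None and step_scale > 0 and geometry.diameter < step_scale:
        raise GeometryError(
            f"rod diameter {geometry.diameter} um smaller than one step scale "
            f"{step_scale:.3g} um"
        )

    lengths = _geometric_lengths(rng, n_tracks, mean_track_len)
    states = np.where(rng.random(n_tracks) < params.f_bound, "bound", "free")

    tracks: list[Track] = []
    true_positions: list[np.ndarray] = []
    for i in range(n_tracks):
        n = lengths[i]
        d = params.d_bound if states[i] == "bound" else params.d_free
        sd_step = np.sqrt(2.0 * d * params.dt)
        if geometry is None:
            start = rng.uniform(-1.0, 1.0, size=2)
        else:
            start = np.array(
                [
                    rng.uniform(-geometry.length / 2, geometry.length / 2),
                    rng.uniform(-geometry.diameter / 2, geometry.diameter / 2),
                ]
            )
        steps = rng.normal(0.0, sd_step, size=(n - 1, 2)) if sd_step > 0 else np.zeros((n - 1, 2))
        pos = start + np.concatenate([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        if geometry is not None:
            pos[:, 0] = _fold(pos[:, 0], -geometry.length / 2, geometry.length / 2)
            pos[:, 1] = _fold(pos[:, 1], -geometry.diameter / 2, geometry.diameter / 2)
            pos = _rotate(pos, geometry.orientation) + np.asarray(geometry.center)
        noise = (
            rng.normal(0.0, params.sigma_loc, size=pos.shape)
            if params.sigma_loc > 0
            else np.zeros_like(pos)
        )
        observed = pos + noise
        tracks.append(Track(id=i, frames=np.arange(n), positions=observed, source="spt"))
        true_positions.append(pos)

    ts = TrackSet(tracks=tracks, dt=params.dt)
    gt = GroundTruth(params=params, states=list(states), true_positions=true_positions, seed=seed)
    return ts, gt


def simulate_directed_tracks(
    speed: float,
    interval: float,
    n_tracks: int,
    track_len: int,
    sigma_loc: float,
    geometry: CellGeometry,
    seed: int = 0,
) -> tuple[TrackSet, GroundTruth]:
    """Simulate slow, directed circumferential tracks (MreB-like motion).

    speed is in nm/s and interval in s; particles advance at constant
    speed perpendicular to the rod axis, reflecting at the lateral
    boundary, plus per-frame localization noise of std ``sigma_loc`` um.
    """
    if speed < 0:
        raise ParameterError("speed must be >= 0")
    if interval <= 0:
        raise ParameterError("interval must be > 0")
    if track_len < 2:
        raise ParameterError("track_len must be >= 2")
    rng = np.random.default_rng(seed)

    step_um = speed * 1e-3 * interval
    half_w = geometry.diameter / 2.0
    tracks: list[Track] = []
    true_positions: list[np.ndarray] = []
    for i in range(n_tracks):
        x0 = rng.uniform(-geometry.length / 2, geometry.length / 2)
        y0 = rng.uniform(-half_w, half_w)
        direction = rng.choice([-1.0, 1.0])
        y = y0 + direction * step_um * np.arange(track_len)
        y = _fold(y, -half_w, half_w)
        pos = np.column_stack([np.full(track_len, x0), y])
        pos = _rotate(pos, geometry.orientation) + np.asarray(geometry.center)
        noise = (
            rng.normal(0.0, sigma_loc, size=pos.shape) if sigma_loc > 0 else np.zeros_like(pos)
        )
        tracks.append(
            Track(id=i, frames=np.arange(track_len), positions=pos + noise, source="mreb")
        )
        true_positions.append(pos)

    ts = TrackSet(tracks=tracks, dt=interval)
    gt = GroundTruth(
        params={"speed_nm_s": speed, "interval_s": interval, "sigma_loc_um": sigma_loc},
        states=["directed"] * n_tracks,
        true_positions=true_positions,
        seed=seed,
    )
    return ts, gt


def render_spot_movie(
    tracks: TrackSet,
    psf_sigma: float = 1.2,
    amplitude: float = 200.0,
    background: float = 100.0,
    noise_model: str = "none",
    shape: tuple[int, int, int] = (10, 64, 64),
    gaussian_sd: float = 0.0,
    seed: int = 0,
    out_of_frame: str = "clip",
) -> ImageStack:
    """Render localizations as 2-D Gaussian spots on a noisy background.

    Each localization becomes an isotropic Gaussian of the given sigma
    (pixels) and peak amplitude (counts) added to a constant background.
    noise_model is one of {'none', 'poisson', 'poisson+gaussian'};
    'poisson+gaussian' adds read noise of std ``gaussian_sd`` counts.
    Coordinates outside the frame are clipped out ('clip') or raise
    ('error') per ``out_of_frame``.
    """
    if psf_sigma <= 0:
        raise ParameterError("psf_sigma must be > 0")
    if amplitude < 0:
        raise ParameterError("amplitude must be >= 0")
    if noise_model not in {"none", "poisson", "poisson+gaussian"}:
        raise ParameterError(f"unknown noise model {noise_model!r}")
    n_frames, h, w = shape
    px = tracks.pixel_size
    movie = np.full((n_frames, h, w), float(background))
    halo = int(np.ceil(5 * psf_sigma))

    for track in tracks:
        for frame, (x_um, y_um) in zip(track.frames, track.positions):
            if frame < 0 or frame >= n_frames:
                continue
            # physical um -> pixel-centre coordinates (col, row)
            col = x_um / px - 0.5
            row = y_um / px - 0.5
            if not (0 <= col < w and 0 <= row < h):
                if out_of_frame == "error":
                    raise ParameterError(
                        f"localization ({x_um}, {y_um}) um outside the frame"
                    )
                continue
            r0, r1 = int(np.floor(row)) - halo, int(np.floor(row)) + halo + 1
            c0, c1 = int(np.floor(col)) - halo, int(np.floor(col)) + halo + 1
            r0, r1 = max(r0, 0), min(r1, h)
            c0, c1 = max(c0, 0), min(c1, w)
            rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
            movie[frame, r0:r1, c0:c1] += amplitude * np.exp(
                -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * psf_sigma**2)
            )

    if noise_model != "none":
        rng = np.random.default_rng(seed)
        movie = rng.poisson(movie).astype(float)
        if noise_model == "poisson+gaussian":
            movie += rng.normal(0.0, gaussian_sd, size=movie.shape)
    return ImageStack(pixels=movie, pixel_size=px, frame_interval=tracks.dt)


def simulate_growth_curve(
    od0: float,
    doubling_time: float,
    lag: float = 0.0,
    stationary_od: float = np.inf,
    noise_sd: float = 0.0,
    times: np.ndarray | None = None,
    seed: int = 0,
) -> GrowthCurve:
    """Exponential growth with optional lag and stationary plateau.

    OD stays at od0 during the lag, then doubles every ``doubling_time``
    minutes until capped at stationary_od; Gaussian noise of std
    noise_sd is added to every reading.
    """
    if od0 <= 0 or doubling_time <= 0:
        raise ParameterError("od0 and doubling_time must be > 0")
    if times is None:
        times = np.arange(0.0, 600.0, 10.0)
    times = np.asarray(times, dtype=float)
    if len(times) >= 2 and not np.all(np.diff(times) > 0):
        raise ParameterError("times must be strictly increasing")
    od = od0 * np.exp2(np.clip(times - lag, 0.0, None) / doubling_time)
    od = np.minimum(od, stationary_od)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        od = od + rng.normal(0.0, noise_sd, size=od.shape)
    return GrowthCurve(
        times=times,
        od=od,
        meta={
            "od0": od0,
            "doubling_time": doubling_time,
            "lag": lag,
            "stationary_od": stationary_od,
            "seed": seed,
        },
    )


def incorporation_signal(t: np.ndarray, kin: float, kout: float, gamma: float) -> np.ndarray:
    """Noiseless label-per-OD signal of the incorporation/turnover balance.

    d(S)/dt = kin - (gamma + kout) * S, S(0) = 0, hence
    S(t) = kin / (gamma + kout) * (1 - exp(-(gamma + kout) * t)).
    """
    rate = gamma + kout
    return kin / rate * -np.expm1(-rate * np.asarray(t, dtype=float))


def simulate_incorporation_series(
    kin: float,
    kout: float,
    gamma: float,
    times: np.ndarray,
    noise_model: str = "none",
    seed: int = 0,
    label: str = "",
) -> IncorporationSeries:
    """Saturating radiolabel-incorporation series with optional counting noise.

    kin is the incorporation rate (counts/OD/min), kout the turnover rate
    (1/min) and gamma the culture's exponential growth rate (1/min).
    """
    if kin < 0 or kout < 0:
        raise ParameterError("rates must be >= 0")
    if gamma <= 0:
        raise ParameterError("gamma must be > 0")
    if noise_model not in {"none", "poisson"}:
        raise ParameterError(f"unknown noise model {noise_model!r}")
    times = np.asarray(times, dtype=float)
    signal = incorporation_signal(times, kin, kout, gamma)
    if noise_model == "poisson":
        rng = np.random.default_rng(seed)
        signal = rng.poisson(signal).astype(float)
    return IncorporationSeries(times=times, signal=signal, gamma=gamma, label=label)


def simulate_shock_dimensions(
    n_cells: int,
    mean_ext_short: float = 1.05,
    mean_ext_long: float = 1.02,
    sd: float = 0.02,
    seed: int = 0,
    mean_pre_short: float = 0.9,
    mean_pre_long: float = 3.0,
) -> pd.DataFrame:
    """Paired pre/post osmotic-downshock cell dimensions.

    Post/pre ratios per axis are lognormal with the requested means
    (an extension ratio of 1 is no extension); sd is the approximate
    standard deviation of the ratios. Returns a tidy table with one row
    per cell: pre/post short- and long-axis dimensions in um.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    if mean_ext_short <= 0 or mean_ext_long <= 0:
        raise ParameterError("extension means must be > 0")
    if sd < 0:
        raise ParameterError("sd must be >= 0")
    rng = np.random.default_rng(seed)

    def ratios(mean: float) -> np.ndarray:
        if sd == 0:
            return np.full(n_cells, mean)
        s = np.sqrt(np.log1p((sd / mean) ** 2))
        mu = np.log(mean) - s**2 / 2.0
        return rng.lognormal(mu, s, size=n_cells)

    pre_short = mean_pre_short * rng.lognormal(0.0, 0.05, size=n_cells)
    pre_long = mean_pre_long * rng.lognormal(0.0, 0.15, size=n_cells)
    return pd.DataFrame(
        {
            "cell": np.arange(n_cells),
            "pre_short_um": pre_short,
            "pre_long_um": pre_long,
            "post_short_um": pre_short * ratios(mean_ext_short),
            "post_long_um": pre_long * ratios(mean_ext_long),
        }
    )


def spots_from_tracks(tracks: TrackSet) -> list[Spot]:
    """Flatten a TrackSet into the per-frame Spot list a detector would emit."""
    spots = [
        Spot(frame=int(f), x=float(p[0]), y=float(p[1]))
        for track in tracks
        for f, p in zip(track.frames, track.positions)
    ]
    spots.sort(key=lambda s: s.frame)
    return spots
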