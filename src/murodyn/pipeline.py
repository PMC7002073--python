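"""Stage runner binding the analysis modules into reproducible runs.

A run is described by a RunConfig (stage name, inputs, parameter
overrides, seed, output directory). ``run_pipeline`` validates the
config against the stage's schema, executes the stage end-to-end and
returns a manifest listing every artifact with its SHA-256 hash, so
identical config + seed gives identical manifests for deterministic
stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from . import kinetics, mreb, spt, synthetic, tracking
from .containers import ParameterError, TwoStateParams

__all__ = ["RunConfig", "run_pipeline", "load_config", "STAGES"]


@dataclass
class RunConfig:
    stage: str
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = "murodyn_out"

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "stage": self.stage,
                "inputs": self.inputs,
                "params": self.params,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# stage name -> allowed parameter keys (unknown keys are rejected)
STAGES: dict[str, set[str]] = {
    "simulate-spt": {
        "f_bound", "d_free", "d_bound", "sigma_loc", "dt",
        "n_tracks", "mean_track_len",
    },
    "simulate-mreb": {
        "speed_nm_s", "interval_s", "n_tracks", "track_len", "sigma_loc",
        "cell_length", "cell_diameter",
    },
    "link": {"max_disp", "max_gap", "dt", "pixel_size", "cap_last"},
    "fit-spt": {"lags", "fix_d_bound", "method", "n_boot", "dt"},
    "mreb-flux": {"sigma_smooth", "min_localizations", "min_end_to_end",
                  "duration", "total_area"},
    "growth": {"dw_min", "min_points"},
    "shock": {"n_perm"},
    "crosslink": set(),
}


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration, rejecting unknown keys."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    allowed = {"stage", "inputs", "params", "seed", "outdir"}
    unknown = set(raw) - allowed
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _validate(config: RunConfig) -> None:
    if config.stage not in STAGES:
        raise ParameterError(
            f"unknown stage {config.stage!r}; choose from {sorted(STAGES)}"
        )
    unknown = set(config.params) - STAGES[config.stage]
    if unknown:
        raise ParameterError(
            f"unknown parameter keys for stage {config.stage!r}: {sorted(unknown)}"
        )
    for key, path in config.inputs.items():
        if not Path(path).exists():
            raise ParameterError(f"input {key!r} does not exist: {path}")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute one stage end-to-end; return the artifact manifest."""
    _validate(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    artifacts: list[Path] = []

    if config.stage == "simulate-spt":
        params = TwoStateParams(
            f_bound=p.get("f_bound", 0.2),
            d_free=p.get("d_free", 0.075),
            d_bound=p.get("d_bound", 0.0),
            sigma_loc=p.get("sigma_loc", 0.035),
            dt=p.get("dt", 0.06),
        )
        ts, gt = synthetic.simulate_two_state_tracks(
            params,
            n_tracks=p.get("n_tracks", 500),
            mean_track_len=p.get("mean_track_len", 8),
            seed=config.seed,
        )
        artifacts.append(mio.write_tracks_csv(ts, outdir / "tracks.csv"))
        artifacts.append(
            mio.write_json(
                {
                    "params": vars(params) | {},
                    "seed": config.seed,
                    "config_hash": config.config_hash(),
                    "n_tracks": len(ts),
                },
                outdir / "ground_truth_config.json",
            )
        )

    elif config.stage == "simulate-mreb":
        from .containers import CellGeometry

        geom = CellGeometry(
            length=p.get("cell_length", 3.0), diameter=p.get("cell_diameter", 0.9)
        )
        ts, gt = synthetic.simulate_directed_tracks(
            speed=p.get("speed_nm_s", 10.0),
            interval=p.get("interval_s", 2.0),
            n_tracks=p.get("n_tracks", 50),
            track_len=p.get("track_len", 20),
            sigma_loc=p.get("sigma_loc", 0.02),
            geometry=geom,
            seed=config.seed,
        )
        artifacts.append(mio.write_tracks_csv(ts, outdir / "tracks.csv"))

    elif config.stage == "link":
        spots = mio.read_spots_csv(config.inputs["spots"])
        if "cap_last" in p:
            spots = tracking.cap_detections(spots, p["cap_last"])
        ts = tracking.link_spots(
            spots,
            max_disp=p.get("max_disp", 0.3),
            max_gap=p.get("max_gap", 2),
            dt=p.get("dt", 0.06),
            pixel_size=p.get("pixel_size", 0.065),
        )
        artifacts.append(mio.write_tracks_csv(ts, outdir / "tracks.csv"))

    elif config.stage == "fit-spt":
        ts = mio.read_tracks_csv(config.inputs["tracks"], dt=p.get("dt", 0.06))
        sample = spt.collect_jumps(ts, lags=tuple(p.get("lags", [1])))
        fit = spt.fit_two_state(
            sample,
            fix_d_bound=p.get("fix_d_bound", True),
            method=p.get("method", "mle"),
            n_boot=p.get("n_boot", 0),
            seed=config.seed,
        )
        artifacts.append(
            mio.write_json(
                fit.as_dict() | {"seed": config.seed, "config_hash": config.config_hash()},
                outdir / "two_state_fit.json",
            )
        )

    elif config.stage == "mreb-flux":
        ts = mio.read_tracks_csv(config.inputs["tracks"], dt=2.0)
        smoothed = tracking.smooth_tracks(ts, sigma=p.get("sigma_smooth", 1.5))
        filtered = tracking.filter_tracks(
            smoothed, min_localizations=p.get("min_localizations", 8)
        )
        velocities = mreb.velocity_distribution(filtered)
        result = mreb.flux_statistic(
            filtered,
            min_end_to_end=p.get("min_end_to_end", 0.2),
            duration=p.get("duration", 120.0),
            total_area=p.get("total_area", 1.0),
        )
        artifacts.append(
            mio.write_json(
                {
                    "flux_um_per_s_per_um2": result.flux,
                    "n_qualifying_tracks": result.n_qualifying_tracks,
                    "median_velocity_nm_s": float(np.median(velocities))
                    if len(velocities)
                    else None,
                    "seed": config.seed,
                    "config_hash": config.config_hash(),
                },
                outdir / "flux.json",
            )
        )

    elif config.stage == "growth":
        import pandas as pd

        df = pd.read_csv(config.inputs["od"])
        from .containers import GrowthCurve

        curve = GrowthCurve(times=df["time_min"].to_numpy(), od=df["od"].to_numpy())
        fit = kinetics.fit_doubling_time(
            curve, dw_min=p.get("dw_min", 1.0), min_points=p.get("min_points", 6)
        )
        artifacts.append(
            mio.write_json(
                {
                    "doubling_time_min": fit.doubling_time,
                    "window": fit.window,
                    "dw": fit.dw,
                    "seed": config.seed,
                    "config_hash": config.config_hash(),
                },
                outdir / "growth_fit.json",
            )
        )

    elif config.stage == "shock":
        import pandas as pd

        table = pd.read_csv(config.inputs["dimensions"])
        ratios = kinetics.shock_extension(table)
        out = outdir / "extension_ratios.csv"
        ratios.to_csv(out, index=False, float_format="%.12g")
        artifacts.append(out)
        if "group" in ratios.columns and ratios["group"].nunique() == 2:
            g1, g2 = sorted(ratios["group"].unique())
            p_short = kinetics.permutation_test_median_diff(
                ratios.loc[ratios["group"] == g1, "short_ratio"].to_numpy(),
                ratios.loc[ratios["group"] == g2, "short_ratio"].to_numpy(),
                n_perm=p.get("n_perm", 10000),
                seed=config.seed,
            )
            artifacts.append(
                mio.write_json(
                    {"p_short": p_short, "groups": [str(g1), str(g2)],
                     "seed": config.seed, "config_hash": config.config_hash()},
                    outdir / "shock_test.json",
                )
            )

    elif config.stage == "crosslink":
        import pandas as pd

        df = pd.read_csv(config.inputs["profile"])
        fractions = dict(zip(df["species"], df["molar_fraction"]))
        profile = kinetics.MuropeptideProfile(
            monomers=fractions.get("monomers", 0.0),
            dimers=fractions.get("dimers", 0.0),
            trimers=fractions.get("trimers", 0.0),
            others=fractions.get("others", 0.0),
        )
        percent, clipped = kinetics.crosslink_percentage(profile)
        artifacts.append(
            mio.write_json(
                {"crosslink_percent": percent, "clipped": clipped,
                 "seed": config.seed, "config_hash": config.config_hash()},
                outdir / "crosslink.json",
            )
        )

    manifest = {
        "stage": config.stage,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "artifacts": {str(a): _hash_file(a) for a in artifacts},
    }
    mio.write_json(manifest, outdir / f"manifest_{config.stage}.json")
    return manifest
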