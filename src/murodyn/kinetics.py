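"""Growth, incorporation, osmotic-shock and cross-linking computations.

* doubling time: exponential (log-linear) fit with a Durbin-Watson gate
  that rejects windows contaminated by lag or stationary phase;
* radiolabel incorporation: joint fit of per-culture incorporation
  rates kin with a single shared turnover rate kout, given prefitted
  growth rates gamma, under S(t) = kin/(gamma+kout)*(1-exp(-(gamma+kout)t));
* osmotic downshock: per-cell post/pre extension ratios and a two-sided
  permutation test on the difference of group medians;
* peptidoglycan cross-linking: percent = dimers + 2 x trimers (molar
  fractions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import optimize

from .containers import GrowthCurve, IncorporationSeries, ParameterError
from .synthetic import incorporation_signal

__all__ = [
    "KineticFitResult",
    "MuropeptideProfile",
    "fit_doubling_time",
    "fit_incorporation_model",
    "shock_extension",
    "permutation_test_median_diff",
    "crosslink_percentage",
    "normalize_od_at_event",
    "durbin_watson",
]

EXHAUSTIVE_LIMIT = 10**6


class KineticFitError(RuntimeError):
    """A kinetic fit failed; carries the best-candidate diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class KineticFitResult:
    """Fitted kinetic parameters with the data window and diagnostics."""

    doubling_time: float | None = None
    kin: dict = field(default_factory=dict)
    kout: float | None = None
    gamma: dict = field(default_factory=dict)
    window: tuple[int, int] | None = None
    dw: float | None = None
    residual_sd: float | None = None


@dataclass(frozen=True)
class MuropeptideProfile:
    """Relative molar fractions of muropeptide classes (sum to 1)."""

    monomers: float
    dimers: float
    trimers: float
    others: float = 0.0

    def __post_init__(self) -> None:
        total = self.monomers + self.dimers + self.trimers + self.others
        if abs(total - 1.0) > 1e-6:
            raise ParameterError(f"fractions must sum to 1, got {total}")
        if min(self.monomers, self.dimers, self.trimers, self.others) < 0:
            raise ParameterError("fractions must be >= 0")


def durbin_watson(residuals: np.ndarray) -> float:
    """Durbin-Watson statistic: ~2 for uncorrelated residuals, <1 when
    consecutive residuals are positively correlated (bad fit window)."""
    residuals = np.asarray(residuals, dtype=float)
    denom = float(np.sum(residuals**2))
    if denom == 0.0:
        return 2.0  # perfect fit: treat as uncorrelated
    return float(np.sum(np.diff(residuals) ** 2) / denom)


def fit_doubling_time(
    curve: GrowthCurve, dw_min: float = 1.0, min_points: int = 6, min_fold: float = 2.0
) -> KineticFitResult:
    """Doubling time from a log-linear fit on a Durbin-Watson-gated window.

    Contiguous windows are scanned longest-first (earliest start first
    among equal lengths); the first window whose log(OD) residuals give
    a Durbin-Watson statistic above ``dw_min`` and a positive slope is
    accepted. A window must also span at least ``min_fold``-fold growth
    (one doubling by default) so that near-flat lag or stationary
    stretches, where any line fits with uncorrelated residuals, cannot
    masquerade as exponential phase. doubling_time = ln 2 / slope
    (minutes).
    """
    n = len(curve.times)
    if n < min_points:
        raise ParameterError(f"need at least {min_points} points, got {n}")
    if np.any(curve.od <= 0):
        positive = curve.od > 0
    else:
        positive = np.ones(n, dtype=bool)

    best_diag = None
    for length in range(n, min_points - 1, -1):
        for start in range(0, n - length + 1):
            sl = slice(start, start + length)
            if not positive[sl].all():
                continue
            if curve.od[sl][-1] < min_fold * curve.od[sl][0]:
                continue
            t = curve.times[sl]
            y = np.log(curve.od[sl])
            slope, intercept = np.polyfit(t, y, 1)
            resid = y - (slope * t + intercept)
            # residuals at float rounding level: a perfect exponential, for
            # which the DW ratio of rounding noise is meaningless
            if np.abs(resid).max() <= 1e-9 * max(1.0, np.abs(y).max()):
                dw = 2.0
            else:
                dw = durbin_watson(resid)
            diag = {
                "window": (start, start + length),
                "dw": dw,
                "slope": slope,
            }
            if best_diag is None or dw > best_diag["dw"]:
                best_diag = diag
            if dw > dw_min:
                if slope <= 0:
                    raise KineticFitError(
                        f"accepted window has non-positive growth rate {slope:.3g}", diag
                    )
                return KineticFitResult(
                    doubling_time=float(np.log(2.0) / slope),
                    gamma={"": float(slope)},
                    window=(start, start + length),
                    dw=float(dw),
                    residual_sd=float(resid.std()),
                )
    raise KineticFitError(
        f"no contiguous window of >= {min_points} points passes DW > {dw_min}", best_diag
    )


def fit_incorporation_model(
    series_by_culture: list[IncorporationSeries],
    gamma_by_culture: list[float] | None = None,
) -> KineticFitResult:
    """Joint incorporation fit: per-culture kin, one shared kout.

    For a fixed kout the model is linear in each kin, so the profiled
    sum of squares is minimized over kout alone (bounded scalar search
    bracketed by candidate starts kout in {0, gamma/10, gamma}); the
    per-culture kin follow in closed form. gamma values are the
    prefitted exponential growth rates (1/min).
    """
    if not series_by_culture:
        raise ParameterError("need at least one culture")
    if gamma_by_culture is None:
        gamma_by_culture = [s.gamma for s in series_by_culture]
    if any(g is None or g <= 0 for g in gamma_by_culture):
        raise ParameterError("every culture needs a positive prefitted gamma")
    for s in series_by_culture:
        if len(s.times) < 3:
            raise ParameterError("need >= 3 time points per culture")

    gammas = np.asarray(gamma_by_culture, dtype=float)

    def kin_and_ssr(kout: float):
        kins = []
        ssr = 0.0
        for s, g in zip(series_by_culture, gammas):
            basis = incorporation_signal(s.times, 1.0, kout, g)
            denom = float(basis @ basis)
            kin = float(basis @ s.signal) / denom if denom > 0 else 0.0
            kin = max(kin, 0.0)
            ssr += float(np.sum((kin * basis - s.signal) ** 2))
            kins.append(kin)
        return kins, ssr

    gbar = float(gammas.mean())
    candidates = [0.0, gbar / 10.0, gbar]
    upper = 50.0 * gbar
    best_kout, best_ssr = None, np.inf
    for lo, hi in [(0.0, gbar), (0.0, upper)]:
        res = optimize.minimize_scalar(
            lambda k: kin_and_ssr(k)[1], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12},
        )
        if res.fun < best_ssr:
            best_kout, best_ssr = float(res.x), float(res.fun)
    for k in candidates:
        _, ssr = kin_and_ssr(k)
        if ssr < best_ssr:
            best_kout, best_ssr = float(k), float(ssr)
    if best_kout is None:
        raise KineticFitError("incorporation fit failed", {"candidates": candidates})

    kins, ssr = kin_and_ssr(best_kout)
    n_total = sum(len(s.times) for s in series_by_culture)
    labels = [s.label or str(i) for i, s in enumerate(series_by_culture)]
    return KineticFitResult(
        kin={lab: k for lab, k in zip(labels, kins)},
        kout=best_kout,
        gamma={lab: float(g) for lab, g in zip(labels, gammas)},
        residual_sd=float(np.sqrt(ssr / max(n_total - len(kins) - 1, 1))),
    )


def shock_extension(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell post/pre extension ratios for both axes.

    Expects columns pre_short_um, post_short_um, pre_long_um,
    post_long_um (plus an optional cell/group column). Rows with any
    missing value are dropped with a warning column in the result
    metadata; a ratio of 1 is no extension.
    """
    required = ["pre_short_um", "post_short_um", "pre_long_um", "post_long_um"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ParameterError(f"missing columns: {missing}")
    complete = table.dropna(subset=required)
    out = pd.DataFrame(index=complete.index)
    if "cell" in complete.columns:
        out["cell"] = complete["cell"]
    if "group" in complete.columns:
        out["group"] = complete["group"]
    out["short_ratio"] = complete["post_short_um"] / complete["pre_short_um"]
    out["long_ratio"] = complete["post_long_um"] / complete["pre_long_um"]
    out.attrs["n_dropped"] = len(table) - len(complete)
    return out


def permutation_test_median_diff(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> float:
    """Two-sided permutation test on |median(a) - median(b)|.

    All C(n_a + n_b, n_a) relabelings are enumerated when feasible
    (up to ``exhaustive_limit``); otherwise ``n_perm`` Monte-Carlo
    permutations with the add-one correction
    p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n_a = len(a)
    observed = abs(np.median(a) - np.median(b))
    tol = 1e-12 * max(1.0, abs(observed))

    n = len(pooled)
    if comb(n, n_a) <= exhaustive_limit:
        idx = np.fromiter(
            (i for c in combinations(range(n), n_a) for i in c), dtype=np.intp
        ).reshape(-1, n_a)
        sel = np.zeros((len(idx), n), dtype=bool)
        np.put_along_axis(sel, idx, True, axis=1)
        med_a = np.median(pooled[idx], axis=1)
        med_b = np.median(
            np.broadcast_to(pooled, sel.shape)[~sel].reshape(len(idx), n - n_a), axis=1
        )
        stats = np.abs(med_a - med_b)
        return float(np.count_nonzero(stats >= observed - tol) / len(idx))

    if n_perm < 100:
        raise ParameterError("n_perm must be >= 100 in Monte-Carlo mode")
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(pooled, (n_perm, n)), axis=1)
    stats = np.abs(np.median(perms[:, :n_a], axis=1) - np.median(perms[:, n_a:], axis=1))
    count = int(np.count_nonzero(stats >= observed - tol))
    return (1 + count) / (1 + n_perm)


def crosslink_percentage(profile: MuropeptideProfile) -> tuple[float, bool]:
    """Peptidoglycan cross-linking index: dimers% + 2 x trimers%.

    Dimeric muropeptides carry one cross-link and trimeric two, so the
    molar fractions combine to the percentage of cross-linked peptides.
    Returns (percent, clipped_flag); the flag marks the (degenerate)
    case of a nominal value above 100%.
    """
    percent = 100.0 * (profile.dimers + 2.0 * profile.trimers)
    return percent, percent > 100.0


def normalize_od_at_event(curves: list[GrowthCurve], event_time: float) -> list[GrowthCurve]:
    """Scale growth curves to share one OD at an event (e.g. a shock).

    Each curve is multiplied by a scalar so that, at ``event_time``
    (linearly interpolated), all curves equal the reference OD: the mean
    of the pre-scaling values there. Scaling leaves each curve's
    doubling time unchanged.
    """
    if not curves:
        return []
    at_event = []
    for c in curves:
        if not (c.times[0] <= event_time <= c.times[-1]):
            raise ParameterError("event_time outside a curve's time range")
        v = float(np.interp(event_time, c.times, c.od))
        if v == 0.0:
            raise ParameterError("zero OD at the event time")
        at_event.append(v)
    reference = float(np.mean(at_event))
    return [
        GrowthCurve(times=c.times.copy(), od=c.od * (reference / v), meta=dict(c.meta))
        for c, v in zip(curves, at_event)
    ]
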