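"""Image filtering, spot localization and rod segmentation.

Two detection paths are supported:

* the single-particle-tracking path: bandpass -> local maxima ->
  subpixel refinement by 2-D Gaussian least squares;
* the directed-motion (MreB) path: bandpass -> 5x spline upsampling ->
  local maxima inside the cell boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.interpolate import RectBivariateSpline
from skimage import measure
from skimage.filters import threshold_otsu

from .containers import DEFAULT_PIXEL_SIZE_UM, ParameterError, Spot

__all__ = [
    "bandpass_filter",
    "upsample_spline",
    "detect_spots",
    "segment_rods",
    "DetectionDiagnostics",
]


def bandpass_filter(image: np.ndarray, lowpass: float = 0.5, highpass: float = 100.0) -> np.ndarray:
    """Suppress pixel noise below ``lowpass`` and background above ``highpass``.

    Difference of two Gaussian smoothings (scales lowpass and highpass,
    in pixels); negative values are clipped to zero, so a constant image
    maps to zero everywhere.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ParameterError("image contains non-finite pixels")
    if not 0 < lowpass < highpass:
        raise ParameterError("require 0 < lowpass < highpass")
    smoothed = ndimage.gaussian_filter(image, lowpass, mode="nearest")
    background = ndimage.gaussian_filter(image, highpass, mode="nearest")
    return np.clip(smoothed - background, 0.0, None)


def upsample_spline(image: np.ndarray, factor: int = 5) -> np.ndarray:
    """Rescale an image by an integer factor with bicubic spline interpolation.

    The interpolant reproduces the input values at the original grid
    points, which land at every ``factor``-th output pixel.
    """
    if factor < 1 or int(factor) != factor:
        raise ParameterError("factor must be an integer >= 1")
    image = np.asarray(image, dtype=float)
    if factor == 1:
        return image.copy()
    h, w = image.shape
    ky = min(3, h - 1)
    kx = min(3, w - 1)
    spline = RectBivariateSpline(np.arange(h), np.arange(w), image, kx=kx, ky=ky, s=0)
    rows = np.arange(h * factor) / factor
    cols = np.arange(w * factor) / factor
    return spline(rows, cols)


@dataclass
class DetectionDiagnostics:
    """Bookkeeping for spots dropped during refinement."""

    n_candidates: int = 0
    n_fit_failures: int = 0
    n_outside_mask: int = 0
    n_below_background: int = 0
    notes: list[str] = field(default_factory=list)


def _local_maxima(image: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Strict-ish local maxima above threshold with a deterministic order.

    Plateau ties are resolved by keeping the representative with higher
    filtered intensity, then lower row, then lower column.
    """
    footprint = np.ones((3, 3), dtype=bool)
    maxed = ndimage.maximum_filter(image, footprint=footprint, mode="nearest")
    candidates = np.argwhere((image >= maxed) & (image > threshold))
    order = np.lexsort((candidates[:, 1], candidates[:, 0], -image[tuple(candidates.T)]))
    seen = np.zeros(image.shape, dtype=bool)
    keep: list[tuple[int, int]] = []
    for idx in order:
        r, c = candidates[idx]
        if seen[max(r - 1, 0) : r + 2, max(c - 1, 0) : c + 2].any():
            continue
        seen[r, c] = True
        keep.append((int(r), int(c)))
    return keep


def _gaussian_model(params: np.ndarray, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    offset, amp, row0, col0, sigma = params
    return offset + amp * np.exp(-((rr - row0) ** 2 + (cc - col0) ** 2) / (2.0 * sigma**2))


def _fit_gaussian(image: np.ndarray, r: int, c: int, window: int = 7):
    """Least-squares isotropic Gaussian fit in a window around (r, c).

    Returns (row, col, amplitude, sigma, rms_residual) or None on failure.
    """
    half = window // 2
    r0, r1 = max(r - half, 0), min(r + half + 1, image.shape[0])
    c0, c1 = max(c - half, 0), min(c + half + 1, image.shape[1])
    patch = image[r0:r1, c0:c1]
    if patch.size < 9:
        return None
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    p0 = np.array([float(patch.min()), float(patch[r - r0, c - c0] - patch.min()), r, c, 1.3])

    def resid(p):
        return (_gaussian_model(p, rr, cc) - patch).ravel()

    try:
        sol = optimize.least_squares(
            resid,
            p0,
            bounds=([-np.inf, 0.0, r0 - 1, c0 - 1, 0.3], [np.inf, np.inf, r1, c1, window]),
            max_nfev=200,
        )
    except Exception:
        return None
    if not sol.success and sol.status <= 0:
        return None
    offset, amp, row, col, sigma = sol.x
    if not (r0 - 1 <= row <= r1 and c0 - 1 <= col <= c1) or amp <= 0:
        return None
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return float(row), float(col), float(amp), float(sigma), rms, float(offset)


def detect_spots(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    threshold_mode: str = "auto",
    threshold: float | None = None,
    min_above_background: bool = False,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    frame: int = 0,
    lowpass: float = 0.5,
    highpass: float = 100.0,
    fit_window: int = 7,
    diagnostics: DetectionDiagnostics | None = None,
) -> list[Spot]:
    """Localize fluorescent spots to subpixel precision.

    Candidate local maxima of the band-passed image above the threshold
    (auto mode: the standard deviation of the band-passed image, a
    first-level noise statistic) are refined with a 2-D Gaussian
    least-squares fit in a ``fit_window`` x ``fit_window`` window. Spots
    whose fitted centre falls outside ``mask`` are dropped, as are, with
    ``min_above_background``, spots whose amplitude does not exceed the
    in-mask median intensity. Returned coordinates are in micrometres
    (x along columns, y along rows; pixel centre convention).
    """
    image = np.asarray(image, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.shape:
            raise ParameterError("mask shape must match image shape")
    diag = diagnostics if diagnostics is not None else DetectionDiagnostics()

    filtered = bandpass_filter(image, lowpass=lowpass, highpass=highpass)
    if threshold_mode == "auto":
        thr = float(np.std(filtered))
    elif threshold_mode == "value":
        if threshold is None:
            raise ParameterError("threshold_mode='value' requires a threshold")
        thr = float(threshold)
    else:
        raise ParameterError(f"unknown threshold_mode {threshold_mode!r}")
    if thr <= 0:
        return []

    maxima = _local_maxima(filtered, thr)
    diag.n_candidates += len(maxima)
    background = float(np.median(image[mask])) if (mask is not None and mask.any()) else float(
        np.median(image)
    )

    spots: list[Spot] = []
    for r, c in maxima:
        fit = _fit_gaussian(image, r, c, window=fit_window)
        if fit is None:
            diag.n_fit_failures += 1
            continue
        row, col, amp, sigma, rms, offset = fit
        ri, ci = int(round(row)), int(round(col))
        if not (0 <= ri < image.shape[0] and 0 <= ci < image.shape[1]):
            diag.n_fit_failures += 1
            continue
        if mask is not None and not mask[ri, ci]:
            diag.n_outside_mask += 1
            continue
        if min_above_background and offset + amp <= background:
            diag.n_below_background += 1
            continue
        quality = amp / (rms + 1e-12)
        spots.append(
            Spot(
                frame=frame,
                x=(col + 0.5) * pixel_size,
                y=(row + 0.5) * pixel_size,
                amplitude=amp,
                sigma=sigma,
                quality=quality,
            )
        )
    return spots


def segment_rods(phase_image: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Threshold-segment dark rod-shaped cells in a phase-contrast image.

    Returns (masks, contours): one boolean mask and one closed contour
    (n, 2) array in (row, col) pixels per kept cell. Components touching
    the image border, or touching another component after a 1-px
    dilation (cells in close proximity), are discarded.
    """
    image = np.asarray(phase_image, dtype=float)
    if image.max() == image.min():
        return [], []
    thr = threshold_otsu(image)
    cells = image < thr  # dark in phase contrast
    labels, n = ndimage.label(cells)
    if n == 0:
        return [], []

    structure = np.ones((3, 3), dtype=bool)
    dilated = {
        lab: ndimage.binary_dilation(labels == lab, structure=structure)
        for lab in range(1, n + 1)
    }
    keep = []
    for lab in range(1, n + 1):
        mask = labels == lab
        rows, cols = np.where(mask)
        if (
            rows.min() == 0
            or cols.min() == 0
            or rows.max() == image.shape[0] - 1
            or cols.max() == image.shape[1] - 1
        ):
            continue
        # cells whose 1-px dilations touch are in close proximity: drop both
        if any(np.any(dilated[lab] & dilated[other]) for other in dilated if other != lab):
            continue
        keep.append(mask)

    masks: list[np.ndarray] = []
    contours: list[np.ndarray] = []
    for mask in keep:
        cs = measure.find_contours(mask.astype(float), 0.5)
        if not cs:
            continue
        masks.append(mask)
        contours.append(max(cs, key=len))
    return masks, contours
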