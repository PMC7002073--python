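"""Cell morphometrics and illumination-corrected fluorescence.

A cell is represented by its closed contour (um coordinates). The major
axis is the total-least-squares (orthogonal regression) line through
the contour vertices; polar regions are vertices whose local curvature
exceeds a threshold; cell width is twice the mean contour-to-axis
distance of the non-polar vertices and length is the spread of vertex
projections along the axis. Fluorescence concentration integrates the
illumination-corrected signal over the (dilated) in-contour pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .containers import ParameterError

__all__ = [
    "CellContour",
    "CellShapeRecord",
    "FluorescenceField",
    "fit_cell_axis",
    "detect_poles",
    "measure_dimensions",
    "correct_illumination",
    "quantify_cell_fluorescence",
    "sharpness_score",
    "rectangle_contour",
    "spherocylinder_contour",
]


class DegenerateAxisError(ValueError):
    """The contour has no preferred direction (principal values ~equal)."""


@dataclass
class CellContour:
    """Closed (x, y) polyline in micrometres (last vertex != first)."""

    vertices: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ParameterError("vertices must be (n, 2)")
        if len(self.vertices) < 8:
            raise ParameterError("contour needs >= 8 vertices")

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class CellShapeRecord:
    """Per-cell morphometric and fluorescence summary."""

    length: float
    diameter: float
    axis_point: tuple[float, float]
    axis_direction: tuple[float, float]
    pole_vertex_indices: list[int] = field(default_factory=list)
    area: float = np.nan
    sharpness: float = np.nan
    concentration: float = np.nan
    quality_flags: list[str] = field(default_factory=list)


@dataclass
class FluorescenceField:
    """Raw fluorescence, illumination correction and background mask.

    f is the raw image, I a multiplicative flat-field correction factor
    (same shape), bg a boolean mask of cell-free background pixels.
    """

    f: np.ndarray
    I: np.ndarray  # noqa: E741 - field name mirrors the correction factor symbol
    bg: np.ndarray
    autofluorescence: float = 0.0

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.bg = np.asarray(self.bg, dtype=bool)
        if self.f.shape != self.I.shape or self.f.shape != self.bg.shape:
            raise ParameterError("f, I and bg must share one shape")


def fit_cell_axis(contour: CellContour) -> tuple[np.ndarray, np.ndarray]:
    """Major axis by total (orthogonal) regression on the contour vertices.

    Returns (point, unit direction); the direction sign is normalized to
    positive x (ties broken toward positive y). Raises
    DegenerateAxisError when the two principal values are within 1%.
    """
    pts = contour.vertices
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[0] <= 0 or (svals[0] - svals[1]) / svals[0] < 0.01:
        raise DegenerateAxisError("contour is isotropic; no major axis")
    direction = vt[0]
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction
    return centroid, direction


def _circumscribed_curvature(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Curvature 1/R of the circle through three points (0 if collinear)."""
    a = np.linalg.norm(p2 - p1)
    b = np.linalg.norm(p3 - p2)
    c = np.linalg.norm(p3 - p1)
    cross = abs((p2[0] - p1[0]) * (p3[1] - p1[1]) - (p2[1] - p1[1]) * (p3[0] - p1[0]))
    denom = a * b * c
    if denom == 0:
        return 0.0
    return 2.0 * cross / denom


def detect_poles(
    contour: CellContour,
    curvature_threshold: float | None = None,
) -> tuple[list[int], list[str]]:
    """Vertices whose local curvature exceeds the threshold (the poles).

    Discrete curvature uses the circumscribed circle through each vertex
    and its +/-2 neighbours (cyclic). The default threshold is
    1 / diameter_estimate, i.e. half the curvature of a hemispherical
    cap (about 2/diameter), so caps clear it comfortably while the
    straight flanks (curvature near zero) stay below. Returns
    (pole indices, quality flags); rods should produce exactly two
    connected pole arcs, anything else is flagged.
    """
    pts = contour.vertices
    n = len(pts)
    if curvature_threshold is None:
        point, direction = fit_cell_axis(contour)
        dists = _perp_distances(pts, point, direction)
        diameter_estimate = 2.0 * dists.mean()
        curvature_threshold = 1.0 / diameter_estimate
    if curvature_threshold <= 0:
        raise ParameterError("curvature_threshold must be > 0")

    kappa = np.array(
        [
            _circumscribed_curvature(pts[(i - 2) % n], pts[i], pts[(i + 2) % n])
            for i in range(n)
        ]
    )
    polar = kappa > curvature_threshold
    # pole regions are contiguous on a rod contour: absorb single-vertex
    # gaps (e.g. the flat midpoint of a squared-off end between two corners)
    polar = polar | (np.roll(polar, 1) & np.roll(polar, -1))
    indices = np.where(polar)[0].tolist()

    flags: list[str] = []
    if indices:
        # count connected arcs on the cyclic index set
        idx_set = set(indices)
        arcs = sum(1 for i in indices if (i - 1) % n not in idx_set)
        if len(indices) == n:
            arcs = 1
        if arcs != 2:
            flags.append(f"expected 2 pole arcs, found {arcs}")
    else:
        flags.append("no polar vertices found")
    return indices, flags


def _perp_distances(pts: np.ndarray, point: np.ndarray, direction: np.ndarray) -> np.ndarray:
    rel = pts - point
    normal = np.array([-direction[1], direction[0]])
    return np.abs(rel @ normal)


def measure_dimensions(
    contour: CellContour,
    axis: tuple[np.ndarray, np.ndarray] | None = None,
    poles: list[int] | None = None,
) -> tuple[float, float]:
    """Cell length and diameter from contour, axis and pole set.

    length = spread (max - min) of vertex projections on the axis;
    diameter = 2 x mean perpendicular distance of the non-polar vertices
    to the axis (the doubling turns the literal half-width into a
    diameter).
    """
    if axis is None:
        axis = fit_cell_axis(contour)
    if poles is None:
        poles, _ = detect_poles(contour)
    point, direction = axis
    pts = contour.vertices
    proj = (pts - point) @ direction
    length = float(proj.max() - proj.min())
    keep = np.ones(len(pts), dtype=bool)
    keep[list(poles)] = False
    if not keep.any():
        raise ParameterError("all vertices are polar; cannot measure width")
    diameter = float(2.0 * _perp_distances(pts[keep], point, direction).mean())
    return length, diameter


def correct_illumination(field: FluorescenceField) -> np.ndarray:
    """Flat-field and background-correct a fluorescence image.

    corrected = f * I - < f * I >_bg, the mean taken over the cell-free
    background mask only, so the corrected background averages to zero.
    """
    if not field.bg.any():
        raise ParameterError("background mask is empty")
    product = field.f * field.I
    return product - product[field.bg].mean()


def quantify_cell_fluorescence(
    corrected: np.ndarray,
    contour: CellContour,
    dilation_px: int = 1,
    autofluorescence: float = 0.0,
    pixel_size: float = 0.065,
) -> float:
    """Mean corrected intensity over the dilated in-contour pixels.

    The contour is rasterized, dilated by ``dilation_px`` (3x3
    structuring element per pixel, to capture membrane-proximal signal),
    and the mean corrected intensity minus the autofluorescence level is
    returned. The value may be negative; it is not clamped.
    """
    if dilation_px < 0:
        raise ParameterError("dilation_px must be >= 0")
    # um -> pixel index space (pixel centre convention)
    cols = contour.vertices[:, 0] / pixel_size - 0.5
    rows = contour.vertices[:, 1] / pixel_size - 0.5
    if (
        cols.min() < -0.5
        or rows.min() < -0.5
        or cols.max() > corrected.shape[1] - 0.5
        or rows.max() > corrected.shape[0] - 0.5
    ):
        raise ParameterError("contour extends outside the image")
    rr, cc = draw_polygon(rows, cols, shape=corrected.shape)
    mask = np.zeros(corrected.shape, dtype=bool)
    mask[rr, cc] = True
    for _ in range(dilation_px):
        mask = ndimage.binary_dilation(mask, structure=np.ones((3, 3), dtype=bool))
    if not mask.any():
        raise ParameterError("contour rasterizes to an empty pixel set")
    return float(corrected[mask].mean() - autofluorescence)


def sharpness_score(
    image: np.ndarray,
    contour: CellContour | None = None,
    pixel_size: float = 0.065,
) -> float:
    """Variance of the gradient magnitude, optionally inside a contour.

    Used to filter out-of-focus cells in phase contrast: blurring
    reduces gradients and hence the score. Adding a constant intensity
    leaves the score unchanged.
    """
    image = np.asarray(image, dtype=float)
    gy, gx = np.gradient(image)
    grad_mag = np.hypot(gx, gy)
    if contour is None:
        return float(grad_mag.var())
    cols = contour.vertices[:, 0] / pixel_size - 0.5
    rows = contour.vertices[:, 1] / pixel_size - 0.5
    rr, cc = draw_polygon(rows, cols, shape=image.shape)
    if len(rr) == 0:
        raise ParameterError("contour rasterizes to an empty pixel set")
    return float(grad_mag[rr, cc].var())


def rectangle_contour(
    length: float,
    width: float,
    n_per_side: int = 50,
    n_end: int = 1,
    center=(0.0, 0.0),
    angle: float = 0.0,
) -> CellContour:
    """Densely sampled rectangular contour (for validation and fixtures).

    The point set is symmetric under both reflections, so the orthogonal
    regression axis of the axis-aligned rectangle is exactly (1, 0).
    Ends are sampled sparsely (n_end points) so that, through the +/-2
    neighbour curvature window, each short side reads as one polar arc.
    """
    hl, hw = length / 2.0, width / 2.0
    xs = np.linspace(-hl, hl, n_per_side)[1:-1]
    ys = np.linspace(-hw, hw, n_end + 2)[1:-1]
    pts = np.concatenate(
        [
            np.column_stack([xs, np.full_like(xs, -hw)]),
            [[hl, -hw]],
            np.column_stack([np.full_like(ys, hl), ys]),
            [[hl, hw]],
            np.column_stack([xs[::-1], np.full_like(xs, hw)]),
            [[-hl, hw]],
            np.column_stack([np.full_like(ys, -hl), ys[::-1]]),
            [[-hl, -hw]],
        ]
    )
    c, s = np.cos(angle), np.sin(angle)
    pts = pts @ np.array([[c, s], [-s, c]])
    return CellContour(vertices=pts + np.asarray(center))


def spherocylinder_contour(
    length: float, radius: float, n_flank: int = 60, n_cap: int = 30, center=(0.0, 0.0)
) -> CellContour:
    """Rod contour: two straight flanks joined by semicircular caps.

    length is the total tip-to-tip length (cylindrical part has length
    ``length - 2 * radius``).
    """
    if length < 2 * radius:
        raise ParameterError("length must be >= 2 * radius")
    hl = length / 2.0 - radius
    xs = np.linspace(-hl, hl, n_flank, endpoint=False)
    th_right = np.linspace(-np.pi / 2, np.pi / 2, n_cap, endpoint=False)
    th_left = np.linspace(np.pi / 2, 3 * np.pi / 2, n_cap, endpoint=False)
    pts = np.concatenate(
        [
            np.column_stack([xs, np.full_like(xs, -radius)]),
            np.column_stack([hl + radius * np.cos(th_right), radius * np.sin(th_right)]),
            np.column_stack([xs[::-1], np.full_like(xs, radius)]),
            np.column_stack([-hl + radius * np.cos(th_left), radius * np.sin(th_left)]),
        ]
    )
    return CellContour(vertices=pts + np.asarray(center))
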