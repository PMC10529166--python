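"""Blue fiducial-marker detection and pixel-to-cm^2 calibration.

A 2 cm x 2 cm blue square placed in-plane with the wound provides the
physical scale: the photograph is converted to HSV, thresholded to a
blue mask, each connected component's contour is simplified to a
quadrilateral, and the candidate whose quadrilateral area best matches
its thresholded pixel area is selected.  Placement quality is gated by
two scores before the scale is trusted:

* proportionality — shortest side over longest side of the fitted
  quadrilateral; 1 for a perfect square, small for elongated shapes;
* asymmetry — the larger of the relative length mismatches between the
  two pairs of opposite sides; 0 for any parallelogram (so in-plane
  rotation is free) and growing with perspective foreshortening.

When the marker passes QC, one pixel corresponds to
``4 cm^2 / quad_area_px`` and wound areas convert by multiplication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv
from skimage.measure import approximate_polygon, find_contours, label as cc_label

from woundmetric.raster_io import BinaryMask, RgbImage
from woundmetric.roi_segmentation import RoiResult
from woundmetric.scene_synthesis import MARKER_PHYSICAL_CM2


class MeasurementError(RuntimeError):
    """Raised when a physical measurement is requested without a valid marker."""


@dataclass(frozen=True)
class HsvRange:
    """Inclusive per-channel HSV window; hue in degrees, sat/val in [0,1].

    The default covers the shades of blue the marker may take under
    varying illumination.  Hue wraparound is not supported (blue does
    not straddle 0 deg).
    """

    hue_deg: tuple[float, float] = (200.0, 260.0)
    sat: tuple[float, float] = (0.35, 1.0)
    val: tuple[float, float] = (0.20, 1.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.hue_deg, self.sat, self.val):
            if lo > hi:
                raise ValueError("range low must not exceed high")


@dataclass(frozen=True)
class QcThresholds:
    min_proportionality: float = 0.8
    max_asymmetry: float = 0.2
    min_area_px: int = 400


@dataclass(frozen=True)
class MarkerResult:
    """Outcome of marker detection and placement validation."""

    corners: np.ndarray | None  # 4 ordered (row, col), clockwise from top-left
    quad_area_px: float | None
    mask_area_px: int | None
    proportionality: float | None
    asymmetry: float | None
    valid: bool
    scale_cm2_per_px: float | None = None
    reject_reason: str | None = None


def to_hsv(image: RgbImage) -> np.ndarray:
    """Standard hexcone HSV: hue in degrees [0, 360), sat and val in [0, 1]."""
    hsv = rgb2hsv(image.pixels)
    hsv[..., 0] *= 360.0
    return hsv


def blue_mask(hsv: np.ndarray, rng: HsvRange | None = None) -> BinaryMask:
    """Pixels whose hue, saturation and value all fall in the window."""
    rng = rng or HsvRange()
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    keep = (
        (h >= rng.hue_deg[0]) & (h <= rng.hue_deg[1])
        & (s >= rng.sat[0]) & (s <= rng.sat[1])
        & (v >= rng.val[0]) & (v <= rng.val[1])
    )
    return BinaryMask(keep)


def _side_lengths(corners: np.ndarray) -> np.ndarray:
    return np.linalg.norm(np.roll(corners, -1, axis=0) - corners, axis=1)


def asymmetry_score(corners: np.ndarray) -> float:
    """Relative mismatch of opposite side lengths of a quadrilateral.

    With corners ordered clockwise from top-left the sides are top,
    right, bottom, left; the score is
    ``max(|top-bottom|/max(top,bottom), |left-right|/max(left,right))``.
    0 for a parallelogram; grows with perspective foreshortening.
    """
    corners = np.asarray(corners, dtype=float)
    if corners.shape != (4, 2):
        raise ValueError("expected 4 (row, col) corners")
    top, right, bottom, left = _side_lengths(corners)
    if min(top, right, bottom, left) <= 0:
        raise ValueError("degenerate quadrilateral: zero-length side")
    return max(
        abs(top - bottom) / max(top, bottom),
        abs(left - right) / max(left, right),
    )


def proportionality_score(corners: np.ndarray) -> float:
    """Shortest side over longest side; 1 for a perfect square."""
    sides = _side_lengths(np.asarray(corners, dtype=float))
    return float(sides.min() / sides.max())


def _quad_area(corners: np.ndarray) -> float:
    r, c = corners[:, 0], corners[:, 1]
    return 0.5 * abs(np.dot(c, np.roll(r, -1)) - np.dot(r, np.roll(c, -1)))


def _order_clockwise(corners: np.ndarray) -> np.ndarray:
    centre = corners.mean(axis=0)
    ang = np.arctan2(corners[:, 0] - centre[0], corners[:, 1] - centre[1])
    ordered = corners[np.argsort(ang)]
    start = int(np.argmin(ordered[:, 0] + ordered[:, 1]))
    return np.roll(ordered, -start, axis=0)


def _refine_corners(contour: np.ndarray, corners: np.ndarray) -> np.ndarray:
    """Sharpen rough corner estimates by intersecting edge lines.

    Rasterised contours staircase along tilted edges, so the simplified
    polygon's vertices can sit well inside the true corners.  For each
    of the four edges we fit a total-least-squares line to the contour
    points between the two adjacent corners (trimming 15% at each end
    to drop corner rounding) and place the refined corner at the
    intersection of neighbouring lines.
    """
    closed = contour[:-1] if np.allclose(contour[0], contour[-1]) else contour
    idx = [int(np.argmin(np.linalg.norm(closed - c, axis=1))) for c in corners]
    lines = []
    n = len(closed)
    for a, b in zip(idx, idx[1:] + idx[:1]):
        span = (b - a) % n
        if span < 8:
            return corners  # too few points to fit edges
        trim = max(int(0.15 * span), 1)
        pts = closed[[(a + t) % n for t in range(trim, span - trim + 1)]]
        centre = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - centre)
        lines.append((centre, vt[0]))  # point + direction
    refined = []
    for (p1, d1), (p2, d2) in zip(lines[-1:] + lines[:-1], lines):
        cross = d1[0] * d2[1] - d1[1] * d2[0]
        if abs(cross) < 1e-9:
            return corners  # near-parallel edges: keep rough corners
        t = ((p2[0] - p1[0]) * d2[1] - (p2[1] - p1[1]) * d2[0]) / cross
        refined.append(p1 + t * d1)
    return _order_clockwise(np.asarray(refined))


def _fit_quadrilateral(component: np.ndarray) -> np.ndarray | None:
    """Simplify a component's outer contour to 4 vertices.

    Douglas-Peucker tolerance starts at 2% of the contour perimeter and
    is relaxed stepwise to 5% before giving up; successful fits are
    refined by edge-line intersection.
    """
    padded = np.pad(component.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return None
    contour = max(contours, key=len) - 1.0
    perimeter = float(np.linalg.norm(np.diff(contour, axis=0), axis=1).sum())
    for frac in np.linspace(0.02, 0.05, 7):
        approx = approximate_polygon(contour, tolerance=frac * perimeter)
        n_vertices = len(approx) - 1 if np.allclose(approx[0], approx[-1]) else len(approx)
        if n_vertices == 4:
            rough = _order_clockwise(
                approx[:4] if n_vertices == len(approx) else approx[:-1])
            return _refine_corners(contour, rough)
    return None


def find_marker(image: RgbImage, rng: HsvRange | None = None,
                qc: QcThresholds | None = None) -> MarkerResult:
    """Detect the blue square marker and validate its placement.

    Pipeline: HSV blue mask -> connected components -> quadrilateral fit
    per sufficiently large component -> select the candidate minimising
    the relative mismatch between quadrilateral area and thresholded
    pixel area -> QC on proportionality and asymmetry -> scale.
    """
    rng = rng or HsvRange()
    qc = qc or QcThresholds()
    mask = blue_mask(to_hsv(image), rng)
    comps = cc_label(mask.pixels, connectivity=1)

    candidates: list[tuple[float, np.ndarray, float, int]] = []
    for cid in range(1, int(comps.max()) + 1):
        comp = comps == cid
        area = int(comp.sum())
        if area < qc.min_area_px:
            continue
        corners = _fit_quadrilateral(comp)
        if corners is None:
            continue
        quad_area = _quad_area(corners)
        if quad_area <= 0:
            continue
        mismatch = abs(quad_area - area) / area
        candidates.append((mismatch, corners, quad_area, area))

    if not candidates:
        return MarkerResult(
            corners=None, quad_area_px=None, mask_area_px=None,
            proportionality=None, asymmetry=None,
            valid=False, reject_reason="no marker found",
        )

    candidates.sort(key=lambda c: c[0])
    _, corners, quad_area, mask_area = candidates[0]
    prop = proportionality_score(corners)
    asym = asymmetry_score(corners)

    reject = None
    if prop < qc.min_proportionality:
        reject = f"proportionality {prop:.3f} below {qc.min_proportionality}"
    elif asym > qc.max_asymmetry:
        reject = f"asymmetry {asym:.3f} above {qc.max_asymmetry}"

    valid = reject is None
    return MarkerResult(
        corners=corners,
        quad_area_px=float(quad_area),
        mask_area_px=mask_area,
        proportionality=prop,
        asymmetry=asym,
        valid=valid,
        scale_cm2_per_px=(MARKER_PHYSICAL_CM2 / quad_area) if valid else None,
        reject_reason=reject,
    )


def measure_area(roi: RoiResult | BinaryMask, marker: MarkerResult) -> float:
    """Physical wound area in cm^2: wound pixel count times the marker scale."""
    if not marker.valid or marker.scale_cm2_per_px is None:
        raise MeasurementError(
            f"marker invalid: {marker.reject_reason or 'unknown reason'}"
        )
    mask = roi.wound_mask if isinstance(roi, RoiResult) else roi
    return mask.area_px * marker.scale_cm2_per_px
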