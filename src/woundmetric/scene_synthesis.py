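"""Synthetic wound photographs with complete ground truth.

Renders an elliptical-to-irregular wound blob containing colour-distinct
tissue zones (dark necrotic core, yellow slough ring, red granulation
rim) on a skin-toned background, plus a blue square fiducial marker of
known physical size (2 cm x 2 cm, i.e. 4 cm^2) under a configurable
in-plane rotation and homography, global illumination gain and additive
Gaussian sensor noise.  Every scene carries its own ground truth (wound
mask, tissue labels, marker corners, true cm^2-per-pixel scale) so each
downstream stage is testable without clinical data.

Geometry is driven by ``shape_seed`` and the other spec fields; ``seed``
drives only the sensor noise, so scenes differing only in ``seed`` share
identical masks and marker corners.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import polygon as draw_polygon

from woundmetric.raster_io import BinaryMask, LabelMask, RgbImage, Scribble

MARKER_PHYSICAL_CM2 = 4.0  # 2 cm x 2 cm fiducial square

# default palette: chosen for separability under the default HSV gates
TISSUE_COLORS = {
    1: (40, 30, 30),     # necrotic
    2: (200, 180, 90),   # slough
    3: (180, 60, 60),    # granulated
}
SKIN_COLOR = (220, 180, 160)


class GeometryError(ValueError):
    """Raised when a requested scene geometry cannot be rendered."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic capture.

    ``marker_perspective`` is a 3x3 homography acting on homogeneous
    (col, row) coordinates; the identity renders the marker
    fronto-parallel.  ``noise_sd`` is in 8-bit intensity units.
    """

    image_size: tuple[int, int] = (256, 256)
    wound_center: tuple[float, float] = (150.0, 150.0)
    wound_radii: tuple[float, float] = (55.0, 65.0)
    boundary_roughness: float = 0.15
    tissue_mix: tuple[float, float, float] = (0.25, 0.35, 0.40)
    marker_center: tuple[float, float] = (48.0, 52.0)
    marker_side_px: float = 60.0
    marker_tilt_deg: float = 0.0
    marker_perspective: np.ndarray = field(
        default_factory=lambda: np.eye(3))
    marker_hue_deg: float = 225.0
    illumination_gain: float = 1.0
    noise_sd: float = 5.0
    seed: int = 0
    shape_seed: int = 0
    include_marker: bool = True

    def __post_init__(self) -> None:
        if abs(sum(self.tissue_mix) - 1.0) > 1e-9:
            raise ValueError("tissue_mix must sum to 1")
        if any(f < 0 for f in self.tissue_mix):
            raise ValueError("tissue_mix fractions must be non-negative")
        if not (0.0 <= self.boundary_roughness <= 1.0):
            raise ValueError("boundary_roughness must lie in [0, 1]")
        H = np.asarray(self.marker_perspective, dtype=float)
        if H.shape != (3, 3):
            raise ValueError("marker_perspective must be 3x3")
        object.__setattr__(self, "marker_perspective", H)


@dataclass(frozen=True)
class WoundScene:
    """A rendered photograph plus its full ground truth."""

    image: RgbImage
    wound_mask: BinaryMask
    tissue_labels: LabelMask
    marker_corners: np.ndarray | None  # 4 ordered (row, col), cw from top-left
    true_scale_cm2_per_px: float | None
    spec: SceneSpec


def _shoelace_area(corners_rc: np.ndarray) -> float:
    r = corners_rc[:, 0]
    c = corners_rc[:, 1]
    return 0.5 * abs(np.dot(c, np.roll(r, -1)) - np.dot(r, np.roll(c, -1)))


def _marker_corners(spec: SceneSpec) -> np.ndarray:
    """Ground-truth marker quadrilateral as 4 (row, col) points, clockwise
    from the top-left corner."""
    half = spec.marker_side_px / 2.0
    # square corners in local (x=col, y=row) coords, then rotate in-plane
    base = np.array([[-half, -half], [half, -half], [half, half], [-half, half]])
    t = np.deg2rad(spec.marker_tilt_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    xy = base @ rot.T
    cy, cx = spec.marker_center
    xy += np.array([cx, cy])
    # homography in homogeneous (x, y, 1)
    ones = np.ones((4, 1))
    h = np.hstack([xy, ones]) @ spec.marker_perspective.T
    xy = h[:, :2] / h[:, 2:3]
    corners = np.column_stack([xy[:, 1], xy[:, 0]])  # back to (row, col)
    return _order_clockwise(corners)


def _order_clockwise(corners: np.ndarray) -> np.ndarray:
    """Order 4 (row, col) points clockwise starting from the top-left."""
    centre = corners.mean(axis=0)
    # image-coordinate clockwise == increasing atan2 with row axis down
    ang = np.arctan2(corners[:, 0] - centre[0], corners[:, 1] - centre[1])
    order = np.argsort(ang)
    ordered = corners[order]
    start = int(np.argmin(ordered[:, 0] + ordered[:, 1]))
    return np.roll(ordered, -start, axis=0)


def _wound_fields(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Boolean wound support and the normalised radial coordinate rho."""
    H, W = spec.image_size
    rr, cc = np.mgrid[0:H, 0:W]
    cy, cx = spec.wound_center
    ry, rx = spec.wound_radii
    dy = (rr - cy) / ry
    dx = (cc - cx) / rx
    theta = np.arctan2(dy, dx)
    rng = np.random.default_rng(spec.shape_seed)
    n_harm = 4
    amps = rng.uniform(0.3, 1.0, n_harm)
    amps *= spec.boundary_roughness / max(amps.sum(), 1e-12)
    phases = rng.uniform(0, 2 * np.pi, n_harm)
    wobble = np.ones_like(theta)
    for k, (a, ph) in enumerate(zip(amps, phases), start=2):
        wobble += a * np.cos(k * theta + ph)
    rho = np.hypot(dy, dx) / np.maximum(wobble, 1e-6)
    return rho <= 1.0, rho


def _tissue_labels(spec: SceneSpec) -> LabelMask:
    """Concentric tissue zones with pixel fractions matching tissue_mix.

    Band boundaries are placed at empirical quantiles of the radial
    coordinate over wound pixels, so the realised fractions track the
    requested mix to within rasterisation error.
    """
    support, rho = _wound_fields(spec)
    labels = np.zeros(spec.image_size, dtype=np.uint8)
    inside = rho[support]
    if inside.size == 0:
        raise GeometryError("wound blob is empty; radii too small")
    f_nec, f_slo, _ = spec.tissue_mix
    q1 = np.quantile(inside, min(f_nec, 1.0)) if f_nec > 0 else -np.inf
    q2 = np.quantile(inside, min(f_nec + f_slo, 1.0)) if f_nec + f_slo > 0 else q1
    lab = np.full(spec.image_size, 3, dtype=np.uint8)
    lab[rho <= q2] = 2
    lab[rho <= q1] = 1
    labels[support] = lab[support]
    return LabelMask(labels)


def render_scene(spec: SceneSpec) -> WoundScene:
    """Render a synthetic wound photograph with ground truth.

    Deterministic for a fixed spec; raises :class:`GeometryError` if the
    marker falls outside the frame or overlaps the wound blob.
    """
    H, W = spec.image_size
    tissue = _tissue_labels(spec)
    wound = tissue.as_binary()

    canvas = np.empty((H, W, 3), dtype=float)
    canvas[:] = SKIN_COLOR
    for label, color in TISSUE_COLORS.items():
        canvas[tissue.pixels == label] = color

    corners: np.ndarray | None = None
    scale: float | None = None
    if spec.include_marker:
        corners = _marker_corners(spec)
        if (corners[:, 0].min() < 0 or corners[:, 1].min() < 0
                or corners[:, 0].max() > H - 1 or corners[:, 1].max() > W - 1):
            raise GeometryError("marker quadrilateral falls outside the frame")
        # half-pixel shift makes the covered pixel count match the
        # quadrilateral's continuous (shoelace) area: an axis-aligned
        # square of side s covers exactly s*s pixels
        rr, cc = draw_polygon(corners[:, 0] - 0.5, corners[:, 1] - 0.5,
                              shape=(H, W))
        if wound.pixels[rr, cc].any():
            raise GeometryError("marker overlaps the wound blob")
        rgb = colorsys.hsv_to_rgb(spec.marker_hue_deg / 360.0, 0.85, 0.75)
        canvas[rr, cc] = np.array(rgb) * 255.0
        quad_area = _shoelace_area(corners)
        if quad_area <= 0:
            raise GeometryError("degenerate marker quadrilateral")
        scale = MARKER_PHYSICAL_CM2 / quad_area

    canvas *= spec.illumination_gain
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        canvas += rng.normal(0.0, spec.noise_sd, canvas.shape)
    image = RgbImage(np.clip(np.round(canvas), 0, 255).astype(np.uint8))
    return WoundScene(image, wound, tissue, corners, scale, spec)


def render_tracing_pair(scene: WoundScene, dilate_px: int = 0,
                        shift_px: int = 0) -> tuple[BinaryMask, BinaryMask]:
    """A (reference, test) tracing pair with a known geometric error.

    The reference is the scene's ground-truth wound mask; the test is
    the reference dilated by ``dilate_px`` then translated ``shift_px``
    pixels along the column axis, yielding controllable FNR/FPR values.
    """
    from scipy.ndimage import binary_dilation

    if dilate_px < 0 or shift_px < 0:
        raise ValueError("dilate_px and shift_px must be non-negative")
    ref = scene.wound_mask.pixels
    test = ref
    if dilate_px > 0:
        test = binary_dilation(test, iterations=dilate_px)
    if shift_px > 0:
        if test[:, -shift_px:].any():
            raise GeometryError("shift pushes the tracing out of frame")
        test = np.roll(test, shift_px, axis=1)
        test[:, :shift_px] = False
    return BinaryMask(ref), BinaryMask(test)


def default_scribble(scene: WoundScene, inset_frac: float = 0.05) -> Scribble:
    """A stroke across the wound bed, clipped to the ground-truth mask.

    Emulates the clinician's in-wound scribble: a horizontal polyline
    along the centre row from near one wound edge to the other (inset
    by ``inset_frac`` of the local width), so it crosses every
    concentric tissue zone.
    """
    cy, _ = scene.spec.wound_center
    r = int(round(cy))
    row = scene.wound_mask.pixels[r]
    cols = np.flatnonzero(row)
    if cols.size == 0:
        raise GeometryError("wound centre row carries no wound pixels")
    span = cols[-1] - cols[0]
    inset = int(round(inset_frac * span))
    c0, c1 = cols[0] + inset, cols[-1] - inset
    pts = [(r, int(c)) for c in range(c0, c1 + 1)
           if scene.wound_mask.pixels[r, int(c)]]
    if not pts:
        raise GeometryError("scribble stroke leaves the wound mask")
    return Scribble(tuple(pts))


def sample_scene_specs(n: int, seed: int = 0, **overrides) -> list[SceneSpec]:
    """Draw ``n`` varied scene specifications.

    Wound placement, radii, boundary shape, tissue mix and marker tilt
    are jittered per scene; keyword overrides are applied to every spec.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        radii = (float(rng.uniform(42, 62)), float(rng.uniform(48, 70)))
        mix = rng.dirichlet((6, 8, 9))
        spec = SceneSpec(
            wound_center=(float(rng.uniform(138, 168)), float(rng.uniform(138, 168))),
            wound_radii=radii,
            boundary_roughness=float(rng.uniform(0.05, 0.2)),
            tissue_mix=(float(mix[0]), float(mix[1]), float(1 - mix[0] - mix[1])),
            marker_tilt_deg=float(rng.uniform(0, 40)),
            seed=int(rng.integers(0, 2**31 - 1)),
            shape_seed=int(rng.integers(0, 2**31 - 1)),
        )
        specs.append(replace(spec, **overrides) if overrides else spec)
    return specs
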