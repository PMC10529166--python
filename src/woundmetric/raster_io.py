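"""Typed raster containers and readers/writers.

In-memory representations of photographs, binary masks, tissue label
masks, user scribbles and the final assessment report, plus PNG/JPEG
readers and the JSON report writer.

Conventions: rasters are row-major numpy arrays indexed ``(row, col)``
with 0-based integer pixel coordinates; colour images are 8-bit RGB.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError

DEFAULT_TISSUE_LEGEND = {1: "necrotic", 2: "slough", 3: "granulated"}


class FormatError(ValueError):
    """Raised when an input file cannot be decoded as expected."""


@dataclass(frozen=True)
class RgbImage:
    """An 8-bit RGB photograph, shape ``(H, W, 3)``, channel order R,G,B."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected HxWx3 raster, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BinaryMask:
    """A boolean raster annotating an image of the same height and width."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected HxW raster, got shape {px.shape}")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def area_px(self) -> int:
        """Number of true pixels; always recomputed from the raster."""
        return int(np.count_nonzero(self.pixels))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class LabelMask:
    """Small-integer label raster; 0 is background, 1..k are tissues."""

    pixels: np.ndarray
    legend: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_LEGEND)
    )

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected HxW raster, got shape {px.shape}")
        if px.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def as_binary(self, positive_labels: Sequence[int] | None = None) -> BinaryMask:
        """Union mask of the given labels (default: every non-zero label)."""
        if positive_labels is None:
            return BinaryMask(self.pixels > 0)
        return BinaryMask(np.isin(self.pixels, list(positive_labels)))


@dataclass(frozen=True)
class Scribble:
    """Ordered polyline of (row, col) points drawn inside the wound."""

    points: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pts = tuple((int(r), int(c)) for r, c in self.points)
        if len(pts) < 1:
            raise ValueError("scribble needs at least one point")
        object.__setattr__(self, "points", pts)

    def validate_bounds(self, height: int, width: int) -> None:
        for r, c in self.points:
            if not (0 <= r < height and 0 <= c < width):
                raise ValueError(
                    f"scribble point ({r}, {c}) outside {height}x{width} frame"
                )

    def as_mask(self, height: int, width: int) -> BinaryMask:
        """Rasterise the polyline with a 1-pixel stroke."""
        from skimage.draw import line

        self.validate_bounds(height, width)
        canvas = np.zeros((height, width), dtype=bool)
        pts = self.points
        if len(pts) == 1:
            canvas[pts[0]] = True
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            rr, cc = line(r0, c0, r1, c1)
            canvas[rr, cc] = True
        return BinaryMask(canvas)


@dataclass
class AssessmentReport:
    """Aggregated output of one assessment run.

    ``area_cm2`` is absent (None) when marker validation failed;
    ``tissue_fractions`` maps tissue name to its fraction of wound area
    and sums to 1 when classification was run.
    """

    area_cm2: float | None
    scale_cm2_per_px: float | None
    marker: dict
    tissue_fractions: Mapping[str, float] | None = None
    provenance: Mapping[str, object] = field(default_factory=dict)

    def validate(self) -> None:
        if self.area_cm2 is not None and self.area_cm2 < 0:
            raise ValueError("area_cm2 must be non-negative")
        if self.tissue_fractions is not None:
            vals = list(self.tissue_fractions.values())
            if any(v < 0 for v in vals):
                raise ValueError("tissue fractions must be non-negative")
            if abs(sum(vals) - 1.0) > 1e-6:
                raise ValueError("tissue fractions must sum to 1")


def read_image(path: str | Path) -> RgbImage:
    """Decode a PNG or JPEG photograph to 8-bit RGB.

    Grayscale inputs are replicated across channels; an alpha channel
    is dropped.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise FormatError(f"cannot decode image file: {path}") from exc
    return RgbImage(arr)


def read_mask(path: str | Path, positive_labels: Sequence[int] = (1,)) -> BinaryMask:
    """Read an 8-bit single-channel PNG as a binary mask.

    Pixels whose value is in ``positive_labels`` become true.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "P", "I", "1"):
                raise FormatError(
                    f"mask must be single-channel, got mode {im.mode!r}: {path}"
                )
            arr = np.asarray(im.convert("L"))
    except (UnidentifiedImageError, OSError) as exc:
        raise FormatError(f"cannot decode mask file: {path}") from exc
    return BinaryMask(np.isin(arr, list(positive_labels)))


def read_label_mask(path: str | Path,
                    legend: Mapping[int, str] | None = None) -> LabelMask:
    """Read an 8-bit single-channel PNG as a tissue label mask."""
    path = Path(path)
    with Image.open(path) as im:
        if im.mode not in ("L", "P", "I", "1"):
            raise FormatError(
                f"label mask must be single-channel, got mode {im.mode!r}: {path}"
            )
        arr = np.asarray(im.convert("L"))
    if legend is None:
        legend = dict(DEFAULT_TISSUE_LEGEND)
    return LabelMask(arr, legend)


def write_image(image: RgbImage, path: str | Path) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(Path(path))


def write_mask(mask: BinaryMask | LabelMask, path: str | Path) -> None:
    """Serialize a mask as 8-bit PNG: 0/1 for binary, legend labels for tissue."""
    arr = np.asarray(mask.pixels).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def write_report(report: AssessmentReport, path: str | Path) -> None:
    """Write the assessment report as UTF-8 JSON with stable key order.

    Numeric fields survive a write/read round trip to 1e-9.
    """
    report.validate()
    doc = {
        "area_cm2": report.area_cm2,
        "scale_cm2_per_px": report.scale_cm2_per_px,
        "marker": report.marker,
        "tissue_fractions": (
            dict(report.tissue_fractions)
            if report.tissue_fractions is not None else None
        ),
        "provenance": dict(report.provenance),
    }
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=2, sort_keys=False)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}") from exc


def read_report(path: str | Path) -> AssessmentReport:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    return AssessmentReport(
        area_cm2=doc["area_cm2"],
        scale_cm2_per_px=doc["scale_cm2_per_px"],
        marker=doc["marker"],
        tissue_fractions=doc.get("tissue_fractions"),
        provenance=doc.get("provenance", {}),
    )
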