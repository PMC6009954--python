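"""Spot quantification on scanned plate images.

Greyscale conversion, grid-constrained spot-centre refinement, and the
circular-ROI mean grey value ("colour value") per spot.  Higher mean grey
value = lighter spot = more radical scavenged; values are never inverted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
from PIL import Image

from .errors import ROIError, UnsupportedImageError
from .plate_model import PlateLayout, SpotMeasurement

# luminance weights matching the common image-software default
_GREY_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass
class PlateImage:
    """An 8-bit raster, greyscale ``(H, W)`` or RGB ``(H, W, 3)``."""

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != np.uint8:
            raise UnsupportedImageError(
                f"expected 8-bit (uint8) pixels, got dtype {px.dtype}"
            )
        if px.ndim == 3 and px.shape[2] == 4:  # drop alpha silently
            px = px[:, :, :3]
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise UnsupportedImageError(
                f"expected (H, W) grey or (H, W, 3) RGB raster, got shape {px.shape}"
            )
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_grey(self) -> bool:
        return self.pixels.ndim == 2

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PlateImage":
        with Image.open(path) as im:
            if im.mode in ("L", "RGB"):
                arr = np.asarray(im)
            elif im.mode in ("RGBA", "P", "LA", "1", "I;16"):
                arr = np.asarray(im.convert("RGB"))
            else:
                raise UnsupportedImageError(
                    f"unsupported image mode {im.mode!r} in {path}"
                )
        return cls(pixels=arr.astype(np.uint8), source_path=str(path))

    def to_file(self, path: Union[str, Path]) -> None:
        Image.fromarray(self.pixels).save(path)


def to_grey(image: PlateImage) -> PlateImage:
    """Convert RGB to greyscale with 0.299/0.587/0.114 luminance weights.

    The weighted sum is rounded half-up to an integer in [0, 255]; the mean
    grey value downstream is computed on these integer greys.  Idempotent on
    greyscale input.
    """
    if image.is_grey:
        return image
    lum = image.pixels.astype(np.float64) @ _GREY_WEIGHTS
    grey = np.floor(lum + 0.5).clip(0, 255).astype(np.uint8)
    return PlateImage(pixels=grey, source_path=image.source_path)


def _disc_mask_bounds(
    centre: Tuple[float, float], radius: float, width: int, height: int
) -> Tuple[int, int, int, int]:
    cx, cy = centre
    if radius < 1:
        raise ROIError(f"radius must be >= 1 pixel, got {radius}")
    if cx - radius < 0 or cx + radius > width - 1 or cy - radius < 0 or cy + radius > height - 1:
        raise ROIError(
            f"ROI centre ({cx}, {cy}) radius {radius} exceeds image "
            f"bounds {width}x{height}"
        )
    x0 = int(np.floor(cx - radius))
    x1 = int(np.ceil(cx + radius))
    y0 = int(np.floor(cy - radius))
    y1 = int(np.ceil(cy + radius))
    return x0, x1, y0, y1


def mean_grey_value(
    image: PlateImage, centre: Tuple[float, float], radius: float
) -> Tuple[float, int]:
    """Arithmetic mean of pixels whose centres lie within the disc.

    Membership is pixel-centre-in-disc (Euclidean distance <= radius); no
    partial-pixel weighting, so pixel counts are reproducible integers.
    Returns ``(colour_value, n_pixels)``.
    """
    if not image.is_grey:
        raise UnsupportedImageError("mean_grey_value requires a greyscale image")
    cx, cy = centre
    x0, x1, y0, y1 = _disc_mask_bounds(centre, radius, image.width, image.height)
    ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
    mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    patch = image.pixels[y0 : y1 + 1, x0 : x1 + 1]
    n = int(mask.sum())
    if n < 1:
        raise ROIError("ROI contains no pixel centres")
    return float(patch[mask].mean()), n


@dataclass(frozen=True)
class RefinedCentre:
    row: int
    col: int
    x: float
    y: float
    fallback: bool  # True when no contrast was found and the nominal centre was used


def refine_spot_centres(
    image: PlateImage,
    layout: PlateLayout,
    search_radius: Optional[float] = None,
    min_contrast: float = 5.0,
) -> List[RefinedCentre]:
    """Refine each well centre to the centroid of its dark deviation.

    Within a square window of half-size ``search_radius`` around the nominal
    grid centre, pixels darker than the local background (90th percentile)
    are weighted by their deviation; pixels in the top half of the deviation
    range form the intensity-weighted centroid.  Centres never move farther
    than ``search_radius``; wells with peak deviation below ``min_contrast``
    grey levels fall back to the nominal centre with ``fallback=True``.
    """
    grey = to_grey(image)
    if search_radius is None:
        search_radius = min(layout.pitch_x, layout.pitch_y) / 2 - 1
    if not search_radius < min(layout.pitch_x, layout.pitch_y) / 2:
        raise ROIError("search_radius must be < min pitch / 2")

    px = grey.pixels.astype(np.float64)
    out: List[RefinedCentre] = []
    for well in layout.wells:
        cx, cy = layout.centre(well.row, well.col)
        x0 = max(0, int(np.floor(cx - search_radius)))
        x1 = min(grey.width - 1, int(np.ceil(cx + search_radius)))
        y0 = max(0, int(np.floor(cy - search_radius)))
        y1 = min(grey.height - 1, int(np.ceil(cy + search_radius)))
        window = px[y0 : y1 + 1, x0 : x1 + 1]
        bg = np.percentile(window, 90)
        deviation = np.clip(bg - window, 0.0, None)
        peak = deviation.max()
        if peak < min_contrast:
            out.append(RefinedCentre(well.row, well.col, cx, cy, fallback=True))
            continue
        weights = np.where(deviation >= 0.5 * peak, deviation, 0.0)
        total = weights.sum()
        ys, xs = np.mgrid[y0 : y1 + 1, x0 : x1 + 1]
        rx = float((weights * xs).sum() / total)
        ry = float((weights * ys).sum() / total)
        # clamp the displacement to the search radius
        dx, dy = rx - cx, ry - cy
        dist = np.hypot(dx, dy)
        if dist > search_radius:
            scale = search_radius / dist
            rx, ry = cx + dx * scale, cy + dy * scale
        out.append(RefinedCentre(well.row, well.col, rx, ry, fallback=False))
    return out


def quantify_plate(
    image: PlateImage,
    layout: PlateLayout,
    refine: bool = True,
    search_radius: Optional[float] = None,
) -> List[SpotMeasurement]:
    """Measure every assigned well: one :class:`SpotMeasurement` per well.

    Deterministic for fixed inputs.  ROI errors are re-raised naming the
    offending grid cell.
    """
    grey = to_grey(image)
    if refine:
        centres = {
            (c.row, c.col): (c.x, c.y)
            for c in refine_spot_centres(grey, layout, search_radius)
        }
    else:
        centres = {
            (w.row, w.col): layout.centre(w.row, w.col) for w in layout.wells
        }

    measurements: List[SpotMeasurement] = []
    for well in layout.wells:
        centre = centres[(well.row, well.col)]
        try:
            value, n = mean_grey_value(grey, centre, layout.spot_radius)
        except ROIError as exc:
            raise ROIError(
                f"well (row={well.row}, col={well.col}): {exc}"
            ) from exc
        measurements.append(
            SpotMeasurement(
                sample_id=well.sample_id,
                concentration=well.concentration,
                replicate=well.replicate,
                role=well.role,
                centre=centre,
                radius=layout.spot_radius,
                colour_value=value,
                n_pixels=n,
                unit=well.unit,
                row=well.row,
                col=well.col,
            )
        )
    return measurements
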