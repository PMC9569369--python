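"""Standardization of fundus photographs to the pipeline's canonical frame.

Fundus cameras deliver rectangular rasters in which the circular retinal
field of view floats on a dark surround.  Every quantitative stage downstream
(vessel counting, zone-B SNR, cohort statistics) assumes a square frame with
the retina centred, so this module provides

* :func:`detect_retina_extent` — locate the circular retina,
* :func:`center_crop_resize`   — centre, square-crop, and resize (1024 px by
  convention for high-resolution work), and
* :func:`quality_filter`       — brightness / saturation / zoom exclusion
  heuristics standing in for the manual+disc-detector exclusions applied to
  clinical datasets.

Coordinate convention: 0-based ``(row, col)``, pixel centres at integer
coordinates, origin at the top-left.  Intensities live in ``[0, 1]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.transform import resize

logger = logging.getLogger(__name__)

__all__ = [
    "FundusImage",
    "QualityThresholds",
    "QualityReport",
    "RetinaDetectionError",
    "load_image",
    "save_image",
    "detect_retina_extent",
    "center_crop_resize",
    "quality_filter",
]


class RetinaDetectionError(ValueError):
    """No circular retina foreground could be located in the image."""


@dataclass
class FundusImage:
    """A fundus raster plus identity metadata.

    ``pixels`` is ``H x W`` (grayscale) or ``H x W x 3`` (RGB), float in
    ``[0, 1]``.
    """

    pixels: np.ndarray
    id: str = ""
    cohort: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim not in (2, 3):
            raise ValueError("pixels must be HxW or HxWx3")
        if px.size == 0:
            raise ValueError("empty image")
        if px.min() < -1e-9 or px.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")
        self.pixels = np.clip(px, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def gray(self, channel: str = "green") -> np.ndarray:
        """Return a single-channel view.

        For RGB inputs the green plane is the fundus-imaging standard for
        vessel work (best vessel/background contrast); ``channel`` may also
        be ``"red"``, ``"blue"`` or ``"luma"``.
        """
        if self.pixels.ndim == 2:
            return self.pixels
        idx = {"red": 0, "green": 1, "blue": 2}
        if channel == "luma":
            return self.pixels.mean(axis=2)
        try:
            return self.pixels[:, :, idx[channel]]
        except KeyError:
            raise ValueError(f"unknown channel {channel!r}") from None


@dataclass
class QualityThresholds:
    """Tunable exclusion thresholds (the clinical criteria are qualitative;
    these defaults are deliberately permissive placeholders)."""

    dark: float = 0.08          # mean brightness below -> "dark"
    saturated: float = 0.25     # fraction of pixels >= sat_level -> "saturated"
    zoom: float = 0.97          # retina radius / half frame width above -> "zoomed"
    sat_level: float = 0.98


@dataclass
class QualityReport:
    mean_brightness: float
    saturated_fraction: float
    retina_radius_ratio: float  # NaN when the retina could not be detected
    excluded: bool = False
    reasons: list[str] = field(default_factory=list)


def load_image(path: str | Path, id: str = "", cohort: str = "") -> FundusImage:
    """Read a PNG/TIFF/JPEG file into a :class:`FundusImage` (8/16-bit aware)."""
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.dtype == np.uint8:
        px = arr / 255.0
    elif arr.dtype == np.uint16:
        px = arr / 65535.0
    else:
        px = np.asarray(arr, dtype=float)
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[:, :, :3]
    return FundusImage(px, id=id or path.stem, cohort=cohort, provenance=str(path))


def save_image(image: FundusImage | np.ndarray, path: str | Path) -> None:
    """Write an image (or bare array in [0,1]) as 8-bit PNG."""
    px = image.pixels if isinstance(image, FundusImage) else np.asarray(image, float)
    arr = np.clip(np.round(px * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(Path(path), format="PNG")


def detect_retina_extent(image: FundusImage) -> tuple[tuple[float, float], float]:
    """Estimate the centre and radius of the circular retina region.

    Global Otsu threshold on the gray image, then the largest 8-connected
    foreground component; the bounding box of that component gives the
    bounding circle (centre = box centre, radius = half the larger side).
    """
    gray = image.gray("luma")
    if float(gray.max()) - float(gray.min()) < 1e-9:
        raise RetinaDetectionError("image is constant; no foreground component")
    # smooth before thresholding so pixel noise cannot perturb the boundary
    smooth = ndimage.gaussian_filter(gray, 2.0)
    thr = threshold_otsu(smooth)
    fg = smooth > thr
    fg = ndimage.binary_opening(fg, structure=np.ones((3, 3), bool), iterations=2)
    if not fg.any():
        raise RetinaDetectionError("no foreground above Otsu threshold")
    lbl, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    rows, cols = np.nonzero(lbl == biggest)
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    center = ((r0 + r1) / 2.0, (c0 + c1) / 2.0)
    radius = max(r1 - r0 + 1, c1 - c0 + 1) / 2.0
    return center, radius


def center_crop_resize(
    image: FundusImage, target_size: int = 1024, margin: float = 0.05
) -> FundusImage:
    """Centre the retina, square-crop to the retina circle (+``margin``),
    and resize to ``target_size`` x ``target_size``.

    Bilinear resampling; regions outside the original frame are zero-padded.
    An input that is already standardized (square ``target_size`` frame,
    retina centred and filling the frame up to the margin) is returned
    unchanged, which makes the operation idempotent.
    """
    if target_size < 2:
        raise ValueError("target_size must be >= 2")
    (cr, cc), radius = detect_retina_extent(image)
    H, W = image.pixels.shape[:2]
    side = int(2 * round(radius * (1.0 + margin)))
    side = max(side, 2)

    already_square = H == W == target_size
    centred = abs(cr - (H - 1) / 2.0) <= 1.0 and abs(cc - (W - 1) / 2.0) <= 1.0
    if already_square and centred and abs(side - W) <= 2:
        return FundusImage(
            image.pixels.copy(), id=image.id, cohort=image.cohort,
            provenance=image.provenance,
        )

    if side > min(H, W):
        logger.warning(
            "retina circle (+margin) larger than frame (%d > %dx%d); padding crop",
            side, H, W,
        )

    r_start = int(round(cr)) - side // 2
    c_start = int(round(cc)) - side // 2
    shape = (side, side) + image.pixels.shape[2:]
    window = np.zeros(shape, dtype=float)
    rs, re = max(r_start, 0), min(r_start + side, H)
    cs, ce = max(c_start, 0), min(c_start + side, W)
    window[rs - r_start:re - r_start, cs - c_start:ce - c_start] = (
        image.pixels[rs:re, cs:ce]
    )

    out_shape = (target_size, target_size) + image.pixels.shape[2:]
    out = resize(
        window, out_shape, order=1, mode="constant",
        anti_aliasing=side > target_size, preserve_range=True,
    )
    return FundusImage(
        np.clip(out, 0.0, 1.0), id=image.id, cohort=image.cohort,
        provenance=image.provenance,
    )


def quality_filter(
    image: FundusImage, thresholds: QualityThresholds | None = None
) -> QualityReport:
    """Flag dark / saturated / zoomed images.

    A pure function of the pixels and thresholds; always returns a report.
    ``retina_radius_ratio`` is NaN (and the zoom rule is skipped) when the
    retina cannot be detected.
    """
    thr = thresholds or QualityThresholds()
    gray = image.gray("luma")
    mean_brightness = float(gray.mean())
    saturated_fraction = float((gray >= thr.sat_level).mean())
    try:
        _, radius = detect_retina_extent(image)
        ratio = float(radius / (gray.shape[1] / 2.0))
    except RetinaDetectionError:
        ratio = float("nan")

    reasons: list[str] = []
    if mean_brightness < thr.dark:
        reasons.append("dark")
    if saturated_fraction > thr.saturated:
        reasons.append("saturated")
    if np.isfinite(ratio) and ratio > thr.zoom:
        reasons.append("zoomed")
    return QualityReport(
        mean_brightness=mean_brightness,
        saturated_fraction=saturated_fraction,
        retina_radius_ratio=ratio,
        excluded=bool(reasons),
        reasons=reasons,
    )
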