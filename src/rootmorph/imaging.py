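"""Tray image I/O, stack median projection, and scale calibration.

A root tray is photographed ~5 times with a stage-mounted camera; the
exposures are co-registered, so a per-pixel (temporal) median across the
stack removes transient specks and sensor impulse noise while preserving
edges.  All intensities are carried as floats in [0, 1]; physical scale is
carried as dots-per-inch (DPI) alongside every image and mask.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ScaleCalibration",
    "RasterImage",
    "TrayImageStack",
    "BinaryMask",
    "load_stack",
    "median_project",
    "to_grayscale",
    "spatial_median",
]

#: fixed luminance weights for RGB -> gray reduction
_LUMA = np.array([0.299, 0.587, 0.114])

_CM_PER_INCH = 2.54


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel <-> physical-unit conversion for a known imaging resolution.

    The imaging rig delivers a fixed resolution (about 450 DPI in the
    reference setup); lengths are reported in cm and diameters in mm.
    """

    dpi: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dpi) and self.dpi > 0):
            raise ValueError(f"dpi must be positive and finite, got {self.dpi}")

    @property
    def px_per_cm(self) -> float:
        return self.dpi / _CM_PER_INCH

    @property
    def px_per_mm(self) -> float:
        return self.dpi / (10.0 * _CM_PER_INCH)

    def px_to_cm(self, px):
        return np.asarray(px, dtype=float) / self.px_per_cm

    def px_to_mm(self, px):
        return np.asarray(px, dtype=float) / self.px_per_mm

    def cm_to_px(self, cm):
        return np.asarray(cm, dtype=float) * self.px_per_cm

    def mm_to_px(self, mm):
        return np.asarray(mm, dtype=float) * self.px_per_mm


@dataclass
class RasterImage:
    """A grayscale or RGB raster with intensities in [0, 1] and a DPI.

    ``offset`` records the (row, col) position of this image's origin in
    its source image; crops compose offsets so mask coordinates can be
    mapped back to the original photograph.
    """

    pixels: np.ndarray
    dpi: float
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 3 and px.shape[2] == 1:
            px = px[:, :, 0]
        if px.ndim not in (2, 3):
            raise ValueError(f"expected 2-D or 3-D pixel array, got ndim={px.ndim}")
        if px.ndim == 3 and px.shape[2] not in (1, 3):
            raise ValueError(f"expected 1 or 3 channels, got {px.shape[2]}")
        if px.size == 0:
            raise ValueError("image has no pixels")
        lo, hi = float(px.min()), float(px.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities must lie in [0, 1], got range [{lo}, {hi}]")
        self.pixels = np.clip(px, 0.0, 1.0)
        if not (np.isfinite(self.dpi) and self.dpi > 0):
            raise ValueError(f"dpi must be positive and finite, got {self.dpi}")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def calibration(self) -> ScaleCalibration:
        return ScaleCalibration(self.dpi)


@dataclass
class TrayImageStack:
    """The co-registered exposures of one root tray (length >= 1, ~5 typical)."""

    images: list[RasterImage]
    tray_id: str = "tray"
    plant_id: str = "plant"

    def __post_init__(self) -> None:
        if len(self.images) < 1:
            raise ValueError("a tray stack needs at least one image")
        ref = self.images[0]
        for i, im in enumerate(self.images):
            if (im.height_px, im.width_px, im.channels) != (
                ref.height_px,
                ref.width_px,
                ref.channels,
            ):
                raise ValueError(
                    f"stack image {i} has shape "
                    f"{(im.height_px, im.width_px, im.channels)}, expected "
                    f"{(ref.height_px, ref.width_px, ref.channels)}"
                )
            if im.dpi != ref.dpi:
                raise ValueError(f"stack image {i} has dpi {im.dpi} != {ref.dpi}")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def dpi(self) -> float:
        return self.images[0].dpi


@dataclass
class BinaryMask:
    """Boolean foreground grid with the DPI of its source image."""

    pixels: np.ndarray
    dpi: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2-D, got ndim={px.ndim}")
        self.pixels = px.astype(bool)
        if not (np.isfinite(self.dpi) and self.dpi > 0):
            raise ValueError(f"dpi must be positive and finite, got {self.dpi}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def area_px(self) -> int:
        return int(self.pixels.sum())


def _read_raster(path: str) -> np.ndarray:
    """Read one TIFF or PNG file; multi-page TIFFs return (pages, H, W[, C])."""
    if not os.path.exists(path):
        raise IOError(f"image file not found: {path}")
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in (".tif", ".tiff"):
            import tifffile

            return tifffile.imread(path)
        if ext == ".png":
            import imageio.v3 as iio

            return iio.imread(path)
        raise IOError(f"unsupported image format {ext!r}: {path}")
    except IOError:
        raise
    except Exception as exc:  # decoder failure
        raise IOError(f"could not decode image {path}: {exc}") from exc


def _normalise(arr: np.ndarray) -> np.ndarray:
    """Rescale integer intensities to [0, 1]; floats are assumed in [0, 1]."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / float(np.iinfo(arr.dtype).max)
    return arr.astype(float)


def load_stack(
    paths: list[str], dpi: float, tray_id: str = "tray", plant_id: str = "plant"
) -> TrayImageStack:
    """Load a tray stack from TIFF/PNG files, rescaling intensities to [0, 1].

    A multi-page TIFF contributes each of its pages to the stack.  DPI is a
    required input and is never read from file metadata.
    """
    if not paths:
        raise ValueError("need at least one image path")
    frames: list[np.ndarray] = []
    sources: list[str] = []
    for path in paths:
        arr = _read_raster(path)
        if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[2] in (1, 3)):
            pages = [arr]
        elif arr.ndim == 3:  # multi-page grayscale TIFF
            pages = list(arr)
        elif arr.ndim == 4 and arr.shape[3] in (1, 3):
            pages = list(arr)
        else:
            raise ValueError(f"unsupported image layout {arr.shape} in {path}")
        for page in pages:
            frames.append(_normalise(page))
            sources.append(path)
    ref_shape = frames[0].shape
    for frame, src in zip(frames, sources):
        if frame.shape != ref_shape:
            raise ValueError(
                f"dimension mismatch: {src} has shape {frame.shape}, "
                f"expected {ref_shape}"
            )
    images = [RasterImage(frame, dpi=dpi) for frame in frames]
    return TrayImageStack(images, tray_id=tray_id, plant_id=plant_id)


def median_project(stack: TrayImageStack) -> RasterImage:
    """Per-pixel median across the stack's exposures (temporal median).

    For even stack lengths the *lower* median (order statistic ceil(n/2) of
    the sorted values) is taken, so every output intensity is one of the
    observed intensities — no interpolated values enter the mixture fit.
    """
    if len(stack) == 1:
        return replace(stack.images[0])
    arr = np.stack([im.pixels for im in stack.images], axis=0)
    k = (arr.shape[0] - 1) // 2  # lower median
    med = np.partition(arr, k, axis=0)[k]
    return RasterImage(med, dpi=stack.dpi, offset=stack.images[0].offset)


def to_grayscale(image: RasterImage) -> RasterImage:
    """Reduce RGB to luminance with fixed weights (0.299, 0.587, 0.114)."""
    if image.channels == 1:
        return image
    if image.channels != 3:
        raise ValueError(f"cannot convert {image.channels}-channel image")
    gray = image.pixels @ _LUMA
    return RasterImage(gray, dpi=image.dpi, offset=image.offset)


def spatial_median(image: RasterImage, size: int = 3) -> RasterImage:
    """Optional in-plane median filter (off by default in the pipeline)."""
    from scipy.ndimage import median_filter

    if image.channels != 1:
        raise ValueError("spatial median expects a grayscale image")
    out = median_filter(image.pixels, size=size, mode="reflect")
    return RasterImage(out, dpi=image.dpi, offset=image.offset)
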