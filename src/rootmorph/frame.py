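"""Tray-frame detection and removal.

The roots are arranged on a bright DIN-A4 board whose straight margins are
the strongest lines in the photograph.  A Canny edge map feeds a standard
normal-form Hough transform (rho = x*cos(theta) + y*sin(theta), with x the
column and y the row); the outermost near-horizontal and near-vertical line
pairs define the frame, and the image is cropped to the largest axis-aligned
rectangle strictly inside them, shrunk by a safety margin.

Coordinates are row-major, 0-based, with half-open intervals [min, max).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imaging import BinaryMask, RasterImage

__all__ = [
    "HoughLine",
    "FrameGeometry",
    "FrameNotFoundError",
    "detect_edges",
    "hough_accumulator",
    "hough_lines",
    "fit_frame",
    "crop_interior",
]


class FrameNotFoundError(RuntimeError):
    """Raised when fewer than two horizontal or vertical frame lines are found."""


@dataclass(frozen=True)
class HoughLine:
    """A straight line in normal form: rho = x*cos(theta) + y*sin(theta)."""

    rho: float
    theta: float  # in [0, pi)
    votes: int

    def row_at(self, col: float) -> float:
        """Row coordinate of the line at a given column (near-horizontal lines)."""
        return (self.rho - col * math.cos(self.theta)) / math.sin(self.theta)

    def col_at(self, row: float) -> float:
        """Column coordinate of the line at a given row (near-vertical lines)."""
        return (self.rho - row * math.sin(self.theta)) / math.cos(self.theta)


@dataclass(frozen=True)
class FrameGeometry:
    """The four frame lines and the margin-free interior rectangle.

    ``interior`` is (row_min, row_max, col_min, col_max), half-open on the
    max edges.
    """

    top: HoughLine
    bottom: HoughLine
    left: HoughLine
    right: HoughLine
    interior: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        r0, r1, c0, c1 = self.interior
        if not (r0 < r1 and c0 < c1):
            raise ValueError(f"empty frame interior {self.interior}")


def detect_edges(
    image: RasterImage, low: float = 0.1, high: float = 0.3, sigma: float = 1.5
) -> BinaryMask:
    """Gradient-magnitude edge map with hysteresis thresholds (Canny)."""
    from skimage.feature import canny

    if image.channels != 1:
        raise ValueError("edge detection expects a grayscale image")
    if not (0 <= low < high <= 1):
        raise ValueError(f"need 0 <= low < high <= 1, got low={low}, high={high}")
    edges = canny(image.pixels, sigma=sigma, low_threshold=low, high_threshold=high)
    return BinaryMask(edges, dpi=image.dpi)


def hough_accumulator(
    edges: BinaryMask, rho_res: float = 1.0, theta_res: float = math.pi / 360
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the (rho, theta) vote accumulator for an edge map.

    Returns ``(acc, rhos, thetas)`` where ``acc[i, j]`` counts edge pixels
    whose normal-form distance at angle ``thetas[j]`` rounds to bin center
    ``rhos[i]``.  The theta grid spans [0, pi) at ``theta_res`` spacing; the
    rho grid spans the image diagonal symmetrically at ``rho_res`` spacing.
    """
    if rho_res <= 0 or theta_res <= 0:
        raise ValueError("rho_res and theta_res must be positive")
    h, w = edges.shape
    thetas = np.arange(0.0, math.pi, theta_res)
    diag = math.hypot(h, w)
    n_rho = int(math.ceil(diag / rho_res))
    rhos = np.arange(-n_rho, n_rho + 1) * rho_res
    acc = np.zeros((rhos.size, thetas.size), dtype=np.int64)
    ys, xs = np.nonzero(edges.pixels)
    if ys.size == 0:
        return acc, rhos, thetas
    cos_t = np.cos(thetas)
    sin_t = np.sin(thetas)
    for j in range(thetas.size):
        rho = xs * cos_t[j] + ys * sin_t[j]
        idx = np.rint(rho / rho_res).astype(np.int64) + n_rho
        acc[:, j] += np.bincount(idx, minlength=rhos.size)
    return acc, rhos, thetas


def _extract_peaks(
    acc: np.ndarray,
    rhos: np.ndarray,
    thetas: np.ndarray,
    min_votes: int,
    nms_rho_bins: int,
    nms_theta_bins: int,
) -> list[HoughLine]:
    """Greedy non-maximum suppression: strongest cells first, suppressing a
    (2*nms+1)-cell neighbourhood; ties broken by (rho index, theta index)."""
    ri, tj = np.nonzero(acc >= max(min_votes, 1))
    if ri.size == 0:
        return []
    votes = acc[ri, tj]
    order = np.lexsort((tj, ri, -votes))
    taken_r: list[int] = []
    taken_t: list[int] = []
    lines: list[HoughLine] = []
    for k in order:
        r, t = int(ri[k]), int(tj[k])
        suppressed = False
        for rr, tt in zip(taken_r, taken_t):
            if abs(r - rr) <= nms_rho_bins and abs(t - tt) <= nms_theta_bins:
                suppressed = True
                break
        if suppressed:
            continue
        taken_r.append(r)
        taken_t.append(t)
        lines.append(HoughLine(float(rhos[r]), float(thetas[t]), int(votes[k])))
    return lines


def hough_lines(
    edges: BinaryMask,
    rho_res: float = 1.0,
    theta_res: float = math.pi / 360,
    min_votes: int = 1,
    nms_rho_bins: int = 5,
    nms_theta_bins: int = 5,
) -> list[HoughLine]:
    """Detect straight lines as accumulator peaks with votes >= ``min_votes``.

    Peaks are local maxima after greedy non-maximum suppression, returned
    sorted by votes descending.
    """
    acc, rhos, thetas = hough_accumulator(edges, rho_res, theta_res)
    return _extract_peaks(acc, rhos, thetas, min_votes, nms_rho_bins, nms_theta_bins)


def _is_horizontal(line: HoughLine, max_tilt: float) -> bool:
    return abs(line.theta - math.pi / 2) <= max_tilt


def _is_vertical(line: HoughLine, max_tilt: float) -> bool:
    return min(line.theta, math.pi - line.theta) <= max_tilt


def fit_frame(
    lines: list[HoughLine],
    image_shape: tuple[int, int],
    max_tilt: float = math.radians(5),
    safety_margin_px: int = 3,
) -> FrameGeometry:
    """Pick the outermost near-horizontal and near-vertical line pairs and
    compute the margin-free interior rectangle.

    The interior is the largest axis-aligned rectangle strictly inside all
    four lines, shrunk by ``safety_margin_px`` on every side.
    """
    h, w = image_shape
    horiz = [ln for ln in lines if _is_horizontal(ln, max_tilt)]
    vert = [ln for ln in lines if _is_vertical(ln, max_tilt)]
    if len(horiz) < 2 or len(vert) < 2:
        raise FrameNotFoundError(
            f"frame not found: {len(horiz)} near-horizontal and {len(vert)} "
            f"near-vertical lines (need 2 of each)"
        )
    mid_col, mid_row = (w - 1) / 2, (h - 1) / 2
    top = min(horiz, key=lambda ln: ln.row_at(mid_col))
    bottom = max(horiz, key=lambda ln: ln.row_at(mid_col))
    left = min(vert, key=lambda ln: ln.col_at(mid_row))
    right = max(vert, key=lambda ln: ln.col_at(mid_row))
    # a genuine frame spans a substantial part of the image
    if (bottom.row_at(mid_col) - top.row_at(mid_col)) < 0.1 * h or (
        right.col_at(mid_row) - left.col_at(mid_row)
    ) < 0.1 * w:
        raise FrameNotFoundError("frame not found: candidate line pairs too close")
    m = safety_margin_px
    cols = np.array([0.0, w - 1.0])
    rows = np.array([0.0, h - 1.0])
    row_min = int(math.floor(max(top.row_at(c) for c in cols))) + 1 + m
    row_max = int(math.ceil(min(bottom.row_at(c) for c in cols))) - m  # exclusive
    col_min = int(math.floor(max(left.col_at(r) for r in rows))) + 1 + m
    col_max = int(math.ceil(min(right.col_at(r) for r in rows))) - m  # exclusive
    row_min, col_min = max(row_min, 0), max(col_min, 0)
    row_max, col_max = min(row_max, h), min(col_max, w)
    if row_min >= row_max or col_min >= col_max:
        raise FrameNotFoundError("frame not found: empty interior after margins")
    return FrameGeometry(top, bottom, left, right, (row_min, row_max, col_min, col_max))


def crop_interior(image: RasterImage, frame: FrameGeometry) -> RasterImage:
    """Crop to the frame's interior rectangle; DPI and composed offset kept."""
    r0, r1, c0, c1 = frame.interior
    h, w = image.height_px, image.width_px
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(
            f"interior {frame.interior} outside image bounds {(h, w)}"
        )
    off_r, off_c = image.offset
    return RasterImage(
        image.pixels[r0:r1, c0:c1],
        dpi=image.dpi,
        offset=(off_r + r0, off_c + c0),
    )
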