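"""Root length per diameter class from a binary mask.

The mask is thinned to a 1-px medial axis; the Euclidean distance transform
(EDT) of the mask read at each skeleton pixel gives the local radius, so
local diameter = 2*EDT.  Skeleton length is estimated from the 8-connected
adjacency links (orthogonal links count 1 px, diagonal links sqrt(2)), with
an optional end-correction that adds the local radius at each degree-1
skeleton pixel to compensate the medial axis' end taper.  Each skeleton
pixel's length share is accumulated into the diameter class of its local
diameter, producing the diameter-versus-length frequency table that the
downstream trait analysis consumes.

Units: pixel quantities are converted via the scale calibration — lengths
to cm, diameters to mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .imaging import BinaryMask, ScaleCalibration

__all__ = [
    "Skeleton",
    "DiameterLengthHistogram",
    "skeletonize_mask",
    "local_diameters",
    "skeleton_length",
    "build_histogram",
]

SQRT2 = math.sqrt(2.0)


@dataclass
class Skeleton:
    """A 1-px-wide, 8-connected medial axis with its source-mask shape."""

    mask: np.ndarray  # boolean grid, same shape as the source mask
    dpi: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def coords(self) -> np.ndarray:
        """(N, 2) array of (row, col) skeleton pixel coordinates."""
        return np.argwhere(self.mask)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def skeletonize_mask(mask: BinaryMask) -> Skeleton:
    """Topology-preserving thinning to the medial axis (deterministic).

    Lee's 3-D-capable thinning is used because it digitizes oblique
    centerlines with near-ideal orthogonal/diagonal step statistics, which
    the corrected length estimator below relies on; Zhang-style thinning
    produces zigzag paths whose lengths are inflated at ~30° orientations.
    """
    from skimage.morphology import skeletonize

    return Skeleton(skeletonize(mask.pixels, method="lee").astype(bool), dpi=mask.dpi)


def local_diameters(mask: BinaryMask, skeleton: Skeleton) -> np.ndarray:
    """Local diameter (px) at each skeleton pixel: 2x the mask's EDT.

    Order matches ``skeleton.coords``.
    """
    from scipy.ndimage import distance_transform_edt

    coords = skeleton.coords
    if coords.size and not mask.pixels[coords[:, 0], coords[:, 1]].all():
        raise ValueError("skeleton has pixels outside the mask foreground")
    edt = distance_transform_edt(mask.pixels)
    return 2.0 * edt[coords[:, 0], coords[:, 1]]


def _link_counts(skel: np.ndarray):
    """Per-pixel orthogonal/diagonal link half-counts and degree.

    Each 8-adjacency link between two skeleton pixels contributes half its
    length to each endpoint.  Returns (orth_halves, diag_halves, degree)
    as full-grid arrays.
    """
    s = skel.astype(np.int8)
    orth = np.zeros(s.shape, dtype=np.float64)
    diag = np.zeros(s.shape, dtype=np.float64)
    # orthogonal neighbours: right and down (each link seen once)
    pairs_o = [((slice(None), slice(None, -1)), (slice(None), slice(1, None))),
               ((slice(None, -1), slice(None)), (slice(1, None), slice(None)))]
    pairs_d = [((slice(None, -1), slice(None, -1)), (slice(1, None), slice(1, None))),
               ((slice(None, -1), slice(1, None)), (slice(1, None), slice(None, -1)))]
    for a, b in pairs_o:
        link = skel[a] & skel[b]
        orth[a] += 0.5 * link
        orth[b] += 0.5 * link
    for a, b in pairs_d:
        link = skel[a] & skel[b]
        diag[a] += 0.5 * link
        diag[b] += 0.5 * link
    degree = np.zeros(s.shape, dtype=np.int32)
    for a, b in pairs_o + pairs_d:
        link = (skel[a] & skel[b]).astype(np.int32)
        degree[a] += link
        degree[b] += link
    return orth, diag, degree


def skeleton_length(
    skeleton: Skeleton,
    method: str = "kimura",
    end_correction: bool = True,
    diameters_px: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Estimate skeleton length in px and split it into per-pixel shares.

    method "chain": length = N_o + sqrt(2)*N_d over the adjacency links,
    each link shared half-and-half between its endpoints.  method "kimura":
    the corrected estimator L = sqrt(N_d^2 + (N_d + N_o/2)^2) + N_o/2,
    applied per connected component (chain shares rescaled to the corrected
    component total).

    With ``end_correction`` the local radius (EDT, i.e. ``diameters_px/2``)
    is added at every degree-1 pixel — and twice at isolated pixels — to
    compensate the end taper of the medial axis; ``diameters_px`` (aligned
    with ``skeleton.coords``) is then required.

    Returns ``(total_px, shares_px)`` with shares aligned to
    ``skeleton.coords``; the shares sum to the total exactly (up to float
    summation).
    """
    if method not in ("chain", "kimura"):
        raise ValueError(f"unknown length method {method!r}")
    coords = skeleton.coords
    if coords.size == 0:
        return 0.0, np.zeros(0)
    orth, diag, degree = _link_counts(skeleton.mask)
    rr, cc = coords[:, 0], coords[:, 1]
    shares = orth[rr, cc] + SQRT2 * diag[rr, cc]

    if method == "kimura":
        from skimage.measure import label

        labels = label(skeleton.mask, connectivity=2)
        lab_px = labels[rr, cc]
        chain_px = shares.copy()
        for lbl in np.unique(lab_px):
            sel = lab_px == lbl
            n_o = float(orth[rr[sel], cc[sel]].sum())  # half-counts sum to N_o
            n_d = float(diag[rr[sel], cc[sel]].sum())
            chain_total = n_o + SQRT2 * n_d
            kimura_total = math.sqrt(n_d**2 + (n_d + n_o / 2) ** 2) + n_o / 2
            if chain_total > 0:
                shares[sel] = chain_px[sel] * (kimura_total / chain_total)
            else:  # isolated pixel: no links
                shares[sel] = 0.0

    if end_correction:
        if diameters_px is None:
            raise ValueError("end_correction requires diameters_px")
        radius = np.asarray(diameters_px, dtype=float) / 2.0
        deg = degree[rr, cc]
        shares = shares + radius * (deg == 1) + 2.0 * radius * (deg == 0)
    return float(shares.sum()), shares


@dataclass
class DiameterLengthHistogram:
    """Root length (cm) per diameter class (mm) — the pipeline's exchange table.

    Bins are fixed-width, half-open [lo, hi) except the last, which is
    closed above.  ``bin_edges`` starts at 0.
    """

    bin_edges: np.ndarray  # (n_bins + 1,) ascending, in mm, first edge 0
    length_per_bin: np.ndarray  # (n_bins,) in cm, >= 0
    plant_id: str = ""
    n_trays: int = 1

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.length_per_bin = np.asarray(self.length_per_bin, dtype=float)
        if self.bin_edges.ndim != 1 or self.bin_edges.size < 2:
            raise ValueError("need at least one bin")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly ascending")
        if self.length_per_bin.shape != (self.bin_edges.size - 1,):
            raise ValueError("length_per_bin must have one entry per bin")
        if (self.length_per_bin < 0).any() or not np.isfinite(
            self.length_per_bin
        ).all():
            raise ValueError("bin lengths must be finite and >= 0")

    @property
    def n_bins(self) -> int:
        return self.length_per_bin.size

    @property
    def midpoints_mm(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_length_cm(self) -> float:
        return float(self.length_per_bin.sum())

    def bin_index(self, diameter_mm) -> np.ndarray:
        """Bin of each diameter; the last bin is closed above (overflow bin)."""
        d = np.asarray(diameter_mm, dtype=float)
        width = self.bin_edges[1] - self.bin_edges[0]
        idx = np.floor((d - self.bin_edges[0]) / width).astype(int)
        return np.clip(idx, 0, self.n_bins - 1)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_lo_mm": self.bin_edges[:-1],
                "bin_hi_mm": self.bin_edges[1:],
                "length_cm": self.length_per_bin,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, plant_id: str = "", n_trays: int = 1):
        import pandas as pd

        df = pd.read_csv(path)
        edges = np.append(df["bin_lo_mm"].to_numpy(), df["bin_hi_mm"].iloc[-1])
        return cls(edges, df["length_cm"].to_numpy(), plant_id, n_trays)


def empty_histogram(
    bin_width_mm: float = 0.1,
    max_diameter_mm: float = 6.0,
    plant_id: str = "",
) -> DiameterLengthHistogram:
    n_bins = max(int(math.ceil(max_diameter_mm / bin_width_mm)), 1)
    edges = np.arange(n_bins + 1) * bin_width_mm
    return DiameterLengthHistogram(edges, np.zeros(n_bins), plant_id=plant_id)


def build_histogram(
    skeleton: Skeleton,
    diameters_px: np.ndarray,
    shares_px: np.ndarray,
    calib: ScaleCalibration,
    bin_width_mm: float = 0.1,
    max_diameter_mm: float = 6.0,
    plant_id: str = "",
) -> DiameterLengthHistogram:
    """Accumulate each skeleton pixel's length share into its diameter class.

    Shares are converted px -> cm and diameters px -> mm via ``calib``; the
    histogram's total mass equals the summed shares exactly (to float
    round-off).  Diameters beyond ``max_diameter_mm`` land in the last
    (closed-above) bin so that histograms from different trays share one
    fixed edge grid and can be cumulated without rebinning.
    """
    if bin_width_mm <= 0:
        raise ValueError("bin_width_mm must be positive")
    hist = empty_histogram(bin_width_mm, max_diameter_mm, plant_id=plant_id)
    if skeleton.n_pixels == 0:
        return hist
    d_mm = calib.px_to_mm(diameters_px)
    l_cm = calib.px_to_cm(shares_px)
    idx = hist.bin_index(d_mm)
    np.add.at(hist.length_per_bin, idx, l_cm)
    return hist
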