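"""Synthetic root-tray scenes with exact ground truth.

Emulates the imaging protocol: washed roots separated (non-overlapping) on
a bright DIN-A4 board, photographed ~5 times with per-exposure sensor
noise.  A scene holds a dark surround, the bright board, dark smooth root
strokes with a bimodal width distribution (fine fibrous vs. thick storage),
compact dirt blobs of intermediate intensity, and — per exposure — Gaussian
noise plus transient impulse specks (so the stack median has work to do).

Ground truth is recorded before any noise: exact centerline arc length and
constant width per stroke, the board geometry, and the dirt inventory.
Widths are drawn uniformly and then snapped to the diameter-class grid
(0.1 mm bins by default) so that traits computed from the stroke list and
traits computed from the truth histogram agree exactly.

The truth raster marks a pixel as root iff its center lies within width/2
of the centerline; rendering anti-aliases the same distance field with a
1-px linear ramp, so softness of the rendering never redefines the truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from .imaging import RasterImage, ScaleCalibration, TrayImageStack
from .measure import DiameterLengthHistogram, empty_histogram
from .traits import RootTraits

__all__ = [
    "SceneParams",
    "StrokeSpec",
    "TrayGroundTruth",
    "PlacementError",
    "generate_tray",
    "truth_traits",
]


class PlacementError(RuntimeError):
    """Stroke/dirt placement failed; advise fewer or shorter strokes."""


@dataclass
class SceneParams:
    """Scene layout and rendering parameters.

    Defaults reproduce the reference imaging conditions: a DIN-A4 board at
    450 DPI, ~5 exposures, fibrous widths 0.3-0.8 mm vs. storage widths
    1.5-4 mm, stroke lengths 2-20 cm.  Smaller trays/DPI are used for fast
    tests; pass the corresponding overrides.
    """

    dpi: float = 450.0
    tray_width_cm: float = 21.0
    tray_height_cm: float = 29.7
    frame_margin_cm: float = 0.8  # dark surround outside the bright board
    tilt_deg: float = 0.0  # board rotation about the image center
    n_fibrous: int = 10
    n_storage: int = 3
    fibrous_width_mm: tuple[float, float] = (0.3, 0.8)
    storage_width_mm: tuple[float, float] = (1.5, 4.0)
    length_cm: tuple[float, float] = (2.0, 20.0)
    n_dirt: int = 5
    dirt_radius_mm: tuple[float, float] = (0.5, 2.0)
    outer_intensity: float = 0.05
    board_intensity: float = 0.95
    root_intensity: float = 0.18
    dirt_intensity: float = 0.55
    noise_sd: float = 0.02
    n_exposures: int = 5
    n_specks: int = 150  # transient impulse specks per exposure
    clearance_mm: float = 0.4  # minimum gap between rendered objects
    rejection_limit: int = 200
    turn_sd_fibrous: float = 0.10  # heading jitter per 0.5 mm step, radians
    turn_sd_storage: float = 0.035  # storage roots are stiffer
    bin_width_mm: float = 0.1
    max_diameter_mm: float = 6.0

    @classmethod
    def quarter_a4(cls, **overrides) -> "SceneParams":
        """Quarter-scale board at full 450 DPI (fast but faithful geometry)."""
        defaults = dict(
            tray_width_cm=10.5,
            tray_height_cm=14.85,
            frame_margin_cm=0.5,
            length_cm=(2.0, 10.0),
            n_fibrous=8,
            n_storage=3,
            n_specks=60,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def mini(cls, **overrides) -> "SceneParams":
        """Small low-resolution tray for batch tests."""
        defaults = dict(
            dpi=250.0,
            tray_width_cm=6.0,
            tray_height_cm=8.0,
            frame_margin_cm=0.4,
            length_cm=(1.5, 5.0),
            n_fibrous=5,
            n_storage=2,
            n_dirt=3,
            n_specks=30,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class StrokeSpec:
    """One rendered root stroke and its exact truth."""

    control_points: np.ndarray  # (N, 2) float (row, col) centerline polyline, px
    width_mm: float
    class_label: str  # "fibrous" | "storage"
    true_length_cm: float

    def to_jsonable(self) -> dict:
        return {
            "control_points": np.asarray(self.control_points).round(2).tolist(),
            "width_mm": self.width_mm,
            "class_label": self.class_label,
            "true_length_cm": self.true_length_cm,
        }


@dataclass
class TrayGroundTruth:
    """Everything the generator knows about one tray, noise-free."""

    strokes: list[StrokeSpec]
    board_interior: tuple[int, int, int, int]  # half-open (r0, r1, c0, c1)
    board_corners: np.ndarray  # (4, 2) float (row, col)
    dirt_blobs: list[tuple[float, float, float]]  # (row, col, radius_px)
    seed: int
    dpi: float
    bin_width_mm: float = 0.1
    max_diameter_mm: float = 6.0
    root_mask: np.ndarray | None = None  # truth raster (not serialized)
    frame_mask: np.ndarray | None = None  # surround + board edge (not serialized)
    dirt_mask: np.ndarray | None = None  # (not serialized)
    clean_image: np.ndarray | None = None  # noise-free scene (not serialized)

    def truth_histogram(self, plant_id: str = "") -> DiameterLengthHistogram:
        hist = empty_histogram(self.bin_width_mm, self.max_diameter_mm, plant_id)
        for s in self.strokes:
            idx = int(hist.bin_index(s.width_mm))
            hist.length_per_bin[idx] += s.true_length_cm
        return hist

    def to_jsonable(self) -> dict:
        return {
            "seed": self.seed,
            "dpi": self.dpi,
            "bin_width_mm": self.bin_width_mm,
            "max_diameter_mm": self.max_diameter_mm,
            "board_interior": list(self.board_interior),
            "board_corners": np.asarray(self.board_corners).round(2).tolist(),
            "dirt_blobs": [list(b) for b in self.dirt_blobs],
            "strokes": [s.to_jsonable() for s in self.strokes],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_jsonable(), fh)

    @classmethod
    def from_jsonable(cls, data: dict) -> "TrayGroundTruth":
        strokes = [
            StrokeSpec(
                np.asarray(s["control_points"], dtype=float),
                s["width_mm"],
                s["class_label"],
                s["true_length_cm"],
            )
            for s in data["strokes"]
        ]
        return cls(
            strokes=strokes,
            board_interior=tuple(data["board_interior"]),
            board_corners=np.asarray(data["board_corners"], dtype=float),
            dirt_blobs=[tuple(b) for b in data["dirt_blobs"]],
            seed=data["seed"],
            dpi=data["dpi"],
            bin_width_mm=data["bin_width_mm"],
            max_diameter_mm=data["max_diameter_mm"],
        )

    @classmethod
    def load_json(cls, path) -> "TrayGroundTruth":
        with open(path) as fh:
            return cls.from_jsonable(json.load(fh))


def truth_traits(truth: TrayGroundTruth, threshold_mm: float) -> RootTraits:
    """Exact traits from the stroke list, bypassing any imaging.

    Uses the same cylinder formulas and the same tie rule (fibrous strictly
    below the threshold) as the analysis path; because stroke widths sit on
    the diameter-class grid, this equals ``cylinder_traits`` applied to the
    truth histogram, exactly.
    """
    fl = sl = fv = sv = fa = sa = fr_num = sr_num = 0.0
    for s in truth.strokes:
        w, L = s.width_mm, s.true_length_cm
        vol = math.pi * (w / 20.0) ** 2 * L
        area = math.pi * (w / 10.0) * L
        if w < threshold_mm:
            fl += L
            fv += vol
            fa += area
            fr_num += (w / 2.0) * L
        else:
            sl += L
            sv += vol
            sa += area
            sr_num += (w / 2.0) * L
    flags = []
    if fl == 0:
        flags.append("empty fibrous class")
    if sl == 0:
        flags.append("empty storage class")
    return RootTraits(
        plant_id="truth",
        fibrous_length_cm=fl,
        storage_length_cm=sl,
        fibrous_volume_cm3=fv,
        storage_volume_cm3=sv,
        fibrous_area_cm2=fa,
        storage_area_cm2=sa,
        fibrous_mean_radius_mm=fr_num / fl if fl > 0 else 0.0,
        storage_mean_radius_mm=sr_num / sl if sl > 0 else 0.0,
        threshold_mm=threshold_mm,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# scene construction helpers


def _snap_width(width_mm: float, bin_width_mm: float) -> float:
    """Snap a width to the nearest diameter-class midpoint."""
    return (math.floor(width_mm / bin_width_mm) + 0.5) * bin_width_mm


def _board_coverage(shape, corners):
    """Per-pixel coverage of the (possibly tilted) board rectangle.

    Coverage is a 1-px linear ramp on the signed distance to the rectangle
    boundary (min over the four inward half-plane distances).
    """
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    dmin = np.full(shape, np.inf)
    n = len(corners)
    center = corners.mean(axis=0)
    for i in range(n):
        a, b = corners[i], corners[(i + 1) % n]
        edge = b - a
        normal = np.array([-edge[1], edge[0]])
        normal /= np.linalg.norm(normal)
        if np.dot(center - a, normal) < 0:
            normal = -normal  # inward
        dist = (rows - a[0]) * normal[0] + (cols - a[1]) * normal[1]
        dmin = np.minimum(dmin, dist)
    return np.clip(dmin + 0.5, 0.0, 1.0), dmin


def _stroke_path(
    rng: np.random.Generator,
    box: tuple[float, float, float, float],
    length_px: float,
    ds_px: float,
    turn_sd: float,
):
    """Random smooth polyline of exact arc length inside an axis-aligned box.

    A constant-step random walk with heading jitter; near the box boundary
    the heading is steered toward the box center.  Returns (N, 2) float
    points or None when the walk got stuck.
    """
    r0, r1, c0, c1 = box
    center = np.array([(r0 + r1) / 2, (c0 + c1) / 2])
    pt = np.array(
        [rng.uniform(r0, r1), rng.uniform(c0, c1)]
    )
    heading = rng.uniform(0, 2 * math.pi)
    n_steps = max(int(round(length_px / ds_px)), 1)
    pts = [pt.copy()]
    for _ in range(n_steps):
        heading += rng.normal(0, turn_sd)
        for _ in range(40):
            direction = np.array([math.sin(heading), math.cos(heading)])
            look = pt + 4 * ds_px * direction
            if r0 <= look[0] <= r1 and c0 <= look[1] <= c1:
                break
            to_center = math.atan2(center[0] - pt[0], center[1] - pt[1])
            diff = (to_center - heading + math.pi) % (2 * math.pi) - math.pi
            heading += np.clip(diff, -0.3, 0.3)
        else:
            return None
        pt = pt + ds_px * np.array([math.sin(heading), math.cos(heading)])
        if not (r0 <= pt[0] <= r1 and c0 <= pt[1] <= c1):
            return None
        pts.append(pt.copy())
    return np.array(pts)


def _self_overlapping(points: np.ndarray, radius_px: float, ds_px: float) -> bool:
    """True when two non-adjacent stretches of the centerline come closer
    than one stroke width (the rendered band would merge with itself)."""
    tree = cKDTree(points)
    pairs = tree.query_pairs(r=2 * radius_px + 2.0, output_type="ndarray")
    if pairs.size == 0:
        return False
    gap = np.abs(pairs[:, 0] - pairs[:, 1])
    min_gap = (2 * radius_px + 4.0) / ds_px
    return bool((gap > min_gap).any())


def _distance_field(points: np.ndarray, shape, reach_px: float):
    """Exact distance to a densely-sampled centerline, on a local band.

    Returns (rows, cols, dist) for pixels within ``reach_px`` of the
    rasterized centerline (a coarse EDT preselects candidates, then a
    KD-tree gives exact distances to the dense samples).
    """
    h, w = shape
    pad = int(math.ceil(reach_px)) + 2
    rmin = max(int(points[:, 0].min()) - pad, 0)
    rmax = min(int(points[:, 0].max()) + pad + 1, h)
    cmin = max(int(points[:, 1].min()) - pad, 0)
    cmax = min(int(points[:, 1].max()) + pad + 1, w)
    local = np.ones((rmax - rmin, cmax - cmin), dtype=bool)
    rr = np.clip(np.rint(points[:, 0]).astype(int) - rmin, 0, rmax - rmin - 1)
    cc = np.clip(np.rint(points[:, 1]).astype(int) - cmin, 0, cmax - cmin - 1)
    local[rr, cc] = False
    coarse = distance_transform_edt(local)
    cand = np.nonzero(coarse <= reach_px + 1.0)
    if cand[0].size == 0:
        return (np.empty(0, int),) * 2 + (np.empty(0),)
    tree = cKDTree(points)
    pix = np.column_stack([cand[0] + rmin, cand[1] + cmin]).astype(float)
    dist, _ = tree.query(pix, workers=1)
    return cand[0] + rmin, cand[1] + cmin, dist


def _densify(points: np.ndarray, spacing_px: float) -> np.ndarray:
    """Resample a polyline at roughly ``spacing_px`` spacing."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    n = max(int(math.ceil(total / spacing_px)) + 1, 2)
    t = np.linspace(0.0, total, n)
    rows = np.interp(t, arclen, points[:, 0])
    cols = np.interp(t, arclen, points[:, 1])
    return np.column_stack([rows, cols])


def generate_tray(
    params: SceneParams | None = None,
    seed: int = 0,
    tray_id: str = "tray",
    plant_id: str = "plant",
) -> tuple[TrayImageStack, TrayGroundTruth]:
    """Render one tray's exposure stack and its exact ground truth."""
    params = params or SceneParams()
    rng = np.random.default_rng(seed)
    calib = ScaleCalibration(params.dpi)
    h = int(round(calib.cm_to_px(params.tray_height_cm)))
    w = int(round(calib.cm_to_px(params.tray_width_cm)))
    shape = (h, w)
    margin_px = calib.cm_to_px(params.frame_margin_cm)

    # board rectangle (optionally tilted about the image center)
    base = np.array(
        [
            [margin_px, margin_px],
            [margin_px, w - 1 - margin_px],
            [h - 1 - margin_px, w - 1 - margin_px],
            [h - 1 - margin_px, margin_px],
        ],
        dtype=float,
    )
    if params.tilt_deg:
        ang = math.radians(params.tilt_deg)
        rot = np.array(
            [[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]]
        )
        ctr = np.array([(h - 1) / 2, (w - 1) / 2])
        corners = (base - ctr) @ rot.T + ctr
    else:
        corners = base
    board_cov, board_dist = _board_coverage(shape, corners)
    clean = params.outer_intensity * (1 - board_cov) + params.board_intensity * board_cov
    frame_mask = board_dist < 0.5  # surround plus the board edge itself

    # axis-aligned placement box strictly inside the (possibly tilted) board
    inset = margin_px + abs(math.sin(math.radians(params.tilt_deg))) * max(h, w) / 2
    r0_int = int(math.floor(inset)) + 1
    r1_int = int(math.ceil(h - 1 - inset))
    c0_int = int(math.floor(inset)) + 1
    c1_int = int(math.ceil(w - 1 - inset))
    board_interior = (r0_int, r1_int, c0_int, c1_int)

    clear_px = calib.mm_to_px(params.clearance_mm)
    ds_px = calib.cm_to_px(0.05)  # 0.5 mm steps along the centerline
    occupancy = np.zeros(shape, dtype=bool)
    root_mask = np.zeros(shape, dtype=bool)
    dirt_mask = np.zeros(shape, dtype=bool)
    strokes: list[StrokeSpec] = []

    jobs = [("storage", params.storage_width_mm, params.turn_sd_storage)] * params.n_storage
    jobs += [("fibrous", params.fibrous_width_mm, params.turn_sd_fibrous)] * params.n_fibrous
    for label, width_range, turn_sd in jobs:
        width_mm = _snap_width(rng.uniform(*width_range), params.bin_width_mm)
        radius_px = calib.mm_to_px(width_mm) / 2.0
        pad = radius_px + clear_px + 1
        box = (r0_int + pad, r1_int - pad, c0_int + pad, c1_int - pad)
        if box[0] >= box[1] or box[2] >= box[3]:
            raise PlacementError("tray too small for the requested stroke width")
        placed = False
        for _ in range(params.rejection_limit):
            length_px = calib.cm_to_px(rng.uniform(*params.length_cm))
            path = _stroke_path(rng, box, length_px, ds_px, turn_sd)
            if path is None:
                continue
            dense = _densify(path, 0.35)
            if _self_overlapping(dense, radius_px, 0.35):
                continue
            rr, cc, dist = _distance_field(dense, shape, radius_px + clear_px)
            band = dist <= radius_px + clear_px
            if occupancy[rr[band], cc[band]].any():
                continue
            # exact truth raster and anti-aliased rendering share one field
            inside = dist <= radius_px
            cov = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
            clean[rr, cc] = clean[rr, cc] * (1 - cov) + params.root_intensity * cov
            root_mask[rr[inside], cc[inside]] = True
            occupancy[rr[band], cc[band]] = True
            seg_len = np.linalg.norm(np.diff(path, axis=0), axis=1).sum()
            strokes.append(
                StrokeSpec(
                    control_points=path,
                    width_mm=width_mm,
                    class_label=label,
                    true_length_cm=float(calib.px_to_cm(seg_len)),
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place a {label} stroke after "
                f"{params.rejection_limit} attempts; use fewer or shorter strokes"
            )

    dirt_blobs: list[tuple[float, float, float]] = []
    for _ in range(params.n_dirt):
        r_px = calib.mm_to_px(rng.uniform(*params.dirt_radius_mm))
        placed = False
        for _ in range(params.rejection_limit):
            cy = rng.uniform(r0_int + r_px + clear_px, r1_int - r_px - clear_px)
            cx = rng.uniform(c0_int + r_px + clear_px, c1_int - r_px - clear_px)
            pad = int(math.ceil(r_px + clear_px)) + 2
            rs = slice(max(int(cy) - pad, 0), min(int(cy) + pad + 1, h))
            cs = slice(max(int(cx) - pad, 0), min(int(cx) + pad + 1, w))
            rows, cols = np.mgrid[rs, cs]
            dist = np.hypot(rows - cy, cols - cx)
            if occupancy[rs, cs][dist <= r_px + clear_px].any():
                continue
            # mildly irregular boundary: low-order angular perturbation
            ang = np.arctan2(rows - cy, cols - cx)
            wobble = np.zeros_like(dist)
            for k in (2, 3, 4):
                wobble += rng.normal(0, 0.03) * np.cos(k * ang + rng.uniform(0, 2 * np.pi))
            r_local = r_px * (1.0 + wobble)
            cov = np.clip(r_local + 0.5 - dist, 0.0, 1.0)
            patch = clean[rs, cs]
            clean[rs, cs] = patch * (1 - cov) + params.dirt_intensity * cov
            inside = dist <= r_local
            dirt_mask[rs, cs] |= inside
            occupancy[rs, cs] |= dist <= r_px + clear_px
            dirt_blobs.append((float(cy), float(cx), float(r_px)))
            placed = True
            break
        if not placed:
            raise PlacementError("could not place a dirt blob; reduce n_dirt")

    images = []
    for _ in range(params.n_exposures):
        frame = clean + rng.normal(0.0, params.noise_sd, size=shape)
        if params.n_specks > 0:
            sr = rng.integers(0, h, params.n_specks)
            sc = rng.integers(0, w, params.n_specks)
            frame[sr, sc] = rng.uniform(0.0, 0.1, params.n_specks)  # dark impulses
        images.append(RasterImage(np.clip(frame, 0.0, 1.0), dpi=params.dpi))

    stack = TrayImageStack(images, tray_id=tray_id, plant_id=plant_id)
    truth = TrayGroundTruth(
        strokes=strokes,
        board_interior=board_interior,
        board_corners=corners,
        dirt_blobs=dirt_blobs,
        seed=seed,
        dpi=params.dpi,
        bin_width_mm=params.bin_width_mm,
        max_diameter_mm=params.max_diameter_mm,
        root_mask=root_mask,
        frame_mask=frame_mask,
        dirt_mask=dirt_mask,
        clean_image=clean,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# batch simulation


def generate_plant(
    params: SceneParams | None = None,
    seed: int = 0,
    n_trays: int = 1,
    plant_id: str = "plant",
) -> tuple[list[TrayImageStack], list[TrayGroundTruth]]:
    """Generate one plant's trays (independent scenes, one plant label)."""
    stacks, truths = [], []
    for t in range(n_trays):
        stack, truth = generate_tray(
            params,
            seed=seed + 7919 * t,
            tray_id=f"{plant_id}_t{t}",
            plant_id=plant_id,
        )
        stacks.append(stack)
        truths.append(truth)
    return stacks, truths


def plant_truth_row(
    truths: list[TrayGroundTruth], plant_id: str, threshold_mm: float = 1.0
) -> dict:
    """Exact per-plant trait row cumulated over the plant's trays."""
    combined = TrayGroundTruth(
        strokes=[s for t in truths for s in t.strokes],
        board_interior=truths[0].board_interior,
        board_corners=truths[0].board_corners,
        dirt_blobs=[b for t in truths for b in t.dirt_blobs],
        seed=truths[0].seed,
        dpi=truths[0].dpi,
        bin_width_mm=truths[0].bin_width_mm,
        max_diameter_mm=truths[0].max_diameter_mm,
    )
    tt = truth_traits(combined, threshold_mm)
    return {
        "plant_id": plant_id,
        "fibrous_length_cm": tt.fibrous_length_cm,
        "storage_length_cm": tt.storage_length_cm,
        "fibrous_volume_cm3": tt.fibrous_volume_cm3,
        "storage_volume_cm3": tt.storage_volume_cm3,
        "fibrous_area_cm2": tt.fibrous_area_cm2,
        "storage_area_cm2": tt.storage_area_cm2,
        "total_length_cm": tt.total_length_cm,
        "total_volume_cm3": tt.total_volume_cm3,
        "total_area_cm2": tt.total_area_cm2,
    }


def simulate_batch(
    out_dir,
    n_plants: int = 6,
    params: SceneParams | None = None,
    seed: int = 0,
    trays_per_plant: int = 1,
    experiment: str = "E1",
    cultivar: str = "synthetic",
    treatment: str = "control",
):
    """Write a simulated experiment to disk: multi-page TIFF stacks, a
    manifest CSV, per-tray truth JSON and a per-plant truth trait CSV.

    Returns (manifest_path, truth_csv_path).
    """
    import os

    import pandas as pd
    import tifffile

    params = params or SceneParams()
    os.makedirs(out_dir, exist_ok=True)
    manifest_rows = []
    truth_rows = []
    for p in range(n_plants):
        plant_id = f"{experiment}_p{p:03d}"
        stacks, truths = generate_plant(
            params, seed=seed + 104729 * p, n_trays=trays_per_plant,
            plant_id=plant_id,
        )
        for stack, truth in zip(stacks, truths):
            pages = np.stack(
                [np.rint(im.pixels * 65535).astype(np.uint16) for im in stack.images]
            )
            tif_path = os.path.join(out_dir, f"{stack.tray_id}.tif")
            tifffile.imwrite(tif_path, pages)
            truth.save_json(os.path.join(out_dir, f"{stack.tray_id}_truth.json"))
            manifest_rows.append(
                {
                    "plant_id": plant_id,
                    "cultivar": cultivar,
                    "treatment": treatment,
                    "experiment": experiment,
                    "tray_id": stack.tray_id,
                    "images": tif_path,
                    "dpi": params.dpi,
                }
            )
        truth_rows.append(plant_truth_row(truths, plant_id))
    manifest_path = os.path.join(out_dir, "manifest.csv")
    truth_path = os.path.join(out_dir, "truth_traits.csv")
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False)
    return manifest_path, truth_path
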