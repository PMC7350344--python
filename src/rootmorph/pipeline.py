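"""End-to-end orchestration: tray stacks -> per-plant root traits.

Per tray: median-project the exposure stack, convert to grayscale, detect
and crop the bright board via the Hough transform, fit the Gaussian
mixture, classify root pixels by posterior, clean the mask and remove
dirt, skeletonize, and accumulate the diameter-versus-length histogram.
Per plant: cumulate tray histograms, split fibrous/storage at the Otsu
threshold, and apply cylinder geometry.  Batches pool plants across
experiments and can be validated against generator ground truth.

Determinism: one global seed; each tray derives a stable sub-seed from
(seed, tray_id) via CRC32, so runs are bit-reproducible and trays are
independent.
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import frame as frame_mod
from . import imaging, measure, segmentation, traits as traits_mod
from .imaging import RasterImage, TrayImageStack
from .measure import DiameterLengthHistogram
from .traits import (
    DegenerateHistogramError,
    RootTraits,
    ValidationReport,
    coefficient_of_determination,
)

__all__ = [
    "PipelineConfig",
    "TrayResult",
    "run_tray",
    "run_plant",
    "run_batch",
    "read_manifest",
    "validate_against_truth",
    "derive_seed",
]

logger = logging.getLogger("rootmorph")

REFERENCE_DPI = 450.0  # pixel-area thresholds below are stated at this DPI

TRAIT_COLUMNS = [
    "plant_id",
    "cultivar",
    "treatment",
    "experiment",
    "fibrous_length_cm",
    "storage_length_cm",
    "fibrous_volume_cm3",
    "storage_volume_cm3",
    "fibrous_area_cm2",
    "storage_area_cm2",
    "fibrous_mean_radius_mm",
    "storage_mean_radius_mm",
    "total_length_cm",
    "total_volume_cm3",
    "total_area_cm2",
    "otsu_threshold_mm",
    "flags",
]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ImagingConfig(_Section):
    spatial_median: bool = False  # optional extra in-plane 3x3 median


class FrameConfig(_Section):
    rho_res_px: float = 1.0
    theta_res_deg: float = 0.5
    min_votes_frac: float = 0.3  # fraction of min(image dimensions)
    max_tilt_deg: float = 5.0
    safety_margin_px: int = 3
    edge_low: float = 0.1
    edge_high: float = 0.3
    edge_sigma: float = 1.0
    required: bool = True


class SegConfig(_Section):
    K: int = 3  # bright board, dark root, intermediate dirt/shadow
    feature_space: str = "gray"
    root_components: str | list[int] = "darkest"
    n_root_components: int = 1
    min_posterior: float = 0.5
    min_separation_sd: float = 6.0  # root comp must sit this far below the board
    max_samples: int = 100_000
    max_iter: int = 300
    tol: float = 1e-6


class DirtConfig(_Section):
    # areas are stated at the 450 DPI reference and rescaled by (dpi/450)^2
    min_elongation: float = 3.0
    max_solidity: float = 0.5
    min_solidity_area_px: int = 200
    max_area_px: int = 50_000
    min_speck_px: int = 25
    fill_hole_px: int = 100


class MeasureConfig(_Section):
    method: str = "kimura"
    end_correction: bool = True
    bin_width_mm: float = 0.1
    max_diameter_mm: float = 6.0


class TraitConfig(_Section):
    global_otsu: bool = False  # one threshold across all plants instead of per plant


class PipelineConfig(_Section):
    """Validated pipeline configuration; unknown keys are rejected."""

    imaging: ImagingConfig = Field(default_factory=ImagingConfig)
    frame: FrameConfig = Field(default_factory=FrameConfig)
    seg: SegConfig = Field(default_factory=SegConfig)
    dirt: DirtConfig = Field(default_factory=DirtConfig)
    measure: MeasureConfig = Field(default_factory=MeasureConfig)
    trait: TraitConfig = Field(default_factory=TraitConfig)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return f"{zlib.crc32(blob):08x}"


def derive_seed(seed: int, tray_id: str) -> int:
    """Stable per-tray sub-seed: CRC32 of the tray id mixed with the seed."""
    return (zlib.crc32(tray_id.encode()) ^ (seed * 2654435761)) % (2**31)


def _area_scale(dpi: float) -> float:
    return (dpi / REFERENCE_DPI) ** 2


@dataclass
class TrayResult:
    """Per-tray histogram plus intermediate artifacts for inspection."""

    histogram: DiameterLengthHistogram
    projected: RasterImage | None = None
    cropped: RasterImage | None = None
    mask: "imaging.BinaryMask | None" = None
    removed_components: list = field(default_factory=list)
    model: "segmentation.MixtureModel | None" = None
    frame_geometry: "frame_mod.FrameGeometry | None" = None


def run_tray(
    stack: TrayImageStack,
    config: PipelineConfig | None = None,
    keep_intermediates: bool = False,
) -> TrayResult:
    """Run the whole per-tray pipeline and return its diameter-length table."""
    cfg = config or PipelineConfig()
    tray_seed = derive_seed(cfg.seed, stack.tray_id)
    dpi = stack.dpi
    calib = imaging.ScaleCalibration(dpi)
    scale = _area_scale(dpi)

    projected = imaging.median_project(stack)
    gray = imaging.to_grayscale(projected)
    if cfg.imaging.spatial_median:
        gray = imaging.spatial_median(gray)

    geom = None
    try:
        edges = frame_mod.detect_edges(
            gray, low=cfg.frame.edge_low, high=cfg.frame.edge_high,
            sigma=cfg.frame.edge_sigma,
        )
        min_votes = int(cfg.frame.min_votes_frac * min(gray.height_px, gray.width_px))
        lines = frame_mod.hough_lines(
            edges,
            rho_res=cfg.frame.rho_res_px,
            theta_res=math.radians(cfg.frame.theta_res_deg),
            min_votes=min_votes,
        )
        geom = frame_mod.fit_frame(
            lines,
            (gray.height_px, gray.width_px),
            max_tilt=math.radians(cfg.frame.max_tilt_deg),
            safety_margin_px=cfg.frame.safety_margin_px,
        )
        interior = frame_mod.crop_interior(gray, geom)
    except frame_mod.FrameNotFoundError as exc:
        if cfg.frame.required:
            raise frame_mod.FrameNotFoundError(
                f"tray {stack.tray_id}: {exc}"
            ) from exc
        logger.warning("tray %s: %s — processing full image", stack.tray_id, exc)
        interior = gray

    samples = segmentation.sample_pixels(
        interior, max_samples=cfg.seg.max_samples, seed=tray_seed
    )
    model = segmentation.fit_mixture(
        samples,
        K=cfg.seg.K,
        seed=tray_seed,
        max_iter=cfg.seg.max_iter,
        tol=cfg.seg.tol,
        feature_space=cfg.seg.feature_space,
    )
    if cfg.seg.root_components == "darkest":
        root_comps = segmentation.select_root_components(
            model, cfg.seg.n_root_components, cfg.seg.min_separation_sd
        )
    else:
        root_comps = set(cfg.seg.root_components)
    if root_comps:
        posterior = segmentation.posterior_map(interior, model)
        mask = segmentation.classify_root_pixels(
            posterior, root_comps, min_posterior=cfg.seg.min_posterior
        )
    else:  # no component is dark enough to be root: empty root system
        logger.info("tray %s: no root-like mixture component", stack.tray_id)
        mask = imaging.BinaryMask(
            np.zeros((interior.height_px, interior.width_px), bool), dpi=dpi
        )
    mask = segmentation.clean_mask(
        mask,
        min_speck_px=max(int(round(cfg.dirt.min_speck_px * scale)), 1),
        fill_hole_px=int(round(cfg.dirt.fill_hole_px * scale)),
    )
    mask, removed = segmentation.remove_dirt(
        mask,
        min_elongation=cfg.dirt.min_elongation,
        max_area_px=int(round(cfg.dirt.max_area_px * scale)),
        max_solidity=cfg.dirt.max_solidity,
        min_solidity_area_px=max(int(round(cfg.dirt.min_solidity_area_px * scale)), 1),
    )

    skeleton = measure.skeletonize_mask(mask)
    diameters = measure.local_diameters(mask, skeleton)
    total_px, shares = measure.skeleton_length(
        skeleton,
        method=cfg.measure.method,
        end_correction=cfg.measure.end_correction,
        diameters_px=diameters,
    )
    hist = measure.build_histogram(
        skeleton,
        diameters,
        shares,
        calib,
        bin_width_mm=cfg.measure.bin_width_mm,
        max_diameter_mm=cfg.measure.max_diameter_mm,
        plant_id=stack.plant_id,
    )
    logger.info(
        "tray %s: %d root px, %d removed components, skeleton %.1f px "
        "(%.2f cm), config %s",
        stack.tray_id,
        mask.area_px(),
        sum(1 for s in removed if s.removed),
        total_px,
        hist.total_length_cm,
        cfg.config_hash(),
    )
    result = TrayResult(histogram=hist)
    if keep_intermediates:
        result.projected = projected
        result.cropped = interior
        result.mask = mask
        result.removed_components = removed
        result.model = model
        result.frame_geometry = geom
    return result


def _split_and_measure(
    cum: DiameterLengthHistogram,
    threshold: "traits_mod.ClassThreshold | None" = None,
) -> RootTraits:
    """Otsu split (or a supplied threshold) plus cylinder traits, with the
    degenerate-histogram fallback: all mass fibrous, flagged."""
    try:
        if threshold is None:
            threshold = traits_mod.otsu_split(cum)
        plant_traits = traits_mod.cylinder_traits(cum, threshold)
    except DegenerateHistogramError:
        threshold = traits_mod.ClassThreshold(
            diameter_mm=float(cum.bin_edges[-1]), between_class_variance=0.0
        )
        plant_traits = traits_mod.cylinder_traits(cum, threshold)
        plant_traits.flags.append("degenerate histogram: all mass fibrous")
    return plant_traits


def run_plant(
    stacks: list[TrayImageStack],
    config: PipelineConfig | None = None,
    threshold: "traits_mod.ClassThreshold | None" = None,
) -> tuple[RootTraits, DiameterLengthHistogram]:
    """Cumulate one plant's trays and split into fibrous/storage traits.

    ``threshold`` overrides the per-plant Otsu split (used by the global
    threshold mode).
    """
    cfg = config or PipelineConfig()
    if not stacks:
        raise ValueError("a plant needs at least one tray")
    hists = [run_tray(s, cfg).histogram for s in stacks]
    cum = traits_mod.cumulate(hists)
    cum.plant_id = stacks[0].plant_id
    plant_traits = _split_and_measure(cum, threshold)
    return plant_traits, cum


def read_manifest(path) -> "pandas.DataFrame":  # noqa: F821
    """Read an input manifest CSV.

    Columns: plant_id, cultivar, treatment, experiment, tray_id, images
    (semicolon-separated paths), dpi.
    """
    import pandas as pd

    df = pd.read_csv(path, dtype={"plant_id": str, "tray_id": str})
    required = {"plant_id", "tray_id", "images", "dpi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")
    if df["tray_id"].duplicated().any():
        raise ValueError("manifest has duplicate tray ids")
    return df


def run_batch(
    manifest: "pandas.DataFrame",  # noqa: F821
    config: PipelineConfig | None = None,
    load_stack=None,
) -> tuple["pandas.DataFrame", dict[str, str]]:  # noqa: F821
    """Process every plant in a manifest; failed plants are isolated.

    ``load_stack(row) -> TrayImageStack`` may be supplied to feed in-memory
    stacks (the simulator uses this); by default image paths are loaded
    from disk.  Returns (trait table, {plant_id: error}).
    """
    import pandas as pd

    cfg = config or PipelineConfig()

    def _default_loader(row):
        paths = [p for p in str(row["images"]).split(";") if p]
        return imaging.load_stack(
            paths,
            dpi=float(row["dpi"]),
            tray_id=str(row["tray_id"]),
            plant_id=str(row["plant_id"]),
        )

    loader = load_stack or _default_loader
    per_plant: dict[str, tuple] = {}
    failures: dict[str, str] = {}
    for plant_id, group in manifest.groupby("plant_id", sort=True):
        try:
            stacks = [loader(row) for _, row in group.iterrows()]
            hists = [run_tray(s, cfg).histogram for s in stacks]
            cum = traits_mod.cumulate(hists)
            cum.plant_id = str(plant_id)
            per_plant[str(plant_id)] = (group.iloc[0], cum)
        except Exception as exc:  # isolate per-plant failures
            logger.error("plant %s failed: %s", plant_id, exc)
            failures[str(plant_id)] = str(exc)
            continue

    global_threshold = None
    if cfg.trait.global_otsu and per_plant:
        pooled = traits_mod.cumulate([cum for _, cum in per_plant.values()])
        try:
            global_threshold = traits_mod.otsu_split(pooled)
        except DegenerateHistogramError:
            global_threshold = None

    rows = []
    for plant_id, (first, cum) in per_plant.items():
        plant_traits = _split_and_measure(cum, global_threshold)
        rows.append(
            {
                "plant_id": plant_id,
                "cultivar": first.get("cultivar", ""),
                "treatment": first.get("treatment", ""),
                "experiment": first.get("experiment", ""),
                "fibrous_length_cm": plant_traits.fibrous_length_cm,
                "storage_length_cm": plant_traits.storage_length_cm,
                "fibrous_volume_cm3": plant_traits.fibrous_volume_cm3,
                "storage_volume_cm3": plant_traits.storage_volume_cm3,
                "fibrous_area_cm2": plant_traits.fibrous_area_cm2,
                "storage_area_cm2": plant_traits.storage_area_cm2,
                "fibrous_mean_radius_mm": plant_traits.fibrous_mean_radius_mm,
                "storage_mean_radius_mm": plant_traits.storage_mean_radius_mm,
                "total_length_cm": plant_traits.total_length_cm,
                "total_volume_cm3": plant_traits.total_volume_cm3,
                "total_area_cm2": plant_traits.total_area_cm2,
                "otsu_threshold_mm": plant_traits.threshold_mm,
                "flags": ";".join(plant_traits.flags),
            }
        )
    table = pd.DataFrame(rows, columns=TRAIT_COLUMNS)
    return table, failures


def validate_against_truth(
    trait_table: "pandas.DataFrame",  # noqa: F821
    truth_table: "pandas.DataFrame",  # noqa: F821
    column: str = "total_volume_cm3",
) -> ValidationReport:
    """r² and per-plant relative errors between estimated and true traits."""
    merged = trait_table.merge(
        truth_table, on="plant_id", suffixes=("", "_truth"), validate="1:1"
    )
    est = merged[column].to_numpy(dtype=float)
    true = merged[f"{column}_truth"].to_numpy(dtype=float)
    report = coefficient_of_determination(true, est)
    rel = np.abs(est - true) / np.where(true != 0, true, np.nan)
    report.per_plant_relative_errors = {
        str(pid): float(e) for pid, e in zip(merged["plant_id"], rel)
    }
    return report
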