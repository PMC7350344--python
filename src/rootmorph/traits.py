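"""Per-plant trait extraction from diameter-length histograms.

Tray histograms are cumulated per plant, the length-weighted diameter
distribution is split into fibrous (thin) and storage (thick) roots at the
Otsu threshold — the bin edge maximizing the between-class variance
sigma_B^2(t) = w0*w1*(mu0 - mu1)^2 of the two classes' length fractions and
length-weighted mean diameters — and cylinder geometry turns each class
into length, volume, surface area and mean radius:

    per bin (midpoint d mm, length l cm):
        V = pi * (d/20)^2 * l   [cm^3]
        A = pi * (d/10)  * l    [cm^2]

Fibrous is strictly below the threshold; storage at or above it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .measure import DiameterLengthHistogram

__all__ = [
    "ClassThreshold",
    "RootTraits",
    "ValidationReport",
    "DegenerateHistogramError",
    "cumulate",
    "otsu_split",
    "cylinder_traits",
    "pool_experiments",
    "coefficient_of_determination",
]


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two occupied diameter classes.

    Guidance: classify all mass as fibrous (the pipeline does this and
    flags the plant) — severe infection can eliminate storage roots
    entirely, so a unimodal histogram is a legitimate outcome.
    """


@dataclass(frozen=True)
class ClassThreshold:
    """Fibrous/storage diameter threshold; always one of the bin edges."""

    diameter_mm: float
    between_class_variance: float
    method: str = "otsu"


@dataclass
class RootTraits:
    """Per-class and combined root traits of one plant."""

    plant_id: str
    fibrous_length_cm: float
    storage_length_cm: float
    fibrous_volume_cm3: float
    storage_volume_cm3: float
    fibrous_area_cm2: float
    storage_area_cm2: float
    fibrous_mean_radius_mm: float
    storage_mean_radius_mm: float
    threshold_mm: float
    flags: list[str] = field(default_factory=list)

    @property
    def total_length_cm(self) -> float:
        return self.fibrous_length_cm + self.storage_length_cm

    @property
    def total_volume_cm3(self) -> float:
        return self.fibrous_volume_cm3 + self.storage_volume_cm3

    @property
    def total_area_cm2(self) -> float:
        return self.fibrous_area_cm2 + self.storage_area_cm2


@dataclass
class ValidationReport:
    """Goodness of correspondence between two trait vectors."""

    r_squared: float
    n: int
    per_plant_relative_errors: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "r_squared": self.r_squared,
                    "n": self.n,
                    "per_plant_relative_errors": self.per_plant_relative_errors,
                },
                fh,
                indent=2,
            )


def cumulate(
    histograms: list[DiameterLengthHistogram],
) -> DiameterLengthHistogram:
    """Bin-wise sum of tray histograms (exact; no rebinning)."""
    if not histograms:
        raise ValueError("nothing to cumulate")
    ref = histograms[0]
    for i, h in enumerate(histograms[1:], start=1):
        if not np.array_equal(h.bin_edges, ref.bin_edges):
            raise ValueError(
                f"histogram {i} has mismatched bin edges; rebinning is not "
                "performed silently"
            )
    total = np.sum([h.length_per_bin for h in histograms], axis=0)
    plant_ids = {h.plant_id for h in histograms}
    return DiameterLengthHistogram(
        ref.bin_edges.copy(),
        total,
        plant_id=plant_ids.pop() if len(plant_ids) == 1 else "",
        n_trays=sum(h.n_trays for h in histograms),
    )


def otsu_split(histogram: DiameterLengthHistogram) -> ClassThreshold:
    """Otsu threshold on the length-weighted diameter distribution.

    Candidate thresholds are the interior bin edges; the winner maximizes
    the between-class variance, ties broken toward the smallest threshold.
    """
    w = histogram.length_per_bin
    if int((w > 0).sum()) < 2:
        raise DegenerateHistogramError(
            "fewer than two occupied diameter classes; classify all mass "
            "as fibrous"
        )
    d = histogram.midpoints_mm
    total = w.sum()
    p = w / total
    # cumulative mass and mean below each interior edge j (bins [0, j))
    cum_w = np.cumsum(p)[:-1]
    cum_m = np.cumsum(p * d)[:-1]
    mean_all = float((p * d).sum())
    w0 = cum_w
    w1 = 1.0 - cum_w
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros_like(w0)
    mu0 = np.divide(cum_m, w0, out=np.zeros_like(cum_m), where=valid)
    mu1 = np.divide(mean_all - cum_m, w1, out=np.zeros_like(cum_m), where=valid)
    sigma_b[valid] = w0[valid] * w1[valid] * (mu0[valid] - mu1[valid]) ** 2
    # ties (e.g. the plateau across an empty gap) break toward the smallest
    # edge; the tolerance absorbs float round-off along the plateau
    best = sigma_b.max()
    j = int(np.nonzero(sigma_b >= best * (1.0 - 1e-12))[0][0])
    return ClassThreshold(
        diameter_mm=float(histogram.bin_edges[j + 1]),
        between_class_variance=float(sigma_b[j]),
    )


def _class_traits(d_mm: np.ndarray, l_cm: np.ndarray):
    length = float(l_cm.sum())
    volume = float(np.sum(math.pi * (d_mm / 20.0) ** 2 * l_cm))
    area = float(np.sum(math.pi * (d_mm / 10.0) * l_cm))
    mean_radius = float(np.sum((d_mm / 2.0) * l_cm) / length) if length > 0 else 0.0
    return length, volume, area, mean_radius


def cylinder_traits(
    histogram: DiameterLengthHistogram, threshold: ClassThreshold
) -> RootTraits:
    """Length, volume, surface area and mean radius per root class.

    Bin midpoints stand in for bin diameters; each bin is one cylinder of
    diameter d (mm) and length l (cm).  Empty classes yield zeros and an
    "empty class" flag.
    """
    d = histogram.midpoints_mm
    l = histogram.length_per_bin
    t = threshold.diameter_mm
    fib = d < t
    flags: list[str] = []
    fl, fv, fa, fr = _class_traits(d[fib], l[fib])
    sl, sv, sa, sr = _class_traits(d[~fib], l[~fib])
    if fl == 0:
        flags.append("empty fibrous class")
    if sl == 0:
        flags.append("empty storage class")
    return RootTraits(
        plant_id=histogram.plant_id,
        fibrous_length_cm=fl,
        storage_length_cm=sl,
        fibrous_volume_cm3=fv,
        storage_volume_cm3=sv,
        fibrous_area_cm2=fa,
        storage_area_cm2=sa,
        fibrous_mean_radius_mm=fr,
        storage_mean_radius_mm=sr,
        threshold_mm=t,
        flags=flags,
    )


def pool_experiments(tables: list) -> "pandas.DataFrame":  # noqa: F821
    """Concatenate per-experiment trait tables, keeping experiment ids."""
    import pandas as pd

    if not tables:
        raise ValueError("nothing to pool")
    cols = list(tables[0].columns)
    for i, t in enumerate(tables[1:], start=1):
        if list(t.columns) != cols:
            raise ValueError(f"table {i} has mismatched columns")
    return pd.concat(tables, ignore_index=True)


def coefficient_of_determination(x, y) -> ValidationReport:
    """r^2 of the least-squares line of y on x (with intercept)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: x has zero variance")
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    syy = np.sum((y - y.mean()) ** 2)
    if syy == 0:
        r2 = 1.0  # constant y is fitted exactly by the intercept-only line
    else:
        r2 = float(sxy**2 / (sxx * syy))
    return ValidationReport(r_squared=r2, n=n)
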