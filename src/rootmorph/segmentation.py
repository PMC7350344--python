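"""Pixel classification by Gaussian mixture posteriors, plus mask cleaning.

Inside the cropped tray the intensity histogram is a mixture of a bright
background (the board), dark roots, and intermediate dirt/shadow.  A
diagonal-covariance Gaussian mixture is fitted by EM on a pixel subsample;
every pixel is then assigned its posterior probability of belonging to the
root component(s), and the maximum-a-posteriori mask is cleaned (speck
removal, hole filling) and stripped of compact dirt blobs by a
component-shape criterion: roots are elongated, soil crumbs are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .imaging import BinaryMask, RasterImage

__all__ = [
    "MixtureModel",
    "PosteriorGrid",
    "ComponentStats",
    "sample_pixels",
    "fit_mixture",
    "posterior_map",
    "classify_root_pixels",
    "darkest_components",
    "select_root_components",
    "clean_mask",
    "remove_dirt",
]

VARIANCE_FLOOR = 1e-6


@dataclass
class MixtureModel:
    """A fitted diagonal Gaussian mixture with its EM trace.

    weights sum to 1; ``variances`` are floored at ``VARIANCE_FLOOR``; the
    per-iteration log-likelihood trace is non-decreasing (a property of EM
    that the test-suite asserts on every fit).
    """

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, D)
    variances: np.ndarray  # (K, D)
    feature_space: str = "gray"
    n_iter: int = 0
    log_likelihood: float = float("-inf")
    ll_trace: list[float] = field(default_factory=list)
    seed: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        if abs(self.weights.sum() - 1.0) > 1e-9 or (self.weights < 0).any():
            raise ValueError("mixture weights must be nonnegative and sum to 1")
        if (self.variances < VARIANCE_FLOOR - 1e-15).any():
            raise ValueError(f"variances below floor {VARIANCE_FLOOR}")

    @property
    def K(self) -> int:
        return self.weights.size

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def log_density(self, X: np.ndarray) -> np.ndarray:
        """Per-sample, per-component log of w_k * N(x; mu_k, sigma2_k)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        diff = X[:, None, :] - self.means[None, :, :]  # (n, K, D)
        log_norm = -0.5 * np.sum(
            np.log(2 * np.pi * self.variances), axis=1
        )  # (K,)
        quad = -0.5 * np.sum(diff**2 / self.variances[None, :, :], axis=2)
        with np.errstate(divide="ignore"):  # zero weights -> -inf, as intended
            log_w = np.log(self.weights)
        return log_w[None, :] + log_norm[None, :] + quad

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        lp = self.log_density(X)
        return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))


@dataclass
class PosteriorGrid:
    """Per-pixel component posteriors (H, W, K); rows sum to 1."""

    probs: np.ndarray
    dpi: float

    @property
    def K(self) -> int:
        return self.probs.shape[2]


@dataclass(frozen=True)
class ComponentStats:
    """Shape summary of one connected component (for the dirt audit trail)."""

    label: int
    area_px: int
    elongation: float  # major/minor axis ratio of the second-moment ellipse
    solidity: float
    skeleton_length_px: float
    skeleton_aspect: float  # skeleton_length^2 / area ~ length/width ratio
    removed: bool


def _features(image: RasterImage) -> np.ndarray:
    px = image.pixels
    if px.ndim == 2:
        return px.reshape(-1, 1)
    return px.reshape(-1, px.shape[2])


def sample_pixels(
    image: RasterImage, max_samples: int = 100_000, seed: int = 0
) -> np.ndarray:
    """Uniform subsample (without replacement) of pixel feature vectors."""
    if max_samples < 100:
        raise ValueError("max_samples must be at least 100")
    X = _features(image)
    n = X.shape[0]
    if n <= max_samples:
        return X.copy()
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=max_samples, replace=False)
    return X[idx]


def _kmeanspp_centers(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centers by squared-distance sampling."""
    n = X.shape[0]
    centers = np.empty((K, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:
            centers[k:] = centers[0]
            break
        probs = d2 / total
        centers[k] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((X - centers[k]) ** 2, axis=1))
    return centers


def fit_mixture(
    samples: np.ndarray,
    K: int = 3,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    feature_space: str = "gray",
) -> MixtureModel:
    """Fit a K-component diagonal Gaussian mixture by EM.

    Initialization is k-means++-style from ``seed``; iteration stops when
    the absolute log-likelihood gain drops below ``tol`` or after
    ``max_iter`` iterations.  Variances are floored each M-step.  Degenerate
    input (all samples identical with K > 1) yields a single dominant
    component with floored variances and ``degenerate=True`` instead of a
    crash.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and X.ndim == 2 and samples.ndim == 1:
        X = X.T
    n, d = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < 10 * K:
        raise ValueError(f"need at least {10 * K} samples for K={K}, got {n}")

    if K > 1 and np.all(np.ptp(X, axis=0) == 0):
        weights = np.zeros(K)
        weights[0] = 1.0
        means = np.tile(X[0], (K, 1))
        variances = np.full((K, d), VARIANCE_FLOOR)
        model = MixtureModel(
            weights, means, variances, feature_space=feature_space, seed=seed,
            degenerate=True,
        )
        model.log_likelihood = float(
            logsumexp(model.log_density(X), axis=1).sum()
        )
        model.ll_trace = [model.log_likelihood]
        return model

    rng = np.random.default_rng(seed)
    means = _kmeanspp_centers(X, K, rng)
    # hard assignment to the seeded centers gives the initial parameters
    d2 = np.sum((X[:, None, :] - means[None, :, :]) ** 2, axis=2)
    assign = np.argmin(d2, axis=1)
    weights = np.empty(K)
    variances = np.empty((K, d))
    global_var = np.maximum(X.var(axis=0), VARIANCE_FLOOR)
    for k in range(K):
        members = X[assign == k]
        weights[k] = max(members.shape[0], 1) / n
        if members.shape[0] >= 2:
            means[k] = members.mean(axis=0)
            variances[k] = np.maximum(members.var(axis=0), VARIANCE_FLOOR)
        else:
            variances[k] = global_var
    weights /= weights.sum()

    model = MixtureModel(
        weights, means, np.maximum(variances, VARIANCE_FLOOR),
        feature_space=feature_space, seed=seed,
    )
    ll_trace: list[float] = []
    prev_ll = -np.inf
    for it in range(max_iter):
        lp = model.log_density(X)  # E-step
        norm = logsumexp(lp, axis=1, keepdims=True)
        ll = float(norm.sum())
        ll_trace.append(ll)
        resp = np.exp(lp - norm)
        if ll - prev_ll < tol and it > 0:
            prev_ll = ll
            break
        prev_ll = ll
        # M-step
        nk = resp.sum(axis=0)
        nk_safe = np.maximum(nk, 1e-12)
        model.weights = nk / nk.sum()
        model.means = (resp.T @ X) / nk_safe[:, None]
        diff2 = (X[:, None, :] - model.means[None, :, :]) ** 2
        var = np.einsum("nk,nkd->kd", resp, diff2) / nk_safe[:, None]
        model.variances = np.maximum(var, VARIANCE_FLOOR)
    model.n_iter = len(ll_trace)
    model.log_likelihood = prev_ll
    model.ll_trace = ll_trace
    return model


def posterior_map(image: RasterImage, model: MixtureModel) -> PosteriorGrid:
    """Evaluate p(k | x) for every pixel; rows sum to 1 within 1e-9."""
    X = _features(image)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} feature(s), image has {X.shape[1]}"
        )
    probs = model.posteriors(X)
    h, w = image.pixels.shape[:2]
    return PosteriorGrid(probs.reshape(h, w, model.K), dpi=image.dpi)


def darkest_components(model: MixtureModel, n: int = 1) -> set[int]:
    """Indices of the n components with the lowest mean luminance."""
    luminance = model.means.mean(axis=1)
    return set(int(i) for i in np.argsort(luminance)[:n])


def select_root_components(
    model: MixtureModel, n: int = 1, min_separation: float = 6.0
) -> set[int]:
    """Darkest component(s), kept only when clearly darker than the board.

    A candidate root component must lie at least ``min_separation``
    board-component standard deviations below the brightest (board)
    component.  On a tray with no roots at all the mixture merely
    partitions sensor noise and no component is that far below the board,
    so the returned set is empty — an empty root system is a legitimate
    outcome, not an error.  The board's own sd is the yardstick because it
    is pinned by the vast background mass, whereas a root component that
    also absorbs dirt or shadow can have an arbitrarily wide variance.
    """
    luminance = model.means.mean(axis=1)
    brightest = int(np.argmax(luminance))
    board_sd = float(np.sqrt(model.variances[brightest].mean()))
    out = set()
    for k in darkest_components(model, n):
        if luminance[brightest] - luminance[k] >= min_separation * board_sd:
            out.add(k)
    return out


def classify_root_pixels(
    posterior: PosteriorGrid,
    root_components: set[int],
    min_posterior: float = 0.5,
) -> BinaryMask:
    """Threshold the summed root-component posterior into a binary mask.

    A pixel is root iff its summed posterior over ``root_components`` is
    >= ``min_posterior`` (ties at the threshold are included).
    """
    if not root_components:
        raise ValueError("root_components must be nonempty")
    bad = [k for k in root_components if not (0 <= k < posterior.K)]
    if bad:
        raise ValueError(f"unknown component indices {bad} (K={posterior.K})")
    p_root = posterior.probs[:, :, sorted(root_components)].sum(axis=2)
    return BinaryMask(p_root >= min_posterior, dpi=posterior.dpi)


def clean_mask(
    mask: BinaryMask, min_speck_px: int = 25, fill_hole_px: int = 100
) -> BinaryMask:
    """Drop 8-connected specks with area < ``min_speck_px`` and fill enclosed
    background holes with area < ``fill_hole_px``.

    Holes matter because rot can hollow a root to its rhizodermis and
    central cylinder, leaving enclosed background inside the root outline.
    """
    if min_speck_px < 0 or fill_hole_px < 0:
        raise ValueError("cleaning parameters must be >= 0")
    from skimage.measure import label

    px = mask.pixels.copy()
    if min_speck_px > 0 and px.any():
        labels = label(px, connectivity=2)
        areas = np.bincount(labels.ravel())
        kill = np.nonzero(areas < min_speck_px)[0]
        kill = kill[kill != 0]
        if kill.size:
            px[np.isin(labels, kill)] = False
    if fill_hole_px > 0 and not px.all():
        bg = label(~px, connectivity=1)
        areas = np.bincount(bg.ravel())
        border = np.unique(
            np.concatenate([bg[0, :], bg[-1, :], bg[:, 0], bg[:, -1]])
        )
        fill = np.array(
            [
                lbl
                for lbl in range(1, areas.size)
                if areas[lbl] < fill_hole_px and lbl not in border
            ],
            dtype=int,
        )
        if fill.size:
            px[np.isin(bg, fill)] = True
    return BinaryMask(px, dpi=mask.dpi)


def remove_dirt(
    mask: BinaryMask,
    min_elongation: float = 3.0,
    max_area_px: int = 50_000,
    max_solidity: float = 0.5,
    min_solidity_area_px: int = 200,
) -> tuple[BinaryMask, list[ComponentStats]]:
    """Remove compact components (dirt); keep elongated ones (roots).

    A component is kept iff it is elongated — its second-moment-ellipse
    axis ratio OR its skeleton aspect (skeleton length squared over area,
    i.e. a curvature-invariant length-to-width ratio) reaches
    ``min_elongation`` — OR its solidity is below ``max_solidity`` (at
    area >= ``min_solidity_area_px``) OR its area exceeds ``max_area_px``
    (large root mats are kept regardless of shape).  The ellipse ratio
    alone misses strongly curved roots, whose second-moment ellipse is
    nearly round; the skeleton aspect is unaffected by bending, while a
    soil crumb's skeleton collapses to a short ridge.  Stats for every
    component are returned for the audit CSV.
    """
    if min_elongation < 1:
        raise ValueError("min_elongation must be >= 1")
    from skimage.measure import label, regionprops
    from skimage.morphology import skeletonize

    from .measure import SQRT2, _link_counts

    labels = label(mask.pixels, connectivity=2)
    skel = skeletonize(mask.pixels, method="lee").astype(bool)
    orth, diag, _ = _link_counts(skel)
    chain = orth + SQRT2 * diag
    out = mask.pixels.copy()
    stats: list[ComponentStats] = []
    for region in regionprops(labels):
        minor = region.axis_minor_length
        major = region.axis_major_length
        if minor > 1e-9:
            elong = major / minor
        else:
            # a 1-px-wide line has a degenerate minor axis: maximally elongated
            elong = float("inf") if major > 1e-9 else 1.0
        rmin, cmin, rmax, cmax = region.bbox
        in_region = labels[rmin:rmax, cmin:cmax] == region.label
        skel_len = float(chain[rmin:rmax, cmin:cmax][in_region & skel[rmin:rmax, cmin:cmax]].sum())
        skel_aspect = skel_len**2 / region.area
        keep = (
            elong >= min_elongation
            or skel_aspect >= min_elongation
            or (region.solidity < max_solidity and region.area >= min_solidity_area_px)
            or region.area > max_area_px
        )
        stats.append(
            ComponentStats(
                label=int(region.label),
                area_px=int(region.area),
                elongation=float(elong),
                solidity=float(region.solidity),
                skeleton_length_px=skel_len,
                skeleton_aspect=float(skel_aspect),
                removed=not keep,
            )
        )
        if not keep:
            out[labels == region.label] = False
    return BinaryMask(out, dpi=mask.dpi), stats
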