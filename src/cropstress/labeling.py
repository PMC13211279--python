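"""Rule-based ground-truth mask generation from vegetation indices.

Water-stress scenes use a stepwise decision chain: an Otsu threshold on
SAVI separates soil from vegetation, a second Otsu threshold on NDRE
splits vegetation into healthy and stressed candidates, and a 2-cluster
k-means in the standardized (NDVI, GCI) feature space splits stressed
candidates into low and high stress (the cluster with the higher mean
NDVI is the lower-stress one).

Rust scenes first split soil from plants with a 1-D 2-means threshold on
SAVI, then run a voting scheme on plant pixels: one vote each for NDRE,
NDVI and SR falling below the plant-region median of that index; two or
more votes flag rust.  The rust support is then cleaned morphologically.

Masks from the two tasks are harmonized into the shared five-class space
(soil, low stress, high stress, healthy, rust).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from sklearn.cluster import KMeans

from cropstress.indices import IndexStack
from cropstress.masks import LabelMask, WATER4, RUST3, MIX5, IGNORE_LABEL


class DegenerateInputError(ValueError):
    """Raised when a threshold is requested on constant (or empty) data."""


@dataclass
class LabelingParams:
    otsu_bins: int = 256
    kmeans_seed: int = 0
    min_component_px: int = 16
    morph_se: int = 1

    def __post_init__(self) -> None:
        if self.otsu_bins < 2:
            raise ValueError("otsu_bins must be >= 2")
        if self.min_component_px < 0:
            raise ValueError("min_component_px must be >= 0")


# healthy-vegetation class id per label space (clean_mask reverts removed
# pixels to this class)
_HEALTHY_ID = {WATER4: 3, RUST3: 2, MIX5: 3}


def otsu_threshold(values: np.ndarray, bins: int = 256) -> float:
    """Between-class-variance-maximizing threshold over a binned histogram.

    Returns the bin *edge* at the maximizing cut, so ``value < threshold``
    reproduces exactly the class-0 bin set.  (Implementations that return
    a bin center can flip the comparison for values inside that bin, which
    matters on quasi-discrete index distributions.)
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    values = values[np.isfinite(values)]
    if values.size < 2 or np.all(values == values[0]):
        raise DegenerateInputError("Otsu threshold needs >= 2 distinct finite values")
    hist, edges = np.histogram(values, bins=bins)
    p = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    cum_mean = np.cumsum(p * centers)[:-1]
    total_mean = (p * centers).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = cum_mean / w0
        m1 = (total_mean - cum_mean) / w1
        bcv = w0 * w1 * (m0 - m1) ** 2
    bcv[~np.isfinite(bcv)] = -np.inf
    return float(edges[int(np.argmax(bcv)) + 1])


def kmeans_split_1d(values: np.ndarray, seed: int = 0) -> tuple[float, float, float]:
    """1-D two-cluster k-means; returns (center_low, center_high, threshold).

    The threshold is the midpoint of the sorted centers, i.e. the boundary
    of the smaller "soil-like" cluster.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    values = values[np.isfinite(values)]
    if values.size < 2 or np.all(values == values[0]):
        raise DegenerateInputError("1-D 2-means needs >= 2 distinct values")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    km.fit(values.reshape(-1, 1))
    lo, hi = np.sort(km.cluster_centers_.ravel())
    return float(lo), float(hi), float((lo + hi) / 2.0)


def water_stress_mask(stack: IndexStack, params: LabelingParams | None = None) -> LabelMask:
    """Water-stress decision chain -> water4 mask {0 soil, 1 low, 2 high, 3 healthy}."""
    params = params or LabelingParams()
    valid = stack.valid_mask
    labels = np.full(stack.shape, IGNORE_LABEL, dtype=np.uint8)
    labels[valid] = 0

    savi = stack.savi
    try:
        t_savi = otsu_threshold(savi[valid], params.otsu_bins)
    except DegenerateInputError:
        warnings.warn("degenerate SAVI distribution: returning all-soil mask")
        return LabelMask(labels, WATER4, valid_mask=valid)
    veg = valid & (savi >= t_savi)
    if not veg.any():
        warnings.warn("no vegetation pixels: returning all-soil mask")
        return LabelMask(labels, WATER4, valid_mask=valid)
    labels[veg] = 3

    try:
        t_ndre = otsu_threshold(stack.ndre[veg], params.otsu_bins)
    except DegenerateInputError:
        return LabelMask(labels, WATER4, valid_mask=valid)
    stressed = veg & (stack.ndre < t_ndre)
    n_stressed = int(stressed.sum())
    if n_stressed >= 2:
        feats = np.column_stack([stack.ndvi[stressed], stack.gci[stressed]])
        mu = feats.mean(axis=0)
        sd = feats.std(axis=0)
        sd[sd == 0] = 1.0
        km = KMeans(n_clusters=2, n_init=10, random_state=params.kmeans_seed)
        assign = km.fit_predict((feats - mu) / sd)
        ndvi_means = [stack.ndvi[stressed][assign == c].mean() if (assign == c).any() else -np.inf
                      for c in (0, 1)]
        low_cluster = int(np.argmax(ndvi_means))  # higher mean NDVI -> lower stress
        sub = np.where(assign == low_cluster, 1, 2).astype(np.uint8)
        labels[stressed] = sub
    return LabelMask(labels, WATER4, valid_mask=valid)


def rust_mask(stack: IndexStack, params: LabelingParams | None = None) -> LabelMask:
    """Rust voting scheme -> rust3 mask {0 soil, 1 rust, 2 healthy}."""
    params = params or LabelingParams()
    valid = stack.valid_mask
    labels = np.full(stack.shape, IGNORE_LABEL, dtype=np.uint8)
    labels[valid] = 0

    try:
        _, _, t_savi = kmeans_split_1d(stack.savi[valid], params.kmeans_seed)
    except DegenerateInputError:
        warnings.warn("degenerate SAVI distribution: returning all-soil mask")
        return LabelMask(labels, RUST3, valid_mask=valid)
    plant = valid & (stack.savi >= t_savi)
    if not plant.any():
        warnings.warn("no plant pixels: returning all-soil mask")
        return LabelMask(labels, RUST3, valid_mask=valid)

    votes = rust_votes(stack, plant)
    labels[plant] = np.where(votes[plant] >= 2, 1, 2).astype(np.uint8)
    mask = LabelMask(labels, RUST3, valid_mask=valid)
    return clean_mask(mask, target_class=1, params=params)


def rust_votes(stack: IndexStack, plant: np.ndarray) -> np.ndarray:
    """Per-pixel rust vote count: one vote per index below its plant-region median."""
    votes = np.zeros(stack.shape, dtype=np.int8)
    for arr in (stack.ndre, stack.ndvi, stack.sr):
        med = np.median(arr[plant])
        votes += (plant & (arr < med)).astype(np.int8)
    return votes


def clean_mask(mask: LabelMask, target_class: int, params: LabelingParams | None = None) -> LabelMask:
    """Morphological cleanup of one class: opening, then small-object removal.

    Pixels removed from the target class revert to the healthy class of the
    mask's label space.
    """
    params = params or LabelingParams()
    if target_class not in np.arange(256):
        raise ValueError("bad target class")
    healthy = _HEALTHY_ID[mask.space]
    support = mask.labels == target_class
    cleaned = support
    if params.morph_se > 0:
        cleaned = ndimage.binary_opening(cleaned, structure=disk(params.morph_se))
    if params.min_component_px > 0:
        labeled, n = ndimage.label(cleaned, structure=np.ones((3, 3), dtype=bool))
        if n:
            sizes = np.bincount(labeled.ravel())
            keep = sizes >= params.min_component_px
            keep[0] = False
            cleaned = keep[labeled]
    out = mask.labels.copy()
    out[support & ~cleaned] = healthy
    out[cleaned] = target_class
    return LabelMask(out, mask.space, valid_mask=mask.valid_mask)


#: rust3 -> mix5 class id mapping: soil stays, healthy joins the common
#: healthy class, rust becomes the fifth class.
RUST3_TO_MIX5 = {0: 0, 1: 4, 2: 3}


def harmonize(mask: LabelMask) -> LabelMask:
    """Map a native-space mask into the five-class mix space."""
    if mask.space == WATER4:
        return LabelMask(mask.labels.copy(), MIX5, valid_mask=mask.valid_mask)
    if mask.space == RUST3:
        lut = np.full(256, IGNORE_LABEL, dtype=np.uint8)
        for src, dst in RUST3_TO_MIX5.items():
            lut[src] = dst
        lut[IGNORE_LABEL] = IGNORE_LABEL
        return LabelMask(lut[mask.labels], MIX5, valid_mask=mask.valid_mask)
    raise ValueError(f"cannot harmonize mask already in space {mask.space!r}")


def densecrf_refine(mask: LabelMask, scene=None) -> LabelMask:
    """Plug-in point for optional CRF-based refinement; currently a no-op."""
    return mask
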