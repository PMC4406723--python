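"""Semi-automatic segmentation primitives.

Smoothing, histogram thresholding, region growing, k-means intensity
clustering, morphological cleanup and inter-slice interpolation — the
building blocks used to derive tissue masks from rendered contrasts.
Foreground connectivity is 6-connected everywhere.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball
from skimage.segmentation import watershed as _sk_watershed

from .grids import LabelVolume, ScalarImage

__all__ = [
    "gaussian_smooth",
    "threshold_histogram",
    "region_grow",
    "kmeans_labels",
    "morph_cleanup",
    "interslice_interpolate",
    "watershed_experimental",
    "FWHM_TO_SIGMA",
]

# FWHM = 2 sqrt(2 ln 2) * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def gaussian_smooth(
    img: ScalarImage, fwhm_mm, kernel_convention: str = "fwhm"
) -> ScalarImage:
    """Separable Gaussian smoothing with kernel width given in mm.

    ``kernel_convention`` selects whether the width denotes the FWHM
    (default) or the standard deviation of the kernel.
    """
    fwhm = np.asarray(fwhm_mm, dtype=float).reshape(-1)
    if fwhm.size == 1:
        fwhm = np.repeat(fwhm, 3)
    if np.any(fwhm < 0):
        raise ValueError("kernel width must be >= 0")
    if kernel_convention == "fwhm":
        sigma_mm = fwhm * FWHM_TO_SIGMA
    elif kernel_convention == "sigma":
        sigma_mm = fwhm
    else:
        raise ValueError("kernel_convention must be 'fwhm' or 'sigma'")
    sigma_vox = sigma_mm / img.spacing
    # truncate at 6 sigma so the discrete kernel matches the analytic
    # Gaussian to ~1e-8 relative
    out = ndimage.gaussian_filter(img.values, sigma=sigma_vox, mode="nearest",
                                  truncate=6.0)
    return ScalarImage(out, img.spacing.copy(), img.origin.copy())


def threshold_histogram(img: ScalarImage, method: str = "otsu", manual: float | None = None):
    """Binary mask of voxels >= threshold.

    ``method='otsu'`` picks the between-class-variance-maximising
    threshold; ``method='manual'`` uses the supplied value.
    """
    v = img.values
    if method == "manual":
        if manual is None:
            raise ValueError("manual method requires a threshold value")
        return v >= manual
    if method == "otsu":
        if np.all(v == v.flat[0]):
            raise ValueError("cannot auto-threshold a constant image")
        t = threshold_otsu(v)
        return v >= t
    raise ValueError(f"unknown method {method!r}")


def region_grow(img: ScalarImage, seeds, low: float, high: float) -> np.ndarray:
    """6-connected flood fill of voxels with intensity in [low, high]
    reachable from the seed points (voxel index triples)."""
    if low > high:
        raise ValueError("low must be <= high")
    shape = img.shape
    band = (img.values >= low) & (img.values <= high)
    comps, _ = ndimage.label(band, structure=STRUCT_6)
    out = np.zeros(shape, dtype=bool)
    for s in seeds:
        s = tuple(int(i) for i in s)
        if any(i < 0 or i >= n for i, n in zip(s, shape)):
            raise ValueError(f"seed {s} outside grid {shape}")
        cid = comps[s]
        if cid > 0:  # seed outside the band grows nothing (not an error)
            out |= comps == cid
    return out


def kmeans_labels(img: ScalarImage, k: int, seed: int = 0, max_iter: int = 300) -> LabelVolume:
    """Lloyd's algorithm on voxel intensities.

    Output labels are 1..k ordered by ascending cluster mean, so the
    labelling is deterministic up to the seeded initialisation.  Runs on
    the image's unique values weighted by their counts, which makes the
    iteration exact and fast for quantised images.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    vals, counts = np.unique(img.values, return_counts=True)
    if vals.size < k:
        raise ValueError(f"image has {vals.size} distinct values < k={k}")
    rng = np.random.default_rng(seed)
    # k-means++-style spread init on the quantile range, seeded
    qs = np.sort(rng.uniform(0, 1, size=k))
    centers = np.quantile(np.repeat(vals, counts), qs)
    centers = np.unique(centers)
    while centers.size < k:  # degenerate draw: pad with distinct values
        extra = vals[rng.integers(vals.size)]
        centers = np.unique(np.append(centers, extra))
    assign = None
    for _ in range(max_iter):
        dist = np.abs(vals[:, None] - centers[None, :])
        new_assign = np.argmin(dist, axis=1)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            sel = assign == j
            if np.any(sel):
                centers[j] = np.average(vals[sel], weights=counts[sel])
    order = np.argsort(centers)
    rank = np.empty(k, dtype=np.int32)
    rank[order] = np.arange(1, k + 1)
    lut_labels = rank[assign]
    idx = np.searchsorted(vals, img.values)
    return LabelVolume(lut_labels[idx].astype(np.int32), img.spacing.copy(), img.origin.copy())


def _remove_islands(mask: np.ndarray, min_size: int) -> np.ndarray:
    comps, n = ndimage.label(mask, structure=STRUCT_6)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(comps.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[comps]


def _fill_holes(mask: np.ndarray) -> np.ndarray:
    # background components not touching the volume border are holes
    bg = ~mask
    comps, n = ndimage.label(bg, structure=STRUCT_6)
    border_ids = set()
    for ax in range(3):
        for sl in (0, -1):
            face = np.take(comps, sl, axis=ax)
            border_ids.update(np.unique(face).tolist())
    border_ids.discard(0)
    out = mask.copy()
    for cid in range(1, n + 1):
        if cid not in border_ids:
            out |= comps == cid
    return out


def morph_cleanup(
    mask: np.ndarray,
    operation: str,
    radius_vox: int = 1,
    min_island_size: int = 1,
) -> np.ndarray:
    """Morphological cleanup: ``open``/``close`` with a ball structuring
    element, ``remove_islands`` (6-connected components below
    ``min_island_size`` deleted), ``fill_holes`` (enclosed background
    filled)."""
    mask = np.asarray(mask, dtype=bool)
    if radius_vox < 0:
        raise ValueError("radius must be >= 0")
    if operation == "open":
        if radius_vox == 0:
            return mask.copy()
        return ndimage.binary_opening(mask, structure=ball(radius_vox))
    if operation == "close":
        if radius_vox == 0:
            return mask.copy()
        return ndimage.binary_closing(mask, structure=ball(radius_vox))
    if operation == "remove_islands":
        return _remove_islands(mask, min_island_size)
    if operation == "fill_holes":
        return _fill_holes(mask)
    raise ValueError(f"unknown operation {operation!r}")


def _signed_distance(mask2d: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance: negative inside the mask, positive outside."""
    inside = ndimage.distance_transform_edt(mask2d)
    outside = ndimage.distance_transform_edt(~mask2d)
    return outside - inside


def interslice_interpolate(
    mask_first: np.ndarray, mask_last: np.ndarray, n_between: int
) -> list[np.ndarray]:
    """Topology-flexible interpolation between two 2-D masks.

    Blends the signed Euclidean distance transforms of the endpoint
    masks linearly and thresholds at zero for each intermediate slice.
    Endpoints are returned verbatim.
    """
    a = np.asarray(mask_first, dtype=bool)
    b = np.asarray(mask_last, dtype=bool)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("endpoint masks must be 2-D and congruent")
    if not a.any() or not b.any():
        raise ValueError("endpoint masks must be nonempty")
    if n_between < 0:
        raise ValueError("n_between must be >= 0")
    da = _signed_distance(a)
    db = _signed_distance(b)
    out = [a.copy()]
    for i in range(1, n_between + 1):
        t = i / (n_between + 1)
        out.append(((1.0 - t) * da + t * db) <= 0.0)
    out.append(b.copy())
    return out


def watershed_experimental(img: ScalarImage, markers: np.ndarray) -> LabelVolume:
    """Marker-based watershed on the gradient magnitude.  Experimental:
    no published parameters back this primitive; use for exploration."""
    grad = ndimage.gaussian_gradient_magnitude(img.values, sigma=1.0)
    labels = _sk_watershed(grad, markers=np.asarray(markers, dtype=np.int32))
    return LabelVolume(labels.astype(np.int32), img.spacing.copy(), img.origin.copy())
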