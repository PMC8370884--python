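"""Segmentation, Dice scoring, error overlays and line profiles.

Two segmentation protocols are provided for real-valued reconstructions:

* clip-at-zero + mean threshold (used for the benchmark tables): negatives
  are clipped to 0 and pixels strictly above the mean of the clipped image
  are foreground;
* two-class k-means on pixel intensities (used for the visual false-positive
  / false-negative overlays), with deterministic min/max centroid
  initialization.

Binary-solver outputs are already segmentations: their Dice is computed on
the upper-level set directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import ImageGrid, PressureImage

__all__ = [
    "BinaryMask",
    "MetricsReport",
    "as_mask",
    "dice",
    "segment_threshold_mean",
    "segment_kmeans2",
    "error_overlay",
    "compare_masks",
    "render_overlay",
    "line_profile",
]

#: overlay colours (RGB): false positives green, false negatives pink
FP_COLOR = (0, 200, 0)
FN_COLOR = (255, 105, 180)
TP_COLOR = (255, 255, 255)


@dataclass
class BinaryMask:
    """A {0,1} field, optionally attached to an :class:`ImageGrid`."""

    values: np.ndarray
    grid: ImageGrid | None = None
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if not np.isin(np.unique(vals), (0, 1)).all():
            raise ValueError("mask must contain only values {0, 1}")
        self.values = vals.astype(np.uint8)

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())


@dataclass
class MetricsReport:
    """Dice score and error maps of one reconstruction against the truth."""

    dice: float
    n_true: int
    n_recon: int
    n_intersect: int
    fp_map: np.ndarray
    fn_map: np.ndarray
    method: str = ""

    def summary(self) -> str:
        return (
            f"method={self.method or '?'} dice={self.dice:.4f} "
            f"|true|={self.n_true} |recon|={self.n_recon} "
            f"|FP|={int(self.fp_map.sum())} |FN|={int(self.fn_map.sum())}"
        )


def as_mask(obj, provenance: str = "unknown") -> BinaryMask:
    """Coerce a mask, a two-level image or a raw array into a BinaryMask.

    Two-level :class:`PressureImage` inputs map their upper level to 1.
    """
    if isinstance(obj, BinaryMask):
        return obj
    if isinstance(obj, PressureImage):
        grid, arr = obj.grid, obj.values
    else:
        grid, arr = None, np.asarray(obj)
    uniq = np.unique(arr)
    if len(uniq) > 2:
        raise ValueError("input is not two-valued; segment it first")
    # two levels: upper level is foreground; one level: nonzero means foreground
    fg = arr > uniq.min() if len(uniq) == 2 else arr != 0
    return BinaryMask(values=fg, grid=grid, provenance=provenance)


def _check_same_shape(a: BinaryMask, b: BinaryMask) -> None:
    if a.values.shape != b.values.shape:
        raise ValueError(f"mask shapes differ: {a.values.shape} vs {b.values.shape}")
    if a.grid is not None and b.grid is not None and a.grid != b.grid:
        raise ValueError("masks live on different grids")


def dice(mask_true, mask_recon) -> float:
    """Dice similarity coefficient ``2|X & Y| / (|X| + |Y|)``.

    Symmetric, in [0, 1]; raises when both masks are empty (0/0).
    """
    mt = as_mask(mask_true)
    mr = as_mask(mask_recon)
    _check_same_shape(mt, mr)
    n_true = mt.n_foreground
    n_recon = mr.n_foreground
    if n_true + n_recon == 0:
        raise ValueError("Dice undefined: both masks are empty")
    inter = int((mt.values & mr.values).sum())
    return 2.0 * inter / (n_true + n_recon)


def segment_threshold_mean(image) -> BinaryMask:
    """Clip negatives to zero, then threshold strictly above the image mean.

    The mean is taken over all pixels of the clipped image. A constant image
    yields an empty foreground with a warning.
    """
    if isinstance(image, PressureImage):
        grid, arr = image.grid, image.values
    else:
        grid, arr = None, np.asarray(image, dtype=float)
    clipped = np.maximum(arr, 0.0)
    thr = float(clipped.mean())
    fg = clipped > thr
    if not fg.any():
        warnings.warn(
            "mean-threshold segmentation produced an empty foreground "
            "(constant or non-positive image)",
            UserWarning,
            stacklevel=2,
        )
    return BinaryMask(values=fg, grid=grid, provenance="threshold_mean")


def segment_kmeans2(image, seed: int = 0, max_iter: int = 100) -> BinaryMask:
    """Two-class 1-D k-means on pixel intensities; foreground = upper class.

    Centroids are initialized deterministically at the min and max intensity,
    so the result is independent of ``seed`` (kept for interface stability).
    """
    from sklearn.cluster import KMeans

    if isinstance(image, PressureImage):
        grid, arr = image.grid, image.values
    else:
        grid, arr = None, np.asarray(image, dtype=float)
    flat = arr.reshape(-1, 1)
    lo, hi = float(flat.min()), float(flat.max())
    if lo == hi:
        raise ValueError("k-means segmentation needs >= 2 distinct intensities")
    km = KMeans(
        n_clusters=2,
        init=np.array([[lo], [hi]]),
        n_init=1,
        max_iter=max_iter,
        random_state=seed,
    )
    labels = km.fit_predict(flat)
    upper = int(np.argmax(km.cluster_centers_.ravel()))
    fg = (labels == upper).reshape(arr.shape)
    return BinaryMask(values=fg, grid=grid, provenance="kmeans2")


def error_overlay(mask_true, mask_recon) -> tuple[np.ndarray, np.ndarray]:
    """False-positive and false-negative maps: ``fp = recon \\ true``, ``fn = true \\ recon``."""
    mt = as_mask(mask_true)
    mr = as_mask(mask_recon)
    _check_same_shape(mt, mr)
    fp = (mr.values.astype(bool) & ~mt.values.astype(bool)).astype(np.uint8)
    fn = (mt.values.astype(bool) & ~mr.values.astype(bool)).astype(np.uint8)
    return fp, fn


def compare_masks(mask_true, mask_recon, method: str = "") -> MetricsReport:
    """Full metrics: Dice, cardinalities and FP/FN maps."""
    mt = as_mask(mask_true)
    mr = as_mask(mask_recon)
    fp, fn = error_overlay(mt, mr)
    inter = int((mt.values & mr.values).sum())
    return MetricsReport(
        dice=dice(mt, mr),
        n_true=mt.n_foreground,
        n_recon=mr.n_foreground,
        n_intersect=inter,
        fp_map=fp,
        fn_map=fn,
        method=method,
    )


def render_overlay(mask_true, mask_recon) -> np.ndarray:
    """RGB overlay image: green = FP, pink = FN, white = TP, black = TN."""
    mt = as_mask(mask_true)
    mr = as_mask(mask_recon)
    fp, fn = error_overlay(mt, mr)
    tp = mt.values & mr.values
    rgb = np.zeros(mt.values.shape + (3,), dtype=np.uint8)
    rgb[tp.astype(bool)] = TP_COLOR
    rgb[fp.astype(bool)] = FP_COLOR
    rgb[fn.astype(bool)] = FN_COLOR
    return rgb


def line_profile(
    image: PressureImage,
    p_start: tuple[float, float],
    p_end: tuple[float, float],
    n_points: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear samples along a segment given in physical mm coordinates.

    Returns ``(distances_mm, values)`` where distances run from 0 at
    ``p_start``. Endpoints must lie inside the field of view.
    """
    grid = image.grid
    half_w, half_h = grid.extent[0] / 2, grid.extent[1] / 2
    for p in (p_start, p_end):
        if abs(p[0]) > half_w or abs(p[1]) > half_h:
            raise ValueError(f"profile endpoint {p} lies outside the FOV")
    t = np.linspace(0.0, 1.0, n_points)
    xs = p_start[0] + t * (p_end[0] - p_start[0])
    ys = p_start[1] + t * (p_end[1] - p_start[1])
    # physical mm -> fractional pixel indices
    ox, oy = grid.origin
    cols = (xs - ox) / grid.dx
    rows = (ys - oy) / grid.dx
    values = ndimage.map_coordinates(
        image.values, np.vstack([rows, cols]), order=1, mode="nearest"
    )
    dist = np.hypot(xs - p_start[0], ys - p_start[1])
    return dist, values
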