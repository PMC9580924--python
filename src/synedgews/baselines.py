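"""Baseline segmenters sharing the preprocessing and size-gate environment
of the edge/watershed segmenter:

* ``segment_thr``    — global Otsu threshold, connected components.
* ``segment_thr_ws`` — Otsu threshold followed by marker-controlled
  watershed splitting of connected sections.
* ``segment_locmax`` — local intensity maxima gated by the global Otsu
  threshold; each ROI is the half-maximum level set around its maximum.

All three apply the same inclusive pixel-area gate as the main segmenter.
"""

from __future__ import annotations

from typing import List

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.morphology import local_maxima

from .config import AcquisitionConfig
from .segment import (
    ROI,
    SegmentationResult,
    _CROSS,
    _make_roi,
    compute_size_range,
    split_watershed,
)

__all__ = ["segment_thr", "segment_thr_ws", "segment_locmax", "SEGMENTERS"]


def _empty_result(shape) -> SegmentationResult:
    return SegmentationResult(label_map=np.zeros(shape, dtype=np.int32))


def _result_from_masks(masks: List[np.ndarray], image: np.ndarray) -> SegmentationResult:
    label_map = np.zeros(image.shape, dtype=np.int32)
    rois = []
    for lab, mask in enumerate(masks, start=1):
        label_map[mask] = lab
        rows, cols = np.nonzero(mask)
        rois.append(_make_roi(lab, rows, cols, image, iteration=0))
    return SegmentationResult(label_map=label_map, rois=rois,
                              iteration_of={r.label: 0 for r in rois})


def _size_filtered(label_map: np.ndarray, image: np.ndarray,
                   cfg: AcquisitionConfig) -> SegmentationResult:
    min_px, max_px = compute_size_range(cfg)
    masks = []
    for lab in np.unique(label_map):
        if lab == 0:
            continue
        mask = label_map == lab
        if min_px <= mask.sum() <= max_px:
            masks.append(mask)
    return _result_from_masks(masks, image)


def segment_thr(image: np.ndarray, cfg: AcquisitionConfig) -> SegmentationResult:
    """Global automatic (Otsu) threshold -> connected components -> size gate."""
    arr = np.asarray(image, dtype=float)
    if arr.max() <= arr.min():
        return _empty_result(arr.shape)
    t = threshold_otsu(arr)
    binary = arr > t
    labels, _ = ndimage.label(binary, structure=_CROSS)
    return _size_filtered(labels, arr, cfg)


def segment_thr_ws(image: np.ndarray, cfg: AcquisitionConfig) -> SegmentationResult:
    """Otsu threshold plus watershed splitting of connected sections."""
    arr = np.asarray(image, dtype=float)
    if arr.max() <= arr.min():
        return _empty_result(arr.shape)
    t = threshold_otsu(arr)
    binary = arr > t
    labels = split_watershed(binary, arr)
    return _size_filtered(labels, arr, cfg)


def segment_locmax(image: np.ndarray, cfg: AcquisitionConfig) -> SegmentationResult:
    """Local maxima gated by the global threshold; half-maximum support ROIs.

    Plateau maxima collapse to a single marker.  Maxima closer than the
    expected minimum punctum diameter are suppressed in order of descending
    intensity (ties by row, then column).  Each ROI consists of pixels whose
    nearest kept maximum is this one and whose intensity exceeds 50% of that
    maximum, restricted to the connected component containing the maximum.
    """
    arr = np.asarray(image, dtype=float)
    if arr.max() <= arr.min():
        return _empty_result(arr.shape)
    t = threshold_otsu(arr)

    # one representative pixel per maximum plateau
    plateaus, n_plat = ndimage.label(local_maxima(arr, connectivity=1), structure=_CROSS)
    reps = []
    for sl_idx, sl in enumerate(ndimage.find_objects(plateaus), start=1):
        if sl is None:
            continue
        rows, cols = np.nonzero(plateaus[sl] == sl_idx)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        cr, cc = rows.mean(), cols.mean()
        k = int(np.argmin((rows - cr) ** 2 + (cols - cc) ** 2))
        reps.append((rows[k], cols[k]))
    reps = [p for p in reps if arr[p] > t]
    if not reps:
        return _empty_result(arr.shape)

    # greedy min-distance suppression
    s = cfg.pixel_size_um
    min_sep = max(1.0, cfg.min_diameter_um / s)
    reps.sort(key=lambda p: (-arr[p], p[0], p[1]))
    kept: List[tuple] = []
    for p in reps:
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep ** 2 for q in kept):
            kept.append(p)

    pts = np.array(kept, dtype=float)
    tree = cKDTree(pts)
    rr, cc = np.indices(arr.shape)
    _, nearest = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    nearest = nearest.reshape(arr.shape)

    masks = []
    for k, p in enumerate(kept):
        support = (nearest == k) & (arr > 0.5 * arr[p])
        comps, n = ndimage.label(support, structure=_CROSS)
        if n == 0 or comps[p] == 0:
            continue
        mask = comps == comps[p]
        masks.append(mask)

    label_map = np.zeros(arr.shape, dtype=np.int32)
    for lab, mask in enumerate(masks, start=1):
        label_map[mask] = lab
    return _size_filtered(label_map, arr, cfg)


SEGMENTERS = {
    "thr": segment_thr,
    "thrws": segment_thr_ws,
    "locmax": segment_locmax,
}
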