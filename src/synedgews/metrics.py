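"""Segmentation-quality metrics.

* object-level F1 — one-to-one greedy ROI matching by pixel overlap; a pair
  is valid when the intersection covers at least half of the smaller ROI.
* dice coefficient — pixel-level mask overlap ``2|A∩B| / (|A|+|B|)``.
* boundary F1 (bf score) — harmonic mean of boundary precision and recall
  within a Euclidean pixel tolerance (default 2 px, punctum-scale contours).

Empty-vs-empty comparisons score 1 in every metric so that perfect
agreement on a blank image is a perfect score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage

from .config import ParameterError
from .segment import SegmentationResult

__all__ = ["MetricReport", "Matching", "match_rois", "object_f1", "dice",
           "bf_score", "evaluate"]


@dataclass
class Matching:
    pairs: List[Tuple[int, int]]        # (ref label, auto label)
    unmatched_ref: List[int]            # false negatives
    unmatched_auto: List[int]           # false positives


@dataclass
class MetricReport:
    precision: float
    recall: float
    f1: float
    dice: float
    bf_score: float
    n_ref: int
    n_auto: int
    n_matched: int
    tolerance_px: float


def _label_map(x) -> np.ndarray:
    if isinstance(x, SegmentationResult):
        return x.label_map
    return np.asarray(x)


def match_rois(ref, auto, min_overlap_fraction: float = 0.5) -> Matching:
    """Greedy one-to-one ROI matching by descending pixel overlap.

    A (ref, auto) pair is a candidate iff their intersection holds at least
    ``min_overlap_fraction`` of the smaller ROI's pixels.  Candidates are
    taken in order of descending overlap, ties broken by smaller ref label
    then smaller auto label.
    """
    ref_map = _label_map(ref)
    auto_map = _label_map(auto)
    if ref_map.shape != auto_map.shape:
        raise ParameterError("label maps must share one image domain")

    ref_labels = [int(v) for v in np.unique(ref_map) if v != 0]
    auto_labels = [int(v) for v in np.unique(auto_map) if v != 0]
    ref_sizes = {l: int((ref_map == l).sum()) for l in ref_labels}
    auto_sizes = {l: int((auto_map == l).sum()) for l in auto_labels}

    both = (ref_map > 0) & (auto_map > 0)
    candidates = []
    if both.any():
        pairs, counts = np.unique(
            np.column_stack([ref_map[both], auto_map[both]]), axis=0, return_counts=True
        )
        for (rl, al), ov in zip(pairs, counts):
            rl, al, ov = int(rl), int(al), int(ov)
            if ov >= min_overlap_fraction * min(ref_sizes[rl], auto_sizes[al]):
                candidates.append((ov, rl, al))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    used_ref, used_auto, matched = set(), set(), []
    for ov, rl, al in candidates:
        if rl in used_ref or al in used_auto:
            continue
        matched.append((rl, al))
        used_ref.add(rl)
        used_auto.add(al)
    return Matching(
        pairs=matched,
        unmatched_ref=[l for l in ref_labels if l not in used_ref],
        unmatched_auto=[l for l in auto_labels if l not in used_auto],
    )


def object_f1(ref, auto, min_overlap_fraction: float = 0.5
              ) -> Tuple[float, float, float]:
    """Object-level (precision, recall, F1) from one-to-one ROI matching."""
    m = match_rois(ref, auto, min_overlap_fraction)
    n_matched = len(m.pairs)
    n_ref = n_matched + len(m.unmatched_ref)
    n_auto = n_matched + len(m.unmatched_auto)
    if n_ref == 0 and n_auto == 0:
        return 1.0, 1.0, 1.0
    precision = n_matched / n_auto if n_auto else 0.0
    recall = n_matched / n_ref if n_ref else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1


def dice(mask_ref: np.ndarray, mask_auto: np.ndarray) -> float:
    """Pixel-level dice coefficient ``2|A∩B| / (|A|+|B|)``; both empty -> 1."""
    a = np.asarray(mask_ref, dtype=bool)
    b = np.asarray(mask_auto, dtype=bool)
    if a.shape != b.shape:
        raise ParameterError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with a 4-neighbor (inside the image) in the complement."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=1
    )
    return mask & ~eroded


def bf_score(mask_ref: np.ndarray, mask_auto: np.ndarray,
             tolerance_px: float = 2.0) -> float:
    """Boundary F1 within a Euclidean pixel tolerance.

    Precision: fraction of auto-boundary pixels within ``tolerance_px`` of
    any ref-boundary pixel; recall symmetric; score their harmonic mean.
    Both boundaries empty -> 1; exactly one empty -> 0.
    """
    a = np.asarray(mask_ref, dtype=bool)
    b = np.asarray(mask_auto, dtype=bool)
    if a.shape != b.shape:
        raise ParameterError(f"shape mismatch: {a.shape} vs {b.shape}")
    if tolerance_px <= 0:
        raise ParameterError("tolerance_px must be positive")
    ba = _boundary(a)
    bb = _boundary(b)
    if not ba.any() and not bb.any():
        return 1.0
    if not ba.any() or not bb.any():
        return 0.0
    dist_to_ref = ndimage.distance_transform_edt(~ba)
    dist_to_auto = ndimage.distance_transform_edt(~bb)
    precision = float((dist_to_ref[bb] <= tolerance_px).mean())
    recall = float((dist_to_auto[ba] <= tolerance_px).mean())
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def evaluate(ref, auto, tolerance_px: float = 2.0) -> MetricReport:
    """All metrics of one (reference, automatic) segmentation pair."""
    ref_map = _label_map(ref)
    auto_map = _label_map(auto)
    m = match_rois(ref_map, auto_map)
    n_matched = len(m.pairs)
    n_ref = n_matched + len(m.unmatched_ref)
    n_auto = n_matched + len(m.unmatched_auto)
    precision, recall, f1 = object_f1(ref_map, auto_map)
    return MetricReport(
        precision=precision,
        recall=recall,
        f1=f1,
        dice=dice(ref_map > 0, auto_map > 0),
        bf_score=bf_score(ref_map > 0, auto_map > 0, tolerance_px),
        n_ref=n_ref,
        n_auto=n_auto,
        n_matched=n_matched,
        tolerance_px=tolerance_px,
    )
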