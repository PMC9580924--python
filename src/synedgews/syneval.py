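"""Three-channel colocalization analysis.

Channel 1 (the synapse-marker staining) is segmented once and serves as the
template; the ROI coordinates are transferred unchanged to channels 2 and 3
where only the mean fluorescence intensity (MFI) per ROI is read out.  A
per-channel positivity threshold is the median of the lowest 1% of
intensities inside a rough (edge/dilate/flood-fill) segmentation of that
channel; an ROI is called positive when its MFI strictly exceeds the
threshold.  The batch driver processes file triplets and exports a feature
table (CSV + XLSX) plus per-image aggregates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import disk

from .config import ParameterError, RunConfig
from .preprocess import preprocess
from .segment import SegmentationResult, compute_gradient, rough_segment, segment, threshold_schedule

logger = logging.getLogger(__name__)

__all__ = ["colocalization_threshold", "transfer_and_measure",
           "analyze_triplet", "run_syneval"]


def colocalization_threshold(image: np.ndarray, cfg) -> float:
    """Positivity threshold: median of the lowest 1% of intensities inside a
    rough segmentation of the channel.

    The rough segmentation reuses the first-iteration gradient threshold of
    the main segmenter (edge filter, dilation, flood fill), floored at six
    times the median nonzero gradient magnitude: the noise-gradient tail
    dies out below that point, so a channel without real structure yields an
    (almost) empty region instead of a region made of noise clusters.  The
    filled region is eroded back by the dilation radius plus one so that
    neither the dilation halo nor the outermost ring fringe (where
    background subtraction clips values to zero) drags the
    lowest-percentile statistic down to the background level.  An empty
    rough segmentation yields ``+inf`` (nothing can be positive) with a
    warning.
    """
    arr = np.asarray(image, dtype=float)
    grad = compute_gradient(arr)
    t0 = threshold_schedule(grad, cfg, 0)
    nz = grad[grad > 0]
    if nz.size:
        t0 = max(t0, 6.0 * float(np.median(nz)))
    region = rough_segment(grad, t0, dilation_radius=2)
    region = ndimage.binary_erosion(region, structure=disk(3), border_value=0)
    vals = arr[region]
    if vals.size == 0:
        logger.warning("colocalization threshold: empty rough segmentation; "
                       "all ROIs will be called negative")
        return math.inf
    k = max(1, math.ceil(0.01 * vals.size))
    lowest = np.sort(vals, kind="stable")[:k]
    return float(np.median(lowest))


def transfer_and_measure(seg: SegmentationResult, channel: np.ndarray) -> np.ndarray:
    """Per-ROI MFI of ``channel`` over the template ROI coordinates."""
    arr = np.asarray(channel, dtype=float)
    if arr.shape != seg.label_map.shape:
        raise ParameterError(
            f"channel shape {arr.shape} does not match template {seg.label_map.shape}"
        )
    return np.array([arr[r.pixels[:, 0], r.pixels[:, 1]].mean() for r in seg.rois])


@dataclass
class TripletResult:
    records: pd.DataFrame
    aggregates: dict
    seg: SegmentationResult


def analyze_triplet(ch1: np.ndarray, ch2: np.ndarray, ch3: np.ndarray,
                    cfg: RunConfig, image_id: str = "image") -> TripletResult:
    """Analyze one preprocessed-from-raw channel triplet in memory."""
    acq = cfg.acquisition
    for name, ch in (("ch2", ch2), ("ch3", ch3)):
        if np.asarray(ch).shape != np.asarray(ch1).shape:
            raise ParameterError(f"{name} shape differs from the template channel")
    p1 = preprocess(ch1, acq)
    p2 = preprocess(ch2, acq)
    p3 = preprocess(ch3, acq)

    seg = segment(p1, acq)
    mfi1 = transfer_and_measure(seg, p1)
    mfi2 = transfer_and_measure(seg, p2)
    mfi3 = transfer_and_measure(seg, p3)
    thr2 = colocalization_threshold(p2, acq)
    thr3 = colocalization_threshold(p3, acq)
    pos2 = mfi2 > thr2
    pos3 = mfi3 > thr3

    records = pd.DataFrame({
        "image_id": image_id,
        "roi_label": [r.label for r in seg.rois],
        "area_px": [r.area_px for r in seg.rois],
        "centroid_row": [r.centroid[0] for r in seg.rois],
        "centroid_col": [r.centroid[1] for r in seg.rois],
        "mfi_ch1": mfi1,
        "mfi_ch2": mfi2,
        "mfi_ch3": mfi3,
        "pos_ch2": pos2,
        "pos_ch3": pos3,
    })

    n = len(seg.rois)
    n23 = int((pos2 & pos3).sum())
    aggregates = {
        "image_id": image_id,
        "n_rois": n,
        "threshold_ch2": thr2,
        "threshold_ch3": thr3,
        "frac_pos_ch2": float(pos2.mean()) if n else 0.0,
        "frac_pos_ch3": float(pos3.mean()) if n else 0.0,
        "frac_neg_ch2": float((~pos2).mean()) if n else 0.0,
        "frac_neg_ch3": float((~pos3).mean()) if n else 0.0,
        "frac_pos_ch2_given_ch3": n23 / int(pos3.sum()) if pos3.any() else 0.0,
        "frac_pos_ch3_given_ch2": n23 / int(pos2.sum()) if pos2.any() else 0.0,
        "mean_mfi_ch2_pos": float(mfi2[pos2].mean()) if pos2.any() else 0.0,
        "mean_mfi_ch3_pos": float(mfi3[pos3].mean()) if pos3.any() else 0.0,
    }
    return TripletResult(records=records, aggregates=aggregates, seg=seg)


def run_syneval(ch1_files: Sequence, ch2_files: Sequence, ch3_files: Sequence,
                cfg: RunConfig, out_dir=None) -> Tuple[pd.DataFrame, pd.DataFrame, List[str]]:
    """Batch driver: per triplet segment ch1, measure ch2/ch3, call
    positivity, and collect records + per-image aggregates.

    Unreadable or mismatched items are logged and skipped; the batch
    continues.  Returns (records, aggregates, failed_ids) and, if
    ``out_dir`` is given, writes CSV/XLSX tables, label-map TIFFs and a
    config echo there.
    """
    from . import io as sio

    if not (len(ch1_files) == len(ch2_files) == len(ch3_files)):
        raise ParameterError("channel file lists must have equal length")

    all_records, all_aggs, failed = [], [], []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for f1, f2, f3 in zip(ch1_files, ch2_files, ch3_files):
        image_id = Path(str(f1)).stem
        try:
            ch1 = sio.read_image(f1)
            ch2 = sio.read_image(f2)
            ch3 = sio.read_image(f3)
            res = analyze_triplet(ch1, ch2, ch3, cfg, image_id=image_id)
        except Exception as exc:  # per-item failure keeps the batch alive
            logger.error("syneval: item %s failed: %s", image_id, exc)
            failed.append(image_id)
            continue
        all_records.append(res.records)
        all_aggs.append(res.aggregates)
        if out is not None:
            sio.write_label_map(out / f"{image_id}_labels.tif", res.seg.label_map)

    records = (pd.concat(all_records, ignore_index=True) if all_records
               else pd.DataFrame(columns=["image_id", "roi_label", "area_px",
                                          "centroid_row", "centroid_col", "mfi_ch1",
                                          "mfi_ch2", "mfi_ch3", "pos_ch2", "pos_ch3"]))
    aggregates = pd.DataFrame(all_aggs)
    if out is not None:
        sio.export_tables({"features": records, "aggregates": aggregates},
                          out, stem="syneval")
        cfg.to_yaml(out / "config_echo.yaml")
    return records, aggregates, failed
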