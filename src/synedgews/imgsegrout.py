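"""Time-lapse trace extraction.

A template image (single frame or consecutive-frame average, preprocessed)
is segmented once; the ROI coordinates are transferred to every frame of
the stack to read out per-ROI mean-fluorescence-intensity (MFI) traces and
one background value per frame (median of the pixels outside all ROIs,
2-px dilation buffer).  Postprocessing subtracts the background trace,
applies a centered moving-average smoothing, and optionally divides by a
monoexponential photobleaching decay fitted to the baseline frames.
Normalization maps each trace to ΔF/F between its baseline mean (→ 0) and
its alkalization-plateau mean (→ 1); the across-ROI mean curve with
per-frame SEM is emitted alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.morphology import disk

from .config import ParameterError, RunConfig
from .preprocess import preprocess
from .segment import SegmentationResult, segment

logger = logging.getLogger(__name__)

__all__ = ["ImageStack", "TraceSet", "make_template", "extract_traces",
           "postprocess_traces", "normalize_traces", "analyze_stack",
           "run_imgsegrout"]


@dataclass
class ImageStack:
    """Ordered frames of identical shape plus acquisition timing metadata."""

    frames: np.ndarray                 # (n_frames, H, W)
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ParameterError("a stack needs >= 2 frames of identical shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class TraceSet:
    """Per-ROI MFI traces through every processing stage."""

    raw: np.ndarray                            # (n_rois, n_frames)
    background: np.ndarray                     # (n_frames,)
    processed: Optional[np.ndarray] = None
    normalized: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None         # (n_rois,) bool
    baseline_frames: Optional[Tuple[int, int]] = None
    nh4cl_frames: Optional[Tuple[int, int]] = None
    mean_curve: Optional[np.ndarray] = None
    sem_curve: Optional[np.ndarray] = None
    bleach_tau: Optional[np.ndarray] = None    # per-ROI fitted tau (frames)


Selection = Union[int, Tuple[int, int]]


def make_template(stack: ImageStack, selection: Selection, cfg: RunConfig) -> np.ndarray:
    """Preprocessed template: a single frame or a consecutive-frame mean."""
    if isinstance(selection, (int, np.integer)):
        if not 0 <= selection < stack.n_frames:
            raise ParameterError(f"frame index {selection} out of range")
        template = stack.frames[int(selection)]
    else:
        start, stop = int(selection[0]), int(selection[1])
        if not (0 <= start < stop <= stack.n_frames):
            raise ParameterError(f"frame range {selection} out of range")
        template = stack.frames[start:stop].mean(axis=0)
    return preprocess(template, cfg.acquisition)


def extract_traces(stack: ImageStack, seg: SegmentationResult) -> TraceSet:
    """Raw per-ROI MFI traces plus the per-frame background trace.

    The background value of a frame is the median over pixels outside the
    union of all ROIs dilated by 2 px (a spill-over buffer).
    """
    if seg.label_map.shape != stack.shape:
        raise ParameterError("segmentation does not match the stack's frame shape")
    frames = stack.frames
    n_rois = len(seg.rois)
    raw = np.empty((n_rois, stack.n_frames))
    for i, roi in enumerate(seg.rois):
        raw[i] = frames[:, roi.pixels[:, 0], roi.pixels[:, 1]].mean(axis=1)
    union = seg.label_map > 0
    buffer = ndimage.binary_dilation(union, structure=disk(2))
    outside = ~buffer
    if outside.any():
        background = np.median(frames[:, outside], axis=1)
    else:
        logger.warning("extract_traces: no background pixels left; background trace set to 0")
        background = np.zeros(stack.n_frames)
    return TraceSet(raw=raw, background=np.asarray(background, dtype=float))


def _monoexp(t, a, tau):
    return a * np.exp(-t / tau)


def fit_bleach_tau(trace: np.ndarray, baseline_frames: Tuple[int, int]) -> float:
    """Monoexponential decay constant (frames) fitted on the baseline window.

    The model is ``a * exp(-t/tau)``: after background subtraction,
    photobleaching acts multiplicatively on the signal, so the baseline
    decays toward zero without an additive offset.  Returns NaN when the fit
    fails or the baseline is degenerate.
    """
    b0, b1 = baseline_frames
    y = np.asarray(trace, dtype=float)[b0:b1]
    t = np.arange(b0, b1, dtype=float)
    if y.size < 4 or not np.all(np.isfinite(y)) or y.max() <= 0:
        return float("nan")
    try:
        popt, _ = curve_fit(
            _monoexp, t, y,
            p0=(max(float(y[0]), 1e-6), float(max(y.size, 10.0))),
            bounds=([0.0, 1e-3], [np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return float("nan")
    return float(popt[1])


def postprocess_traces(traces: TraceSet, cfg: RunConfig,
                       baseline_frames: Optional[Tuple[int, int]] = None) -> TraceSet:
    """Background subtraction, smoothing, optional bleaching correction.

    Bleaching correction estimates a single decay constant per stack:
    photobleaching is a property of the fluorophore and illumination shared
    by every punctum in the field, and pooling across ROIs (the mean trace)
    makes the short-baseline fit well-conditioned where individual-trace
    fits are noise-dominated.  Every trace is then divided by
    ``exp(-t/tau)`` (unity at t = 0).  If the fit fails the traces are left
    uncorrected with a logged warning.
    """
    processed = traces.raw - traces.background[None, :]
    w = int(cfg.smoothing_window)
    if w > 1:
        processed = ndimage.uniform_filter1d(processed, size=w, axis=1, mode="reflect")

    taus = np.full(processed.shape[0], np.nan)
    if cfg.acquisition.bleach_correct_enabled and processed.shape[0] > 0:
        if baseline_frames is None:
            baseline_frames = cfg.baseline_frames
        mean_trace = processed.mean(axis=0)
        tau = fit_bleach_tau(mean_trace, baseline_frames)
        if np.isfinite(tau):
            t_all = np.arange(processed.shape[1], dtype=float)
            processed = processed / np.exp(-t_all / tau)[None, :]
            taus[:] = tau
        else:
            logger.warning("bleach fit failed on the mean trace; traces left uncorrected")

    return TraceSet(
        raw=traces.raw, background=traces.background, processed=processed,
        bleach_tau=taus,
    )


def normalize_traces(traces: TraceSet, baseline_frames: Tuple[int, int],
                     nh4cl_frames: Tuple[int, int]) -> TraceSet:
    """ΔF/F: per trace, ``(F(t) - F_base) / (F_NH4Cl - F_base)``.

    ``F_base`` / ``F_NH4Cl`` are the trace means over the baseline and
    alkalization-plateau frame ranges.  Traces without dynamic range
    (``F_NH4Cl <= F_base``) are flagged invalid and excluded from the
    across-ROI mean ± SEM curve.
    """
    b0, b1 = baseline_frames
    a0, a1 = nh4cl_frames
    if not (b1 <= a0 or a1 <= b0):
        raise ParameterError("baseline and alkalization frame ranges must be disjoint")
    y = traces.processed if traces.processed is not None else traces.raw
    n_frames = y.shape[1]
    if not (0 <= b0 < b1 <= n_frames and 0 <= a0 < a1 <= n_frames):
        raise ParameterError("frame ranges outside the stack")

    f_base = y[:, b0:b1].mean(axis=1)
    f_plateau = y[:, a0:a1].mean(axis=1)
    denom = f_plateau - f_base
    valid = denom > 0
    if not valid.all():
        logger.warning("normalize_traces: %d trace(s) without dynamic range excluded",
                       int((~valid).sum()))
    normalized = np.full_like(y, np.nan)
    normalized[valid] = (y[valid] - f_base[valid, None]) / denom[valid, None]

    if valid.any():
        sel = normalized[valid]
        mean_curve = sel.mean(axis=0)
        sem_curve = (sel.std(axis=0, ddof=1) / np.sqrt(sel.shape[0])
                     if sel.shape[0] > 1 else np.zeros(n_frames))
    else:
        mean_curve = np.full(n_frames, np.nan)
        sem_curve = np.full(n_frames, np.nan)

    return TraceSet(
        raw=traces.raw, background=traces.background, processed=y,
        normalized=normalized, valid=valid,
        baseline_frames=(b0, b1), nh4cl_frames=(a0, a1),
        mean_curve=mean_curve, sem_curve=sem_curve,
        bleach_tau=traces.bleach_tau,
    )


@dataclass
class StackResult:
    seg: SegmentationResult
    traces: TraceSet
    stack_id: str = "stack"


def analyze_stack(stack: ImageStack, cfg: RunConfig,
                  template_selection: Optional[Selection] = None,
                  baseline_frames: Optional[Tuple[int, int]] = None,
                  nh4cl_frames: Optional[Tuple[int, int]] = None,
                  stack_id: str = "stack") -> StackResult:
    """Template -> segment once -> extract -> postprocess -> normalize."""
    template_selection = (cfg.template_selection if template_selection is None
                          else template_selection)
    baseline_frames = cfg.baseline_frames if baseline_frames is None else baseline_frames
    nh4cl_frames = cfg.nh4cl_frames if nh4cl_frames is None else nh4cl_frames
    template = make_template(stack, template_selection, cfg)
    seg = segment(template, cfg.acquisition)
    traces = extract_traces(stack, seg)
    traces = postprocess_traces(traces, cfg, baseline_frames=baseline_frames)
    traces = normalize_traces(traces, baseline_frames, nh4cl_frames)
    return StackResult(seg=seg, traces=traces, stack_id=stack_id)


def run_imgsegrout(stack_files: Sequence, cfg: RunConfig,
                   template_selection: Optional[Selection] = None,
                   baseline_frames: Optional[Tuple[int, int]] = None,
                   nh4cl_frames: Optional[Tuple[int, int]] = None,
                   out_dir=None) -> Tuple[List[StackResult], List[str]]:
    """Batch driver over multi-page TIFF stacks; unreadable items are logged
    and skipped.  With ``out_dir`` set, exports per-stack trace tables
    (raw/processed/normalized/background), the mean ± SEM curve, the
    template label map, and a config echo."""
    from . import io as sio

    results: List[StackResult] = []
    failed: List[str] = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for path in stack_files:
        stack_id = Path(str(path)).stem
        try:
            stack = sio.read_stack(path)
            res = analyze_stack(stack, cfg, template_selection,
                                baseline_frames, nh4cl_frames, stack_id=stack_id)
        except Exception as exc:
            logger.error("imgsegrout: stack %s failed: %s", stack_id, exc)
            failed.append(stack_id)
            continue
        results.append(res)
        if out is not None:
            _export_stack_result(res, out)
    if out is not None:
        cfg.to_yaml(out / "config_echo.yaml")
    return results, failed


def _export_stack_result(res: StackResult, out: Path) -> None:
    from . import io as sio

    ts = res.traces
    labels = [f"roi_{r.label}" for r in res.seg.rois]
    tables = {
        "raw": pd.DataFrame(ts.raw.T, columns=labels),
        "processed": pd.DataFrame(ts.processed.T, columns=labels),
        "normalized": pd.DataFrame(ts.normalized.T, columns=labels),
        "background": pd.DataFrame({"background": ts.background}),
        "mean_curve": pd.DataFrame({"mean_dff": ts.mean_curve, "sem": ts.sem_curve}),
    }
    sio.export_tables(tables, out, stem=res.stack_id)
    sio.write_label_map(out / f"{res.stack_id}_labels.tif", res.seg.label_map)
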