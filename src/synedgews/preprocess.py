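"""Image preprocessing: background estimation/subtraction, contrast
normalization, and retouching of very bright regions.

The chain applied before any segmentation is::

    background = mean-filter(original)
    original   = retouch(original, background)     # optional
    out        = clip(original - background, 0, inf)
    out        = (out - min) / (max - min)

Background is estimated by convolution with a normalized uniform (mean)
kernel wide enough to average puncta away while retaining slow illumination
structure.  Retouching targets images whose intensity histogram is bimodal —
a dim neurite/background mode plus a bright soma mode — and replaces pixels
above the inter-mode minimum by the background estimate, so that strong
somatic fluorescence does not dominate the gradient statistics downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.morphology import disk

from .config import AcquisitionConfig, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "RetouchResult",
    "estimate_background",
    "subtract_background",
    "normalize_linear",
    "retouch_bright_regions",
    "default_background_radius",
    "preprocess",
]


@dataclass
class RetouchResult:
    """Retouched image plus the binary mask of replaced pixels."""

    image: np.ndarray
    mask: np.ndarray


def _as_float_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ParameterError(f"expected a 2D image, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ParameterError("image contains non-finite values")
    return arr


def estimate_background(image: np.ndarray, kernel_radius: int) -> np.ndarray:
    """Smooth background estimate: mean filter with a (2r+1)² uniform kernel.

    Borders are handled by reflection, so a constant image maps to itself.
    """
    arr = _as_float_image(image)
    r = int(kernel_radius)
    if r < 1:
        raise ParameterError("kernel_radius must be >= 1")
    if r >= min(arr.shape) / 2:
        raise ParameterError(
            f"kernel_radius {r} too large for image of shape {arr.shape}"
        )
    return ndimage.uniform_filter(arr, size=2 * r + 1, mode="reflect")


def subtract_background(image: np.ndarray, background: np.ndarray) -> np.ndarray:
    """``max(image - background, 0)`` elementwise."""
    arr = _as_float_image(image)
    bg = _as_float_image(background)
    if arr.shape != bg.shape:
        raise ParameterError(f"shape mismatch: {arr.shape} vs {bg.shape}")
    return np.clip(arr - bg, 0.0, None)


def normalize_linear(image: np.ndarray) -> np.ndarray:
    """Linear stretch to [0, 1]; a constant image maps to all zeros."""
    arr = _as_float_image(image)
    lo = arr.min()
    hi = arr.max()
    if hi <= lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def retouch_bright_regions(
    image: np.ndarray,
    background: np.ndarray,
    *,
    n_bins: int = 256,
    smooth_bins: int = 5,
    prominence_floor: float = 0.002,
    min_mode_separation_bins: int = 25,
    valley_ratio: float = 0.5,
    min_bright_fraction: float = 0.005,
    dilation_radius: int = 2,
) -> RetouchResult:
    """Replace very bright regions (somata) by background values.

    The cutoff is located at the histogram minimum between the two most
    prominent modes of the smoothed 256-bin intensity histogram.  The
    above-cutoff mask is dilated (disk radius 2) and flood-filled before
    replacement.

    A genuine soma mode is small (a cell body covers a few percent of the
    field) but sits far up the intensity axis with a near-empty valley in
    between, whereas spurious secondary peaks from histogram sampling noise
    hug the main mode on a high shoulder.  The image is therefore returned
    unchanged (empty mask, logged warning) unless a second mode exists with
    prominence >= ``prominence_floor`` of the histogram maximum, at least
    ``min_mode_separation_bins`` away from the primary mode, and with the
    histogram minimum between the two modes below ``valley_ratio`` times
    the second mode's height (valley-dominance bimodality).
    """
    arr = _as_float_image(image)
    bg = _as_float_image(background)
    if arr.shape != bg.shape:
        raise ParameterError(f"shape mismatch: {arr.shape} vs {bg.shape}")

    empty = RetouchResult(image=arr.copy(), mask=np.zeros(arr.shape, dtype=bool))
    lo, hi = arr.min(), arr.max()
    if hi <= lo:
        logger.warning("retouch: constant image, nothing to retouch")
        return empty

    counts, edges = np.histogram(arr, bins=n_bins, range=(lo, hi))
    kernel = np.ones(smooth_bins) / smooth_bins
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")

    peaks, props = find_peaks(smoothed, prominence=0.0)
    top2 = None
    if peaks.size >= 2:
        order = np.argsort(props["prominences"])[::-1]
        main = peaks[order[0]]
        floor = prominence_floor * smoothed.max()
        for i in order[1:]:
            cand = peaks[i]
            if (props["prominences"][i] < floor
                    or abs(int(cand) - int(main)) < min_mode_separation_bins):
                continue
            lo_bin, hi_bin = sorted((int(main), int(cand)))
            valley_bin = lo_bin + int(np.argmin(smoothed[lo_bin:hi_bin + 1]))
            valley = smoothed[valley_bin]
            # a retouchable bright mode must be separated by a deep valley
            # AND cover a non-negligible area of the field
            bright_mass = counts[valley_bin:].sum() if cand > main else counts[:valley_bin + 1].sum()
            if (valley <= valley_ratio * smoothed[cand]
                    and bright_mass >= min_bright_fraction * arr.size):
                top2 = np.array([lo_bin, hi_bin])
                break
    if top2 is None:
        logger.warning("retouch: histogram not bimodal, image left unchanged")
        return empty

    between = smoothed[top2[0] : top2[1] + 1]
    cut_bin = top2[0] + int(np.argmin(between))
    cutoff = 0.5 * (edges[cut_bin] + edges[cut_bin + 1])

    mask = arr > cutoff
    mask = ndimage.binary_dilation(mask, structure=disk(dilation_radius))
    mask = ndimage.binary_fill_holes(mask)

    out = arr.copy()
    out[mask] = bg[mask]
    return RetouchResult(image=out, mask=mask)


def default_background_radius(cfg: AcquisitionConfig, image_shape=None) -> int:
    """Mean-kernel radius: twice the maximum expected punctum diameter in px.

    Wide enough that puncta are averaged out of the background estimate while
    illumination structure is retained.  Clamped to fit the image if a shape
    is given.
    """
    radius = max(1, math.ceil(2.0 * cfg.max_diameter_um / cfg.pixel_size_um))
    if image_shape is not None:
        radius = min(radius, (min(image_shape) - 1) // 2)
    return max(1, radius)


def preprocess(
    image: np.ndarray,
    cfg: AcquisitionConfig,
    *,
    kernel_radius: int | None = None,
) -> np.ndarray:
    """Full preprocessing chain; output is in [0, 1] and deterministic."""
    arr = _as_float_image(image)
    if kernel_radius is None:
        kernel_radius = default_background_radius(cfg, arr.shape)
    background = estimate_background(arr, kernel_radius)
    if cfg.retouch_enabled:
        arr = retouch_bright_regions(arr, background).image
    out = subtract_background(arr, background)
    return normalize_linear(out)
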