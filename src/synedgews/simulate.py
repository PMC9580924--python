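"""Seeded generators of synthetic fluorescence micrographs, three-channel
triplets, and pHluorin-style time-lapse stacks with exact ground truth.

Puncta are rendered as isotropic 2D Gaussians (a diffraction-limited-spot
proxy); the true ROI of a punctum is the disc of radius 2σ around its
center.  Optional ingredients emulate the failure modes the segmenter must
survive: heterogeneous punctum amplitudes, touching punctum pairs (center
distance 2.5σ — merged at the rough-segmentation scale yet separable by
watershed), a linear uneven-illumination plane, very bright flat soma
discs, Gaussian read noise, and an optional Poisson (shot-noise) term.

Stacks render a cumulative-release protocol: a quenched baseline, one or
more stimulus-locked cumulative fluorescence steps (vesicle re-acidification
blocked, so fusion fluorescence accumulates), an alkalization plateau that
de-quenches the whole reporter pool (the normalization ceiling), optional
global monoexponential photobleaching, and per-frame noise.  The per-frame
punctum amplitude is ``A * (f0 + (1 - f0) * level(t))`` with ``level`` the
released fraction, so the true ΔF/F trace of every punctum equals
``level(t)`` exactly.

All outputs are deterministic functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .config import ParameterError

__all__ = ["SynthParams", "GroundTruth", "GenerationError",
           "generate_puncta_image", "generate_triplet", "generate_stack"]


class GenerationError(RuntimeError):
    """Raised when a constraint-satisfying layout cannot be placed."""


@dataclass
class SynthParams:
    """Generator settings; every field has a deterministic effect per seed."""

    shape: Tuple[int, int] = (256, 256)
    n_puncta: int = 30
    sigma_range: Tuple[float, float] = (1.5, 2.5)
    amplitude_range: Tuple[float, float] = (150.0, 300.0)
    amplitude_values: Optional[Sequence[float]] = None  # cycled if given
    fraction_touching: float = 0.0
    touching_distance_sigma: float = 2.5
    background: float = 100.0
    noise_sd: float = 10.0
    poisson_scale: float = 0.0          # photons per intensity unit; 0 = off
    illumination_gradient: float = 0.0  # peak extra intensity of linear plane
    n_soma: int = 0
    soma_radius: float = 20.0
    soma_amplitude: float = 2000.0
    soma_edge_sigma: float = 2.0
    soma_texture: float = 0.25      # relative amplitude of intra-soma texture
    min_separation_px: float = 14.0
    # --- triplet ---
    ch2_fraction: float = 0.5
    ch3_fraction: float = 0.5
    # --- stack kinetics ---
    n_frames: int = 260
    baseline_visible_fraction: float = 0.2
    stim_steps: Tuple[Tuple[int, int, float], ...] = ((40, 2, 0.2), (100, 45, 0.8))
    nh4cl_frames: Tuple[int, int] = (230, 260)
    nh4cl_ramp_frames: int = 2
    bleach_tau: float = 0.0             # frames; 0 = no bleaching
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_puncta < 0:
            raise ParameterError("n_puncta must be >= 0")
        if not 0 <= self.fraction_touching <= 1:
            raise ParameterError("fraction_touching must be in [0, 1]")
        for name in ("ch2_fraction", "ch3_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.sigma_range[0] <= 0 or self.sigma_range[0] > self.sigma_range[1]:
            raise ParameterError("invalid sigma_range")
        if not 0 <= self.baseline_visible_fraction < 1:
            raise ParameterError("baseline_visible_fraction must be in [0, 1)")
        lo, hi = self.nh4cl_frames
        for start, duration, level in self.stim_steps:
            if not 0 < level <= 1:
                raise ParameterError("step levels must be in (0, 1]")
            if start < self.n_frames and start + duration > lo:
                raise ParameterError("stimulus window overlaps the alkalization window")


@dataclass
class GroundTruth:
    """Exact layout and kinetics behind one generated dataset."""

    centers: np.ndarray                  # (n, 2) float (row, col)
    sigmas: np.ndarray                   # (n,)
    amplitudes: np.ndarray               # (n,) full (de-quenched) amplitude
    label_map: np.ndarray                # int32, punctum k -> label k+1
    touching_pairs: List[Tuple[int, int]] = field(default_factory=list)
    soma: List[Tuple[Tuple[float, float], float, float]] = field(default_factory=list)
    positive_ch2: Optional[np.ndarray] = None
    positive_ch3: Optional[np.ndarray] = None
    level_curve: Optional[np.ndarray] = None   # (n_frames,) true ΔF/F
    step_levels: Optional[Tuple[float, ...]] = None
    bleach_tau: float = 0.0
    baseline_frames: Optional[Tuple[int, int]] = None
    nh4cl_frames: Optional[Tuple[int, int]] = None


# ----------------------------------------------------------------- layout

def _place_layout(params: SynthParams, rng: np.random.Generator):
    h, w = params.shape
    sig_lo, sig_hi = params.sigma_range
    margin = math.ceil(2 * sig_hi) + 3
    if h - 2 * margin <= 1 or w - 2 * margin <= 1:
        raise ParameterError("image too small for the configured punctum size")

    n_pairs = int(round(params.fraction_touching * params.n_puncta / 2))
    n_singles = params.n_puncta - 2 * n_pairs

    centers: List[Tuple[float, float]] = []
    sigmas: List[float] = []
    amplitudes: List[float] = []
    pairs: List[Tuple[int, int]] = []

    def amp(i: int) -> float:
        if params.amplitude_values is not None:
            vals = list(params.amplitude_values)
            return float(vals[i % len(vals)])
        return float(rng.uniform(*params.amplitude_range))

    def far_enough(r, c):
        return all((r - rr) ** 2 + (c - cc) ** 2 >= params.min_separation_px ** 2
                   for rr, cc in centers)

    max_tries = 200 * max(1, params.n_puncta)
    tries = 0
    for _ in range(n_pairs):
        sigma = float(rng.uniform(sig_lo, sig_hi))
        a = amp(len(centers))
        d = params.touching_distance_sigma * sigma
        while True:
            tries += 1
            if tries > max_tries:
                raise GenerationError("could not place touching pairs within retry budget")
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            theta = rng.uniform(0, 2 * math.pi)
            r2 = r + d * math.sin(theta)
            c2 = c + d * math.cos(theta)
            if not (margin <= r2 < h - margin and margin <= c2 < w - margin):
                continue
            if far_enough(r, c) and far_enough(r2, c2):
                break
        i = len(centers)
        centers.extend([(r, c), (r2, c2)])
        sigmas.extend([sigma, sigma])
        amplitudes.extend([a, a])  # equal within pair: similar touching synapses
        pairs.append((i, i + 1))

    for _ in range(n_singles):
        while True:
            tries += 1
            if tries > max_tries:
                raise GenerationError("could not place puncta within retry budget")
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if far_enough(r, c):
                break
        centers.append((r, c))
        sigmas.append(float(rng.uniform(sig_lo, sig_hi)))
        amplitudes.append(amp(len(centers) - 1))

    soma = []
    for _ in range(params.n_soma):
        rad = params.soma_radius
        while True:
            tries += 1
            if tries > max_tries:
                raise GenerationError("could not place soma within retry budget")
            r = rng.uniform(rad + 2, h - rad - 2)
            c = rng.uniform(rad + 2, w - rad - 2)
            if all((r - rr) ** 2 + (c - cc) ** 2 >= (rad + 4 * sig_hi) ** 2
                   for rr, cc in centers):
                break
        soma.append(((r, c), rad, params.soma_amplitude))

    return (np.array(centers, dtype=float).reshape(-1, 2),
            np.array(sigmas, dtype=float),
            np.array(amplitudes, dtype=float),
            pairs, soma)


def _true_label_map(shape, centers, sigmas) -> np.ndarray:
    """Punctum k labels the pixels within 2σ_k of its center; on overlap the
    center with the smaller normalized distance d/σ wins."""
    label_map = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf)
    for k, ((cr, cc), sigma) in enumerate(zip(centers, sigmas)):
        rad = int(math.ceil(2 * sigma))
        r0, r1 = max(0, int(cr) - rad - 1), min(shape[0], int(cr) + rad + 2)
        c0, c1 = max(0, int(cc) - rad - 1), min(shape[1], int(cc) + rad + 2)
        rr, cc_ = np.mgrid[r0:r1, c0:c1]
        d = np.sqrt((rr - cr) ** 2 + (cc_ - cc) ** 2)
        nd = d / sigma
        patch_best = best[r0:r1, c0:c1]
        take = (d <= 2 * sigma) & (nd < patch_best)
        label_map[r0:r1, c0:c1][take] = k + 1
        patch_best[take] = nd[take]
    return label_map


def _punctum_patches(shape, centers, sigmas):
    """Unit-amplitude Gaussian patch and slice per punctum."""
    patches = []
    for (cr, cc), sigma in zip(centers, sigmas):
        rad = int(math.ceil(4 * sigma))
        r0, r1 = max(0, int(cr) - rad), min(shape[0], int(cr) + rad + 1)
        c0, c1 = max(0, int(cc) - rad), min(shape[1], int(cc) + rad + 1)
        rr, cc_ = np.mgrid[r0:r1, c0:c1]
        g = np.exp(-((rr - cr) ** 2 + (cc_ - cc) ** 2) / (2 * sigma ** 2))
        patches.append(((slice(r0, r1), slice(c0, c1)), g))
    return patches


def _scene_base(params: SynthParams, soma,
                rng: np.random.Generator | None = None) -> np.ndarray:
    """Background + illumination plane + soma discs (no puncta, no noise).

    Somata are bright discs with smooth low-frequency internal texture
    (organelles and uneven reporter expression make real cell bodies
    heterogeneous, which is what seeds spurious detections inside them).
    """
    h, w = params.shape
    base = np.full(params.shape, float(params.background))
    if params.illumination_gradient:
        col = np.linspace(0.0, 1.0, w)
        row = np.linspace(0.0, 1.0, h)
        base += params.illumination_gradient * 0.5 * (row[:, None] + col[None, :])
    for (cr, cc), rad, amp in soma:
        rr, cc_ = np.mgrid[0:h, 0:w]
        disc = ((rr - cr) ** 2 + (cc_ - cc) ** 2 <= rad ** 2).astype(float)
        if params.soma_edge_sigma > 0:
            disc = ndimage.gaussian_filter(disc, params.soma_edge_sigma)
        level = amp
        if params.soma_texture > 0 and rng is not None:
            texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 2.0)
            texture /= max(np.abs(texture).max(), 1e-12)
            level = amp * (1.0 + params.soma_texture * texture)
        base += level * disc
    return base


def _add_noise(img: np.ndarray, params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    out = img
    if params.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * params.poisson_scale) / params.poisson_scale
    if params.noise_sd > 0:
        out = out + rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(out, 0.0, None)


# -------------------------------------------------------------- generators

def generate_puncta_image(params: SynthParams, seed: int | None = None
                          ) -> Tuple[np.ndarray, GroundTruth]:
    """One single-channel micrograph plus its exact ground truth."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    centers, sigmas, amplitudes, pairs, soma = _place_layout(params, rng)
    img = _scene_base(params, soma, rng)
    for (sl, g), a in zip(_punctum_patches(params.shape, centers, sigmas), amplitudes):
        img[sl] += a * g
    img = _add_noise(img, params, rng)
    truth = GroundTruth(
        centers=centers, sigmas=sigmas, amplitudes=amplitudes,
        label_map=_true_label_map(params.shape, centers, sigmas),
        touching_pairs=pairs, soma=soma,
    )
    return img, truth


def generate_triplet(params: SynthParams, seed: int | None = None):
    """Three matched channels: ch1 holds every punctum, ch2/ch3 hold signal
    at random punctum subsets of the configured fractions (independent
    noise per channel)."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    centers, sigmas, amplitudes, pairs, soma = _place_layout(params, rng)
    n = len(centers)

    def pick(fraction: float) -> np.ndarray:
        # exactly round(fraction * n) positives, at random positions
        flags = np.zeros(n, dtype=bool)
        flags[rng.permutation(n)[: int(round(fraction * n))]] = True
        return flags

    pos2 = pick(params.ch2_fraction)
    pos3 = pick(params.ch3_fraction)
    patches = _punctum_patches(params.shape, centers, sigmas)
    base = _scene_base(params, soma, rng)

    def render(select: np.ndarray) -> np.ndarray:
        img = base.copy()
        for keep, (sl, g), a in zip(select, patches, amplitudes):
            if keep:
                img[sl] += a * g
        return _add_noise(img, params, rng)

    ch1 = render(np.ones(n, dtype=bool))
    ch2 = render(pos2)
    ch3 = render(pos3)
    truth = GroundTruth(
        centers=centers, sigmas=sigmas, amplitudes=amplitudes,
        label_map=_true_label_map(params.shape, centers, sigmas),
        touching_pairs=pairs, soma=soma,
        positive_ch2=pos2, positive_ch3=pos3,
    )
    return ch1, ch2, ch3, truth


def release_level_curve(params: SynthParams) -> np.ndarray:
    """True released fraction per frame: 0 at baseline, cumulative ramps at
    the stimulus windows, 1 on the alkalization plateau."""
    level = np.zeros(params.n_frames)
    current = 0.0
    t = 0
    for start, duration, target in sorted(params.stim_steps):
        start = min(start, params.n_frames)
        level[t:start] = current
        ramp_end = min(start + duration, params.n_frames)
        k = ramp_end - start
        if k > 0:
            level[start:ramp_end] = current + (target - current) * np.arange(1, k + 1) / duration
        current = level[ramp_end - 1] if k > 0 else current
        t = ramp_end
    level[t:] = current
    a0, a1 = params.nh4cl_frames
    a0 = min(a0, params.n_frames)
    ramp_end = min(a0 + params.nh4cl_ramp_frames, params.n_frames)
    k = ramp_end - a0
    if k > 0:
        level[a0:ramp_end] = current + (1.0 - current) * np.arange(1, k + 1) / max(1, params.nh4cl_ramp_frames)
    level[ramp_end:] = 1.0
    return level


def generate_stack(params: SynthParams, seed: int | None = None):
    """Time-lapse stack with cumulative-release kinetics plus ground truth.

    Returns ``(frames, truth)`` with ``frames`` shaped (n_frames, H, W).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    centers, sigmas, amplitudes, pairs, soma = _place_layout(params, rng)
    level = release_level_curve(params)
    f0 = params.baseline_visible_fraction
    patches = _punctum_patches(params.shape, centers, sigmas)
    base = _scene_base(params, soma, rng)

    frames = np.empty((params.n_frames,) + tuple(params.shape))
    for t in range(params.n_frames):
        frame = base.copy()
        scale = f0 + (1.0 - f0) * level[t]
        for (sl, g), a in zip(patches, amplitudes):
            frame[sl] += a * scale * g
        if params.bleach_tau > 0:
            frame *= math.exp(-t / params.bleach_tau)
        frames[t] = _add_noise(frame, params, rng)

    a0 = params.nh4cl_frames
    truth = GroundTruth(
        centers=centers, sigmas=sigmas, amplitudes=amplitudes,
        label_map=_true_label_map(params.shape, centers, sigmas),
        touching_pairs=pairs, soma=soma,
        level_curve=level,
        step_levels=tuple(s[2] for s in sorted(params.stim_steps)),
        bleach_tau=params.bleach_tau,
        baseline_frames=(0, min(s[0] for s in params.stim_steps) if params.stim_steps
                         else a0[0]),
        nh4cl_frames=(min(a0[0] + params.nh4cl_ramp_frames, params.n_frames), min(a0[1], params.n_frames)),
    )
    return frames, truth
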