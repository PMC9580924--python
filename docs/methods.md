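# Methods

This note documents the models, parameter choices and numerical decisions
behind the package, what the synthetic benchmarks emulate, and the known
limitations.

## Preprocessing

Images are processed in floating point. The chain is:

1. **Background estimation** — convolution with a normalized uniform
   (mean) kernel of radius `r = ⌈2 · d_max / s⌉` pixels, where `d_max` is
   the maximum expected punctum diameter and `s` the sample-plane pixel
   size. Twice the punctum diameter is large enough to average puncta out
   of the estimate while retaining slow illumination structure. Borders
   are handled by edge-inclusive reflection.
2. **Retouching** (optional) — very bright regions (cell bodies) are
   replaced by the background estimate. The cutoff is the histogram
   minimum between the two modes of the smoothed 256-bin intensity
   histogram; the above-cutoff mask is dilated (disk r = 2) and
   flood-filled before replacement. Bimodality is accepted only when the
   secondary mode (i) has prominence ≥ 0.2% of the histogram maximum,
   (ii) lies ≥ 25 bins from the primary mode, (iii) is separated by a
   valley below half its height, and (iv) carries ≥ 0.5% of the pixels
   above the valley. These four conditions were calibrated on the peak
   landscapes of noise-only, puncta-only and soma-bearing scenes: a
   genuine soma mode is small (a cell body covers a few percent of the
   field) but far from the main mode with an empty valley in between,
   whereas histogram-sampling bumps hug the main mode on a high shoulder
   and extreme-tail bumps carry almost no pixel mass. On a unimodal
   histogram the function is a logged no-op.
3. **Subtraction and normalization** — `max(I − B, 0)`, then a linear
   stretch to [0, 1] (a constant image maps to zeros). Normalization makes
   all later thresholds scale-free.

## The edge/watershed segmenter

Detection operates on the Sobel gradient magnitude rather than intensity,
which decouples it from absolute brightness and slow illumination:

* **Threshold schedule** — `t_i = t_0 · δ^i` with
  `t_0 = quantile(|∇I| > 0, q)`. Defaults `q = 0.985`, `δ = 0.5`,
  2 iterations. The quantile must place `t_0` inside the punctum-edge
  gradient band: puncta at typical densities contribute ~2–3% of pixels as
  edges, so q must exceed ~0.98 (a lower q lands in the noise-gradient
  tail and floods the result with noise blobs). With two iterations the
  decay must bridge the ~4× punctum-intensity heterogeneity the tool
  targets; δ = 0.5 does, δ close to 1 cannot. Both are exposed knobs: q
  trades specificity for sensitivity, δ controls how much dimmer the
  second sweep reaches.
* **Rough segmentation** — gradient ≥ t, dilation by disk r = 2 (closing
  noise-induced gaps in near-threshold edge rings; r = 1 leaves partial
  arcs that fill into offset crescents), flood fill of interior holes.
* **Watershed splitting** — per connected section, markers are regional
  maxima after h-maxima suppression with h = 5% of the section's dynamic
  range; markers closer than the minimum expected punctum diameter are
  merged (two maxima that close together cannot be distinct puncta); the
  watershed floods the inverted intensity inside the section. Sections
  with one marker are never split. The 5% h and the size-prior merging
  balance two failure modes: the intensity saddle of a 2.5σ-separated
  punctum pair is only ~13% of peak deep, so h must sit well below it,
  while shallow noise maxima must not seed splits — the distance prior
  handles those instead of a larger h.
* **Cleanup** — morphological opening with the 3×3 structuring element
  (the Chebyshev-metric radius-1 disc) per region; regions erased by the
  opening are discarded, a split region keeps its brightest component.
  The 3×3 element removes width-≤2 filaments and specks without nibbling
  the corners of compact regions.
* **Contour refinement** — boundary pixels dimmer than half the mean of
  the region's interior are peeled iteratively, with a minimum-area guard
  and a connectivity guard (brightest component kept).
* **Acceptance** — a region passes if its area lies in
  `[⌈π(d_min/2s)²⌉, ⌊π(d_max/2s)²⌋]` (inclusive) *and* it contains its
  intensity maximum strictly in its interior. The second condition
  rejects bands filled from partial edge arcs, which peak on their own
  boundary; the punctum is then recovered whole by the next, lower
  threshold.
* **Iteration exclusion** — the whole source watershed section of every
  accepted ROI (not just the refined ROI) is dilated by 1 px and masked
  out of later iterations, so a detected punctum's outer gradient ring is
  not re-detected at lower thresholds. First-iteration results are by
  construction independent of the total iteration count, which makes ROI
  count monotone in the number of iterations.

Coordinates are 0-based (row, col); components and ROIs use
4-connectivity; ROI centroids are intensity-weighted.

## Baseline segmenters

`segment_thr` (Otsu threshold → 4-connected components), `segment_thr_ws`
(the same binary map split by the shared watershed), and `segment_locmax`
(plateau-collapsed local maxima gated by the Otsu threshold, suppressed to
a minimum separation of one minimum punctum diameter, each ROI the
connected half-maximum support in the maximum's nearest-neighbor cell).
All three share the preprocessing and the inclusive size gate, so
comparisons isolate the detection rule itself.

## Metrics

Object-level matching is greedy by descending pixel overlap with a
validity rule |intersection| ≥ 0.5 · min(|ref|, |auto|) and ties broken by
smaller reference label — tolerant to contour disagreement, strict on
identity. Precision = matched/auto, recall = matched/reference, F1 their
harmonic mean; empty-vs-empty scores 1 by convention (perfect agreement on
a blank image). Dice is `2|A∩B|/(|A|+|B|)` on the union masks. Boundary
F1 uses 4-connected inner boundaries and a Euclidean tolerance, default
2 px (punctum-scale contours; exposed as a flag). Dice and boundary F1 are
verified against O(n²) pixel-counting / all-pairs-distance oracles, and
greedy matching against exhaustive maximum matching, in the test suite.

## SynEval (three-channel colocalization)

Channel 1 is segmented once; channels 2 and 3 are only measured (mean
intensity over the transferred ROI pixels — no re-segmentation). The
positivity threshold per channel is the median of the lowest
`⌈0.01 N⌉` intensities inside a rough segmentation of that channel — a
deliberately lenient floor at the bottom of the genuine-signal
distribution. Two numerical safeguards make it behave on hard inputs: the
edge threshold for the rough segmentation is floored at 6× the median
nonzero gradient magnitude (pure-noise gradient tails die below that
point, so a structureless channel yields an empty region, an infinite
threshold, and all-negative calls), and the filled region is eroded by the
dilation radius + 1 so that halo and clipped-to-zero fringe pixels cannot
drag the percentile to the background level. Positivity is the strict
inequality MFI > threshold. Aggregates (positive fractions, conditional
fractions, positive-subset MFI means) are exact recomputations from the
per-ROI records.

## ImgSegRout (time-lapse traces)

The template (single frame or consecutive-frame mean, then preprocessed)
is segmented once; ROI coordinates apply to every frame. The background
trace is the per-frame median over pixels outside all ROIs dilated by
2 px — robust to punctum spill-over. Postprocessing: background
subtraction, centered moving-average smoothing (window 3 frames, reflected
ends, window 1 disables), and optional bleaching correction. Bleaching is
modeled as a single multiplicative decay `exp(−t/τ)` shared by the field:
τ is fitted (2-parameter `a·e^{−t/τ}`, no offset — background subtraction
removes the additive term) on the baseline window of the across-ROI mean
trace, and every trace is divided by the decay. Pooling is essential:
per-trace fits on a short baseline are unidentifiable and inject
late-frame scale errors of order 10%, an order of magnitude above the
pooled fit's error. ΔF/F normalization uses the per-trace means over the
baseline and alkalization windows; traces without positive dynamic range
are flagged invalid and excluded from the mean ± SEM curve.

## Synthetic data

Puncta are isotropic 2D Gaussians (σ 1.5–2.5 px by default) on a constant
background of 100 counts with Gaussian read noise (sd 10) and an optional
Poisson term; the true ROI of a punctum is its 2σ disc. Defaults give peak
SNR 15–30, typical of well-stained synaptic immunofluorescence. Optional
ingredients: a linear illumination plane, touching pairs at center
distance 2.5σ (merged at the rough-segmentation scale, separable by
watershed), and bright soma discs with smooth punctum-scale internal
texture (±25%, correlation σ 2 px) — a perfectly flat soma is
segmentation-neutral because its single watershed section fails the size
gate, whereas textured somata reproduce the spurious in-soma detections
that retouching exists to remove. Stacks render a cumulative-release
protocol (re-acidification blocked): per-frame punctum amplitude
`A·(f₀ + (1−f₀)·level(t))` with `level` ramping through the stimulus
steps to the alkalization ceiling, so the true ΔF/F of every punctum
equals `level(t)` exactly; optional global bleaching multiplies whole
frames. All outputs are bit-deterministic per (parameters, seed).

Canonical benchmark conditions live in `synedgews.fixtures`:

* *well_separated* — 30 isolated puncta, 256², the detection/localization
  benchmark (measured sizes: 10–20 fields per run).
* *heterogeneous* — bimodal amplitudes 300/75 (the 4× split), σ fixed at
  2 px, illumination plane amplitude 80, read noise sd 3. This fixture
  probes threshold scheduling and illumination robustness at high SNR;
  noise robustness is probed by the default fixture.
* *touching_pairs* — all puncta in 2.5σ pairs with σ 2.0–2.5 px, so pair
  separations (5–6.25 px) stay above the minimum punctum diameter (3 px);
  pairs closer than the size prior are outside the splitter's declared
  operating envelope.
* *with_soma* / *release_stack* / *bleach_stack* — as described above;
  stacks use 50 puncta on 192² over 260 frames at 1 Hz, two cumulative
  steps (to 20% and 80% of the pool) and a 30-frame alkalization plateau,
  with bleach τ = 600 frames (release) or 150 frames (bleach-only).

What passing on these fixtures does **not** show: robustness to neurite
morphology and autofluorescence texture, optical PSF structure beyond
Gaussian blur, stage drift, or focus changes — real micrographs add all of
these, and the absolute scores here (e.g. object F1 ≈ 1.0 on the default
fixture) are upper bounds specific to the synthetic conditions. The
*relative* ordering of algorithms and the contracts (iteration semantics,
splitting, trace algebra) are the transferable results.

## Degenerate inputs and tie-breaks

Constant images normalize to zeros and segment to zero ROIs without
error; an all-zero gradient yields threshold 0 and no edges. Empty-vs-
empty metric comparisons score 1; one-sided empties score 0. Watershed
marker merging unions marker centroids closer than the minimum punctum
diameter; label order after any split follows section order, then marker
label. LocMax ties: plateau maxima collapse to the pixel nearest the
plateau centroid; suppression order is descending intensity, then (row,
col). Batch drivers log per-item failures and continue; exports are
deterministic (fixed column order, config echo written with every run).

## Known limitations

* 2D only; z-stacks must be projected or segmented per plane.
* No drift or motion correction in the time-lapse routine.
* The bleach model is a single shared monoexponential; spatially varying
  or reporter-state-dependent bleaching is not modeled.
* The colocalization threshold assumes the measured channels contain
  *some* genuine signal structure or none at all; a channel whose signal
  is entirely below its own noise floor is called all-negative.
* The retouch bimodality detector is tuned for somata covering roughly
  0.5–20% of the field; a field dominated by bright tissue will not be
  classified as bimodal.
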