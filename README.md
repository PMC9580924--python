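# synedgews

Automated detection and analysis of fluorescently labeled synaptic puncta
in 2D micrographs and time-lapse stacks.

Synapses imaged by fluorescence microscopy appear as diffraction-limited
puncta of widely varying brightness, size and background, and most
downstream quantification — how many synapses are active, how much reporter
each one takes up, how its fluorescence evolves under stimulation — starts
with segmenting them. Global intensity thresholds and local-maximum pickers
degrade quickly under uneven illumination and punctum-to-punctum intensity
heterogeneity. This package implements an edge-gradient segmenter with
marker-controlled watershed splitting that avoids a global intensity
cutoff, together with the preprocessing chain, baseline segmenters,
evaluation metrics, and two batch routines built on top of it:

* **`segment`** (SynEdgeWs) — Sobel gradient magnitude `|∇I|`, thresholded
  at an iteratively decreasing level `t_i = t_0 · δ^i` (with `t_0` a high
  quantile of the nonzero gradient magnitudes), dilation + flood fill into
  candidate regions, marker-controlled watershed (h-maxima markers) to
  split touching puncta, morphological cleanup, contour refinement, and an
  area gate `[A_min, A_max]` derived from the expected punctum diameter
  range, the camera pixel size, magnification and binning:
  `A = π (d / 2s)²` with `s = pixel_size · binning / magnification`.
  ROIs accepted at one iteration are excluded from the next, so each sweep
  of the decreasing threshold recovers progressively dimmer puncta.
* **`segment_thr` / `segment_thr_ws` / `segment_locmax`** — the baseline
  segmenters (Otsu threshold, Otsu + watershed, threshold-gated local
  maxima) sharing the same preprocessing and size gate.
* **`metrics`** — object-level F1 (one-to-one ROI matching, precision =
  matched/auto, recall = matched/reference), pixel-level dice
  `2|A∩B|/(|A|+|B|)`, and boundary F1 within a pixel tolerance.
* **SynEval** (`run_syneval`) — three-channel colocalization: channel 1 is
  segmented once as the template, ROI coordinates are transferred to
  channels 2 and 3, per-ROI mean fluorescence intensities (MFI) are read
  out, and per-channel positivity is called against the median of the
  lowest 1% of intensities inside a rough segmentation of that channel.
* **ImgSegRout** (`run_imgsegrout`) — time-lapse trace extraction: a
  template frame (or frame average) is segmented once, per-ROI MFI traces
  and a per-frame background trace are read from every frame, background
  is subtracted, traces are smoothed and optionally bleach-corrected, and
  each trace is normalized to ΔF/F between its baseline (→ 0) and its
  NH₄Cl alkalization plateau (→ 1):
  `ΔF/F(t) = (F(t) − F_base) / (F_NH4Cl − F_base)`.
* **`simulate`** — seeded generators of synthetic micrographs, channel
  triplets and release stacks with exact ground truth (puncta layout, true
  label maps, true ΔF/F kinetics), used by the entire test suite.

## Worked example

```python
import synedgews as s
from synedgews import fixtures
from synedgews.preprocess import preprocess

cfg = s.AcquisitionConfig()          # 8 µm camera px, 60x, 2x2 binning,
                                     # puncta 0.8-3.2 µm, 2 iterations
img, truth = s.generate_puncta_image(fixtures.heterogeneous(), seed=1)
res = s.segment(preprocess(img, cfg), cfg)
rep = s.evaluate(truth.label_map, res, tolerance_px=2.0)
print(f"{res.n_rois} ROIs, F1={rep.f1:.3f}, dice={rep.dice:.3f}, "
      f"bf={rep.bf_score:.3f}")
```

prints

```
30 ROIs, F1=1.000, dice=0.598, bf=0.993
```

30 detected puncta on a field of 15 bright and 15 four-fold dimmer puncta
under a linear illumination gradient: every punctum matched one-to-one
(object F1 = 1), contours agree within the 2 px boundary tolerance
(bf ≈ 0.99), while the pixel-level dice ≈ 0.6 reflects that the refined
contours are tighter than the generous 2σ ground-truth discs.

The same pipeline is available from the shell:

```bash
synedgews simulate image --seed 1 --out sim/
synedgews segment --image sim/image.tif --algo synedgews --out seg/
synedgews benchmark --synthetic 10 --seed 1 --out bench/
```

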