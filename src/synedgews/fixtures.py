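"""Canonical synthetic study conditions.

Each function returns the :class:`~synedgews.simulate.SynthParams` of one
benchmark condition used throughout the test-suite and the reproduction
script.  They are fixed study conditions, not tuning knobs.

* ``well_separated`` — 30 isolated Gaussian puncta (σ 1.5–2.5 px, peak SNR
  15–30): the detection / localization benchmark.
* ``heterogeneous`` — bimodal punctum amplitudes (bright = 4 × dim) on a
  linear uneven-illumination plane at high SNR: probes the iterative
  threshold schedule and the gradient approach's illumination robustness.
* ``touching_pairs`` — every punctum a member of a 2.5 σ-spaced pair with
  σ 2.0–2.5 px, so pair separations (5–6.25 px) stay above the minimum
  expected punctum diameter: probes watershed splitting.
* ``with_soma`` — puncta plus one very bright flat cell-body disc: probes
  bright-region retouching.
* ``release_stack`` / ``bleach_stack`` — cumulative-release time lapse
  (two stimulus steps, alkalization plateau) with and without strong
  photobleaching: probe trace extraction, normalization and bleach fitting.
"""

from __future__ import annotations

from .simulate import SynthParams

__all__ = ["well_separated", "heterogeneous", "touching_pairs", "with_soma",
           "release_stack", "bleach_stack"]


def well_separated(**overrides) -> SynthParams:
    return SynthParams(**overrides)


def heterogeneous(**overrides) -> SynthParams:
    defaults = dict(
        amplitude_values=(300.0, 75.0),
        sigma_range=(2.0, 2.0),
        noise_sd=3.0,
        illumination_gradient=80.0,
    )
    defaults.update(overrides)
    return SynthParams(**defaults)


def touching_pairs(**overrides) -> SynthParams:
    defaults = dict(
        n_puncta=20,
        fraction_touching=1.0,
        sigma_range=(2.0, 2.5),
        min_separation_px=20.0,
    )
    defaults.update(overrides)
    return SynthParams(**defaults)


def with_soma(**overrides) -> SynthParams:
    defaults = dict(
        n_soma=1,
        soma_radius=30.0,
        soma_amplitude=2000.0,
    )
    defaults.update(overrides)
    return SynthParams(**defaults)


def release_stack(**overrides) -> SynthParams:
    defaults = dict(
        n_puncta=50,
        shape=(192, 192),
        min_separation_px=12.0,
        n_frames=260,
        baseline_visible_fraction=0.2,
        stim_steps=((40, 2, 0.2), (100, 45, 0.8)),
        nh4cl_frames=(230, 260),
        bleach_tau=600.0,
    )
    defaults.update(overrides)
    return SynthParams(**defaults)


def bleach_stack(**overrides) -> SynthParams:
    defaults = dict(
        n_puncta=50,
        shape=(192, 192),
        min_separation_px=12.0,
        n_frames=260,
        baseline_visible_fraction=0.6,
        stim_steps=(),
        nh4cl_frames=(230, 260),
        bleach_tau=150.0,
        noise_sd=5.0,
    )
    defaults.update(overrides)
    return SynthParams(**defaults)
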