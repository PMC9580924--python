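import numpy as np
import pytest

from synedgews import AcquisitionConfig, ParameterError, RunConfig
from synedgews.imgsegrout import (ImageStack, TraceSet, analyze_stack,
                                  extract_traces, fit_bleach_tau,
                                  make_template, normalize_traces,
                                  postprocess_traces, run_imgsegrout)
from synedgews.segment import SegmentationResult
from synedgews.simulate import generate_stack
from synedgews import fixtures


def seg_from_map(label_map):
    return SegmentationResult.from_label_map(np.asarray(label_map))


def constant_stack(value=5.0, n=6, shape=(32, 32)):
    return ImageStack(frames=np.full((n,) + shape, value))


class TestMakeTemplate:
    def test_mean_of_two_frames(self, run_cfg):
        a = np.zeros((16, 16))
        b = np.ones((16, 16))
        a[4:8, 4:8] = 4.0
        b[4:8, 4:8] = 8.0
        stack = ImageStack(frames=np.stack([a, b]))
        template_mean = make_template(stack, (0, 2), run_cfg)
        # preprocess is deterministic, so the template equals the
        # preprocessed pixelwise mean
        from synedgews.preprocess import preprocess
        assert np.array_equal(template_mean,
                              preprocess((a + b) / 2, run_cfg.acquisition))

    def test_single_frame_selection(self, run_cfg):
        stack = constant_stack()
        assert not make_template(stack, 0, run_cfg).any()

    def test_averaging_shrinks_noise(self, run_cfg, rng):
        scene = np.zeros((64, 64))
        scene[30:34, 30:34] = 50.0
        frames = scene[None] + rng.normal(0, 5.0, (64, 64, 64))
        stack = ImageStack(frames=frames)
        single = stack.frames[0]
        averaged = stack.frames.mean(axis=0)
        assert (averaged - scene).std() < 0.3 * (single - scene).std()

    def test_out_of_range_rejected(self, run_cfg):
        with pytest.raises(ParameterError):
            make_template(constant_stack(), 99, run_cfg)


class TestExtractTraces:
    def test_constant_stack_constant_traces(self):
        stack = constant_stack(value=7.0)
        labels = np.zeros((32, 32), np.int32)
        labels[4:8, 4:8] = 1
        ts = extract_traces(stack, seg_from_map(labels))
        assert np.allclose(ts.raw, 7.0)
        assert np.allclose(ts.background, 7.0)

    def test_ramping_roi_trace(self):
        frames = np.zeros((3, 16, 16))
        for t, v in enumerate((1.0, 2.0, 3.0)):
            frames[t, 5:7, 5:7] = v
        labels = np.zeros((16, 16), np.int32)
        labels[5:7, 5:7] = 1
        ts = extract_traces(ImageStack(frames=frames), seg_from_map(labels))
        assert np.allclose(ts.raw[0], [1.0, 2.0, 3.0])

    def test_background_local_to_non_roi_pixels(self, rng):
        frames = rng.uniform(0, 1, (4, 32, 32))
        labels = np.zeros((32, 32), np.int32)
        labels[10:14, 10:14] = 1
        seg = seg_from_map(labels)
        ts1 = extract_traces(ImageStack(frames=frames), seg)
        perturbed = frames.copy()
        perturbed[:, 25:30, 25:30] += 50.0   # far from the ROI
        ts2 = extract_traces(ImageStack(frames=perturbed), seg)
        assert np.array_equal(ts1.raw, ts2.raw)
        assert not np.array_equal(ts1.background, ts2.background)

    def test_shape_mismatch_rejected(self):
        labels = np.zeros((8, 8), np.int32)
        labels[0, 0] = 1
        with pytest.raises(ParameterError):
            extract_traces(constant_stack(shape=(16, 16)), seg_from_map(labels))


class TestPostprocess:
    def test_identity_settings_passthrough(self):
        cfg = RunConfig(smoothing_window=1)
        ts = TraceSet(raw=np.arange(12, dtype=float).reshape(2, 6),
                      background=np.zeros(6))
        out = postprocess_traces(ts, cfg)
        assert np.array_equal(out.processed, ts.raw)

    def test_constant_background_subtracted(self):
        cfg = RunConfig(smoothing_window=1)
        ts = TraceSet(raw=np.full((1, 8), 10.0), background=np.full(8, 4.0))
        out = postprocess_traces(ts, cfg)
        assert np.allclose(out.processed, 6.0)

    def test_smoothing_is_centered_moving_average(self):
        cfg = RunConfig(smoothing_window=3)
        ts = TraceSet(raw=np.array([[0., 0., 3., 0., 0.]]), background=np.zeros(5))
        out = postprocess_traces(ts, cfg)
        assert np.allclose(out.processed[0], [0., 1., 1., 1., 0.])

    def test_bleach_correction_flattens_known_decay(self):
        tau_true = 120.0
        t = np.arange(200, dtype=float)
        raw = 50.0 * np.exp(-t / tau_true)[None, :].repeat(3, axis=0)
        cfg = RunConfig(acquisition=AcquisitionConfig(bleach_correct_enabled=True),
                        smoothing_window=1, baseline_frames=(0, 200),
                        nh4cl_frames=(200, 201))
        out = postprocess_traces(TraceSet(raw=raw, background=np.zeros(200)), cfg,
                                 baseline_frames=(0, 200))
        assert np.allclose(out.processed, 50.0, rtol=0.01)
        assert out.bleach_tau[0] == pytest.approx(tau_true, rel=0.10)

    def test_tau_fit_recovers_ground_truth(self):
        t = np.arange(150, dtype=float)
        assert fit_bleach_tau(30 * np.exp(-t / 80.0), (0, 150)) == pytest.approx(80.0, rel=1e-6)

    def test_degenerate_baseline_skipped_gracefully(self):
        cfg = RunConfig(acquisition=AcquisitionConfig(bleach_correct_enabled=True),
                        smoothing_window=1)
        raw = np.zeros((1, 30))
        out = postprocess_traces(TraceSet(raw=raw, background=np.zeros(30)), cfg,
                                 baseline_frames=(0, 20))
        assert np.isnan(out.bleach_tau[0])
        assert np.array_equal(out.processed, raw)


class TestNormalize:
    def make_traces(self, values):
        arr = np.asarray(values, dtype=float)[None, :]
        return TraceSet(raw=arr, background=np.zeros(arr.shape[1]), processed=arr)

    def test_caption_formula_value(self):
        ts = self.make_traces([100.0] * 4 + [200.0] * 4 + [300.0] * 4)
        out = normalize_traces(ts, (0, 4), (8, 12))
        assert out.normalized[0, 5] == pytest.approx(0.5)

    def test_endpoints_map_to_zero_and_one(self):
        ts = self.make_traces([100.0] * 4 + [150.0] * 4 + [300.0] * 4)
        out = normalize_traces(ts, (0, 4), (8, 12))
        assert out.normalized[0, :4] == pytest.approx(0.0)
        assert out.normalized[0, 8:] == pytest.approx(1.0)

    def test_affine_invariance_of_normalization(self, rng):
        base = rng.uniform(1, 2, 30)
        base[20:] += 5.0
        ts1 = self.make_traces(base)
        ts2 = self.make_traces(3.0 * base + 11.0)
        out1 = normalize_traces(ts1, (0, 10), (20, 30))
        out2 = normalize_traces(ts2, (0, 10), (20, 30))
        assert np.allclose(out1.normalized, out2.normalized)

    def test_zero_dynamic_range_flagged_invalid(self):
        ts = self.make_traces([5.0] * 12)
        out = normalize_traces(ts, (0, 4), (8, 12))
        assert not out.valid[0]
        assert np.isnan(out.mean_curve).all()

    def test_overlapping_ranges_rejected(self):
        ts = self.make_traces([1.0] * 12)
        with pytest.raises(ParameterError):
            normalize_traces(ts, (0, 6), (4, 12))


class TestStackPipeline:
    def test_segmentation_happens_once_on_template(self):
        params = fixtures.release_stack()
        frames, truth = generate_stack(params, seed=1)
        cfg = RunConfig(template_selection=truth.nh4cl_frames,
                        baseline_frames=truth.baseline_frames,
                        nh4cl_frames=truth.nh4cl_frames)
        res = analyze_stack(ImageStack(frames=frames), cfg)
        template = make_template(ImageStack(frames=frames), truth.nh4cl_frames, cfg)
        from synedgews.segment import segment
        assert np.array_equal(res.seg.label_map,
                              segment(template, cfg.acquisition).label_map)
        assert res.traces.raw.shape == (res.seg.n_rois, params.n_frames)

    def test_recovered_traces_match_truth(self):
        params = fixtures.release_stack()
        frames, truth = generate_stack(params, seed=2)
        cfg = RunConfig(acquisition=AcquisitionConfig(bleach_correct_enabled=True),
                        template_selection=truth.nh4cl_frames,
                        baseline_frames=truth.baseline_frames,
                        nh4cl_frames=truth.nh4cl_frames)
        res = analyze_stack(ImageStack(frames=frames), cfg)
        ts = res.traces
        errs = []
        for i, roi in enumerate(res.seg.rois):
            d = np.hypot(truth.centers[:, 0] - roi.centroid[0],
                         truth.centers[:, 1] - roi.centroid[1])
            if d.min() <= 2.0 and ts.valid[i]:
                errs.append(ts.normalized[i] - truth.level_curve)
        assert len(errs) >= 0.9 * params.n_puncta
        rmse = np.sqrt(np.mean(np.square(errs)))
        assert rmse < 0.05

    def test_batch_equals_single_runs(self, tmp_path, run_cfg):
        import tifffile

        params = fixtures.release_stack(n_puncta=20)
        cfg = RunConfig(template_selection=(232, 258), baseline_frames=(0, 40),
                        nh4cl_frames=(232, 258))
        paths, singles = [], []
        for seed in (1, 2):
            frames, _ = generate_stack(params, seed=seed)
            p = tmp_path / f"stack{seed}.tif"
            tifffile.imwrite(p, frames.astype(np.float32))
            paths.append(p)
            singles.append(analyze_stack(ImageStack(frames=frames.astype(np.float32).astype(float)), cfg))
        results, failed = run_imgsegrout(paths, cfg, out_dir=tmp_path / "out")
        assert not failed and len(results) == 2
        for got, want in zip(results, singles):
            assert np.array_equal(got.seg.label_map, want.seg.label_map)
            assert np.allclose(got.traces.normalized, want.traces.normalized,
                               equal_nan=True)
        assert (tmp_path / "out" / "stack1_normalized.csv").exists()
        assert (tmp_path / "out" / "config_echo.yaml").exists()
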