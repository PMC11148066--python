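"""Spot detection, region assignment, counting and intensity
normalization, checked against Monte-Carlo nulls and brute-force oracles."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from rootlapse.puncta import (
    assign_regions,
    bin_timepoints,
    correct_and_normalize_intensity,
    count_and_density,
    detect_puncta,
)
from rootlapse.simulate import (
    PunctaSimParams,
    RegionSet,
    background_roi_for,
    generate_puncta_timelapse,
)
from rootlapse import puncta as rpuncta

PX = 0.29


def _spot_frame(centers, peak=3000.0, sigma_um=1.0, background=100.0, noise_sd=30.0,
                shape=(300, 300), seed=0):
    rng = np.random.default_rng(seed)
    frame = np.full(shape, background)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for cx, cy in centers:
        frame += peak * np.exp(
            -(((xx - cx / PX) ** 2 + (yy - cy / PX) ** 2) * PX**2) / (2 * sigma_um**2)
        )
    if noise_sd:
        frame = frame + rng.normal(0, noise_sd, shape)
    return np.clip(frame, 0, 65535)


class TestDetectPuncta:
    def test_false_positive_rate_under_null_below_point_one_per_frame(self):
        rng = np.random.default_rng(77)
        n_fp = 0
        for _ in range(100):
            blank = np.clip(rng.normal(100, 30, (250, 250)), 0, 65535)
            n_fp += len(detect_puncta(blank, PX))
        assert n_fp / 100 < 0.1

    def test_high_snr_recall_and_precision(self):
        rng = np.random.default_rng(5)
        centers = []
        while len(centers) < 50:  # well-separated random spots
            c = (rng.uniform(6, 80), rng.uniform(6, 80))
            if all((c[0] - o[0]) ** 2 + (c[1] - o[1]) ** 2 > 36 for o in centers):
                centers.append(c)
        frame = _spot_frame(centers, seed=9)
        det = detect_puncta(frame, PX)
        match_r = 2 * PX
        matched = 0
        for cx, cy in centers:
            d = np.hypot(det.x_um - cx, det.y_um - cy)
            if (d <= match_r).any():
                matched += 1
        recall = matched / len(centers)
        precision = matched / max(len(det), 1)
        assert recall >= 0.98
        assert precision >= 0.98

    def test_centroid_and_mean_intensity_of_single_spot(self):
        frame = _spot_frame([(30.0, 40.0)], noise_sd=0.0)
        det = detect_puncta(frame, PX)
        assert len(det) == 1
        assert det.x_um.iloc[0] == pytest.approx(30.0, abs=PX)
        assert det.y_um.iloc[0] == pytest.approx(40.0, abs=PX)
        assert 100.0 < det.mean_intensity.iloc[0] < 100.0 + 3000.0

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            detect_puncta(np.zeros((10, 10)), PX, scale_um=0.0)

    def test_detection_invariant_to_intensity_gain(self):
        frame = _spot_frame([(20.0, 20.0), (50.0, 60.0)], seed=3)
        d1 = detect_puncta(frame, PX)
        d2 = detect_puncta(frame * 7.5, PX)
        assert len(d1) == len(d2)
        pd.testing.assert_frame_equal(
            d1[["x_um", "y_um"]], d2[["x_um", "y_um"]]
        )


def _toy_regions():
    labels = np.zeros((40, 60), dtype=np.uint16)
    labels[:, 10:30] = 1
    labels[:, 30:50] = 2
    classes = {
        1: {"class": "hair", "area_um2": 100.0, "volume_um3": 1000.0, "cell_count": 2},
        2: {"class": "non_hair", "area_um2": 100.0, "volume_um3": 500.0, "cell_count": 2},
    }
    return RegionSet(labels=labels, classes=classes)


class TestAssignAndCount:
    def test_assignment_matches_bruteforce_point_in_mask(self):
        regions = _toy_regions()
        rng = np.random.default_rng(8)
        pts = pd.DataFrame(
            {
                "frame": 0,
                "x_um": rng.uniform(0, 59 * PX, 200),
                "y_um": rng.uniform(0, 39 * PX, 200),
                "mean_intensity": 1.0,
            }
        )
        out = assign_regions(pts, regions, PX)
        for _, row in out.iterrows():
            r = int(round(row.y_um / PX))
            c = int(round(row.x_um / PX))
            assert row.region_label == regions.labels[r, c]

    def test_boundary_pixel_assignment_deterministic(self):
        regions = _toy_regions()
        p = pd.DataFrame(
            {"frame": [0], "x_um": [30 * PX], "y_um": [5 * PX], "mean_intensity": [1.0]}
        )
        a = assign_regions(p, regions, PX)
        b = assign_regions(p, regions, PX)
        assert a.region_label.iloc[0] == b.region_label.iloc[0] == 2

    def test_density_and_per_cell_arithmetic(self):
        regions = _toy_regions()
        det = pd.DataFrame(
            {
                "frame": [0] * 8,
                "region_label": [1] * 8,
                "x_um": [3.0] * 8,
                "y_um": [3.0] * 8,
            }
        )
        table = count_and_density(det, regions, n_frames=1, use_volume=True)
        row = table[table.region_label == 1].iloc[0]
        assert row["count"] == 8
        assert row["density"] == pytest.approx(8.0)  # 8 per 1000 um^3
        assert row["per_cell"] == pytest.approx(4.0)
        empty = table[table.region_label == 2].iloc[0]
        assert empty["count"] == 0
        assert empty["density"] == 0.0

    def test_count_conservation_across_regions_and_excluded(self, tiny_puncta_params):
        stack, regions, _ = generate_puncta_timelapse(tiny_puncta_params)
        detections, table = rpuncta.analyze_puncta_stack(stack, regions)
        for k in range(stack.n_frames):
            det_k = detections[detections.frame == k]
            counted = table[table.frame == k]["count"].sum()
            excluded = (det_k.region_class == "excluded").sum()
            assert counted + excluded == len(det_k)


class TestIntensityNormalization:
    def test_constant_intensity_gives_flat_unit_series(self, tiny_puncta_params):
        p = replace(tiny_puncta_params, noise_sd=0.0)
        stack, regions, _ = generate_puncta_timelapse(p)
        detections, _ = rpuncta.analyze_puncta_stack(stack, regions)
        series = correct_and_normalize_intensity(
            detections, stack, background_roi_for(p)
        )
        assert series.normalized_intensity.iloc[0] == 1.0
        assert np.allclose(series.normalized_intensity, 1.0, atol=0.05)

    def test_background_drift_cancels(self):
        # constant spot over a background ramping +10 per frame
        frames = []
        for k in range(5):
            f = _spot_frame([(30.0, 40.0)], background=100.0 + 10 * k, noise_sd=0.0)
            frames.append(f)
        stack_px = np.stack(frames)[:, None]
        from rootlapse.stack import ImageStack

        stack = ImageStack(
            pixels=stack_px, pixel_size_um=PX, frame_interval_min=15.0
        )
        det = []
        for k in range(5):
            d = detect_puncta(stack.frame(k), PX)
            d.insert(0, "frame", k)
            det.append(d)
        det = pd.concat(det, ignore_index=True)
        from rootlapse.diffusion import RoiSpec

        roi = RoiSpec(kind="circle", role="background", center_um=(75.0, 75.0),
                      diameter_um=12.0)
        series = correct_and_normalize_intensity(det, stack, roi)
        assert np.allclose(series.normalized_intensity, 1.0, atol=0.02)

    def test_decay_regime_reaches_quarter_intensity_after_two_half_lives(self):
        from rootlapse.experiments import run_intensity_decay_study

        series = run_intensity_decay_study(seed=1)
        at_480 = series[np.isclose(series.t_min, 480.0)]
        assert len(at_480) == 1
        assert at_480.normalized_intensity.iloc[0] == pytest.approx(0.25, abs=0.05)

    def test_nonpositive_first_point_rejected(self):
        from rootlapse.stack import ImageStack
        from rootlapse.diffusion import RoiSpec

        pixels = np.full((2, 1, 60, 60), 500.0)
        stack = ImageStack(pixels=pixels, pixel_size_um=PX, frame_interval_min=15.0)
        det = pd.DataFrame(
            {"frame": [0, 1], "mean_intensity": [400.0, 400.0], "x_um": 1.0, "y_um": 1.0}
        )
        roi = RoiSpec(kind="circle", role="background", center_um=(8.0, 8.0),
                      diameter_um=10.0)
        with pytest.raises(ValueError, match="normalization undefined"):
            correct_and_normalize_intensity(det, stack, roi)


class TestBinning:
    def test_window_rule(self):
        table = pd.DataFrame(
            {
                "frame": [0, 1, 2, 3],
                "region_label": [1, 1, 1, 1],
                "region_class": ["hair"] * 4,
                "count": [2, 4, 6, 8],
                "density": [0.2, 0.4, 0.6, 0.8],
                "per_cell": [1.0, 2.0, 3.0, 4.0],
            }
        )
        times = np.array([0.0, 10.0, 20.0, 28.0])
        out = bin_timepoints(table, times, bin_min=15.0)
        assert sorted(out.bin_start_min) == [0.0, 15.0]
        b0 = out[out.bin_start_min == 0.0].iloc[0]
        assert b0["mean_count"] == pytest.approx(3.0)  # frames 0, 10 min
        b1 = out[out.bin_start_min == 15.0].iloc[0]
        assert b1["mean_count"] == pytest.approx(7.0)  # frames 20, 28 min

    def test_single_region_bin_reports_missing_se(self):
        table = pd.DataFrame(
            {
                "frame": [0],
                "region_label": [1],
                "region_class": ["hair"],
                "count": [5],
                "density": [0.5],
                "per_cell": [2.5],
            }
        )
        out = bin_timepoints(table, np.array([0.0]), bin_min=15.0)
        assert math.isnan(out.se_count.iloc[0])

    def test_uniform_counts_mean_preserved_by_binning(self):
        table = pd.DataFrame(
            {
                "frame": list(range(6)) * 2,
                "region_label": [1] * 6 + [2] * 6,
                "region_class": ["hair"] * 12,
                "count": [5] * 12,
                "density": [0.5] * 12,
                "per_cell": [2.5] * 12,
            }
        )
        out = bin_timepoints(table, np.arange(6) * 10.0, bin_min=15.0)
        assert np.allclose(out.mean_count, 5.0)
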