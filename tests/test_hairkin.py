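"""Tip tracking and kinetics extraction, checked against brute-force
rasterization, global-assignment matching and constructed curves."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rootlapse import hairkin
from rootlapse.hairkin import (
    GrowthCurve,
    HairTrack,
    TipCandidate,
    build_growth_curve,
    detect_tips,
    extract_kinetics,
    link_tracks,
    segment_foreground,
    summarize_condition,
)
from rootlapse.simulate import HairSimParams, generate_hair_timelapse, preset

from oracles import match_tracks_to_truth, rasterize_tube


def _single_hair_frame(length_um=80.0, angle_deg=90.0, noise_sd=30.0, seed=4):
    p = HairSimParams(
        n_hairs=1,
        rate_mean=length_um / 100.0,
        rate_sd=1e-9,
        duration_mean=100.0,
        duration_sd=1e-9,
        initiation_window=(0.0, 0.0),
        emergence_angle_deg=(angle_deg, angle_deg),
        noise_sd=noise_sd,
        record_duration_min=104.0,
        seed=seed,
    )
    stack, truth = generate_hair_timelapse(p)
    return stack, truth, p


class TestSegmentForeground:
    def test_noise_only_frame_gives_empty_masks(self, rng):
        frame = rng.normal(100, 5, (200, 300))
        hair, root = segment_foreground(frame, pixel_size_um=0.92)
        assert hair.sum() == 0

    def test_root_band_alone_yields_empty_hair_mask(self, rng):
        frame = rng.normal(100, 10, (200, 300))
        frame[:, :100] = 3000.0
        hair, root = segment_foreground(frame, pixel_size_um=0.92)
        assert hair.sum() == 0
        assert root[:, :98].all()

    def test_hair_components_overlap_ground_truth_tubes(self):
        p = replace(
            preset("control", seed=31),
            n_hairs=5,
            initiation_window=(0.0, 1.0),
            record_duration_min=160.0,
        )
        stack, truth = generate_hair_timelapse(p)
        frame = stack.frame(stack.n_frames - 1)
        hair_mask, _ = segment_foreground(frame, p.pixel_size_um)
        from skimage.measure import label as cc_label

        lab, n = cc_label(hair_mask, connectivity=2, return_num=True)
        assert n == 5
        t_last = stack.times_min()[-1]
        for h in truth.hairs:
            L = min(max(h["rate"] * (t_last - h["t_init"]), 0), h["final_length"])
            th = math.radians(h["angle_deg"])
            tip = (
                h["base_x_um"] + L * math.sin(th),
                h["base_y_um"] - L * math.cos(th),
            )
            tube = rasterize_tube(
                frame.shape,
                (h["base_x_um"], h["base_y_um"]),
                tip,
                p.hair_diameter_um / 2,
                p.pixel_size_um,
            )
            tube &= ~(
                np.arange(frame.shape[1])[None, :] * p.pixel_size_um
                < h["base_x_um"]
            )
            inter = (hair_mask & tube).sum()
            union = (hair_mask & tube).sum() + (tube & ~hair_mask).sum()
            # Jaccard vs this hair's own tube, restricted to the tube's
            # neighbourhood (other hairs are elsewhere in the frame)
            jac = inter / max((tube | (hair_mask & tube)).sum(), 1)
            assert inter / tube.sum() >= 0.7
            assert jac >= 0.7


class TestDetectTips:
    def test_straight_tube_tip_within_two_pixels_of_truth(self):
        stack, truth, p = _single_hair_frame(length_um=80.0)
        frame = stack.frame(stack.n_frames - 1)
        hair, root = segment_foreground(frame, p.pixel_size_um)
        tips, qc = detect_tips(hair, root, p.pixel_size_um)
        assert len(tips) == 1
        h = truth.hairs[0]
        tip_x = h["base_x_um"] + h["final_length"]  # 90 degree emergence
        d = math.hypot(tips[0].x_um - tip_x, tips[0].y_um - h["base_y_um"])
        assert d <= 2 * p.pixel_size_um + p.hair_diameter_um / 2

    def test_zero_length_hair_gives_no_candidate(self):
        p = HairSimParams(
            n_hairs=1,
            initiation_window=(500.0, 500.0),
            record_duration_min=16.0,
            seed=6,
        )
        stack, _ = generate_hair_timelapse(p)
        frame = stack.frame(0)
        hair, root = segment_foreground(frame, p.pixel_size_um)
        tips, _ = detect_tips(hair, root, p.pixel_size_um)
        assert tips == []

    def test_touching_hairs_flagged_ambiguous(self):
        # two tubes sharing a base region form one component with two far
        # endpoints
        px = 0.92
        frame = np.full((200, 400), 100.0)
        frame[:, :30] = 3000.0
        tube1 = rasterize_tube((200, 400), (27.6, 92.0), (180.0, 60.0), 4.5, px)
        tube2 = rasterize_tube((200, 400), (27.6, 96.0), (180.0, 130.0), 4.5, px)
        frame[tube1 | tube2] = 3000.0
        hair, root = segment_foreground(frame, px)
        tips, qc = detect_tips(hair, root, px)
        assert qc["ambiguous"] >= 1
        assert all(t.ambiguous for t in tips)

    def test_geodesic_length_reported_for_straight_tube(self):
        stack, truth, p = _single_hair_frame(length_um=80.0)
        frame = stack.frame(stack.n_frames - 1)
        hair, root = segment_foreground(frame, p.pixel_size_um)
        tips, _ = detect_tips(hair, root, p.pixel_size_um)
        assert tips[0].root_distance_um == pytest.approx(80.0, abs=8.0)


class TestLinkTracks:
    def test_single_hair_yields_single_full_track(self):
        stack, truth, p = _single_hair_frame()
        proj_times = stack.times_min()
        tips_per_frame = []
        for k in range(stack.n_frames):
            hair, root = segment_foreground(stack.frame(k), p.pixel_size_um)
            tips, _ = detect_tips(hair, root, p.pixel_size_um)
            tips_per_frame.append(tips)
        tracks = link_tracks(tips_per_frame, proj_times)
        long_tracks = [t for t in tracks if len(t.samples) > 3]
        assert len(long_tracks) == 1
        n_detectable = sum(1 for tl in tips_per_frame if tl)
        assert len(long_tracks[0].samples) == n_detectable

    def test_preset_hairs_match_ground_truth_one_to_one(self):
        p = replace(preset("control", seed=41), n_hairs=12)
        stack, truth = generate_hair_timelapse(p)
        tracks, _ = hairkin.analyze_stack(stack)
        matches = match_tracks_to_truth(
            tracks, truth.hairs, p.frame_interval_min
        )
        assert len(matches) >= 0.95 * len(truth.hairs)

    def test_gap_tolerance_bridges_missed_frames(self):
        tips = [
            [TipCandidate(10.0, 10.0, 5.0)],
            [],
            [],
            [TipCandidate(13.0, 10.0, 8.0)],
        ]
        tracks = link_tracks(tips, np.array([0.0, 8.0, 16.0, 24.0]), 3.0)
        assert len(tracks) == 1
        assert len(tracks[0].samples) == 2


class TestGrowthCurve:
    def test_straight_growth_gives_linear_curve(self):
        track = HairTrack(
            hair_id=0,
            base_point=(0.0, 0.0),
            samples=[(8.0 * k, 8.0 * k, 50.0) for k in range(6)],
        )
        curve = build_growth_curve(track)
        for k, (t, L) in enumerate(curve.points):
            assert t == pytest.approx(8.0 * k)
            assert L == pytest.approx(8.0 * k)

    def test_curve_defined_on_observed_times_only(self):
        track = HairTrack(
            hair_id=0,
            base_point=(0.0, 0.0),
            samples=[(0.0, 0.0, 0.0), (8.0, 8.0, 0.0), (32.0, 32.0, 0.0)],
        )
        curve = build_growth_curve(track)
        assert [pt[0] for pt in curve.points] == [0.0, 8.0, 32.0]

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(-5, 5, allow_nan=False), st.floats(-5, 5, allow_nan=False)
            ),
            min_size=2,
            max_size=30,
        )
    )
    def test_curves_are_always_non_decreasing(self, offsets):
        samples = [
            (8.0 * k, 100.0 + dx, 50.0 + dy) for k, (dx, dy) in enumerate(offsets)
        ]
        curve = build_growth_curve(
            HairTrack(hair_id=0, base_point=(100.0, 50.0), samples=samples)
        )
        lengths = [pt[1] for pt in curve.points]
        assert all(b >= a for a, b in zip(lengths, lengths[1:]))


def _ideal_curve(lag_min=40.0, slope=1.0, grow_min=120.0, total_min=240.0, dt=8.0):
    pts = []
    t = 0.0
    while t <= total_min:
        L = slope * min(max(t - lag_min, 0.0), grow_min)
        pts.append((t, L))
        t += dt
    return GrowthCurve(hair_id=0, points=pts)


class TestExtractKinetics:
    def test_ideal_piecewise_linear_curve(self):
        rec = extract_kinetics(_ideal_curve())
        assert rec["growth_rate_um_per_min"] == pytest.approx(1.0, abs=0.1)
        assert rec["duration_h"] == pytest.approx(2.0, abs=8.0 / 60)
        assert rec["final_length_um"] == pytest.approx(120.0, abs=8.0)
        assert not rec["truncated"]
        assert rec["qc"] == "ok"

    def test_jitter_only_track_classified_non_growing(self, rng):
        # stationary tip with +-0.5 px localization jitter
        px = 0.92
        samples = [
            (8.0 * k, 100.0 + rng.uniform(-0.5, 0.5) * px, 50.0 + rng.uniform(-0.5, 0.5) * px)
            for k in range(40)
        ]
        curve = build_growth_curve(
            HairTrack(hair_id=0, base_point=(100.0, 50.0), samples=samples)
        )
        assert curve.points[-1][1] <= 40 * px  # bounded by per-frame jitter
        rec = extract_kinetics(curve)
        assert rec["qc"] == "non_growing"
        assert rec["duration_h"] == 0.0

    def test_curve_still_rising_at_record_end_flagged_truncated(self):
        pts = [(8.0 * k, 8.0 * k) for k in range(20)]
        rec = extract_kinetics(GrowthCurve(hair_id=0, points=pts))
        assert rec["truncated"]

    def test_invariant_to_time_offset_and_rigid_motion(self):
        base = [(8.0 * k, 0.92 * 8 * k, 50.0) for k in range(30)]
        rec0 = extract_kinetics(
            build_growth_curve(HairTrack(0, (0.0, 50.0), list(base)))
        )
        # time offset
        shifted = [(t + 160.0, x, y) for t, x, y in base]
        rec_t = extract_kinetics(
            build_growth_curve(HairTrack(0, (0.0, 50.0), shifted))
        )
        # rotation by 35 degrees + translation
        th = math.radians(35)
        rot = [
            (
                t,
                200.0 + x * math.cos(th) - y * math.sin(th),
                300.0 + x * math.sin(th) + y * math.cos(th),
            )
            for t, x, y in base
        ]
        rec_r = extract_kinetics(build_growth_curve(HairTrack(0, (0.0, 0.0), rot)))
        for key in ("final_length_um", "growth_rate_um_per_min", "duration_h"):
            assert rec_t[key] == pytest.approx(rec0[key], rel=1e-9)
            assert rec_r[key] == pytest.approx(rec0[key], rel=1e-6)

    def test_rate_duration_length_self_consistency(self):
        rec = extract_kinetics(_ideal_curve(slope=0.9))
        span = rec["growth_rate_um_per_min"] * rec["duration_h"] * 60
        # grown length between start and stop should match rate x duration
        assert abs(span - 0.9 * 120.0) <= 2 * 8.0 * rec["growth_rate_um_per_min"]


class TestSummaries:
    def test_mean_and_se_arithmetic(self):
        import pandas as pd

        rec = pd.DataFrame(
            {
                "group": ["a"] * 3 + ["b"] * 3,
                "final_length_um": [100.0, 110.0, 90.0, 230.0, 230.0, 230.0],
                "growth_rate_um_per_min": [1.0] * 6,
                "duration_h": [2.0] * 6,
                "truncated": [False] * 6,
                "qc": ["ok"] * 6,
            }
        )
        out = summarize_condition(rec, reference_group="a")
        row = out[(out.group == "a") & (out.metric == "final_length_um")].iloc[0]
        assert row["mean"] == pytest.approx(100.0)
        assert row["se"] == pytest.approx(5.7735, abs=1e-3)
        fold = out[(out.group == "b") & (out.metric == "final_length_um")].iloc[0]
        assert fold["fold_change"] == pytest.approx(2.3)

    def test_truncated_records_excluded(self):
        import pandas as pd

        rec = pd.DataFrame(
            {
                "group": ["a"] * 4,
                "final_length_um": [100.0, 100.0, 100.0, 999.0],
                "growth_rate_um_per_min": [1.0] * 4,
                "duration_h": [2.0] * 4,
                "truncated": [False, False, False, True],
                "qc": ["ok"] * 4,
            }
        )
        out = summarize_condition(rec)
        row = out[out.metric == "final_length_um"].iloc[0]
        assert row["mean"] == pytest.approx(100.0)
        assert row["n"] == 3
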