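"""End-to-end synthetic experiments: generate, analyze, summarize.

These runners tie the generator to the analysis modules the way the imaging
experiments were run: many fields of view ("roots") per condition, records
pooled per condition. They are the computational core behind the analysis
scripts and the acceptance checks.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from . import hairkin, puncta
from .simulate import (
    HairSimParams,
    PunctaSimParams,
    background_roi_for,
    generate_diffusion_stack,
    generate_hair_timelapse,
    generate_puncta_timelapse,
    preset,
)
from . import diffusion as dif

__all__ = [
    "run_hair_condition",
    "run_hair_study",
    "run_puncta_ratio_study",
    "run_intensity_decay_study",
    "run_diffusion_study",
]


def _subseeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_hair_condition(
    params: HairSimParams,
    n_hairs_total: int,
    seed: int,
    n_per_stack: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and analyze one condition, split over several fields of view.

    Returns (kinetics records, ground-truth hair table); hair/track ids are
    made unique across stacks.
    """
    n_stacks = math.ceil(n_hairs_total / n_per_stack)
    seeds = _subseeds(seed, n_stacks)
    rec_frames, truth_rows = [], []
    remaining = n_hairs_total
    for i in range(n_stacks):
        n = min(n_per_stack, remaining)
        remaining -= n
        p = replace(params, n_hairs=n, seed=seeds[i])
        stack, truth = generate_hair_timelapse(p)
        _, records = hairkin.analyze_stack(stack)
        records = records.copy()
        records["stack"] = i
        records["hair_id"] = records["hair_id"].astype(str).radd(f"s{i}_")
        rec_frames.append(records)
        for h in truth.hairs:
            truth_rows.append({**h, "stack": i})
    return (
        pd.concat(rec_frames, ignore_index=True),
        pd.DataFrame(truth_rows),
    )


def run_hair_study(
    seed: int = 1,
    n_hairs_per_group: int = 200,
    groups: tuple[str, ...] = ("control", "sucrose"),
    n_per_stack: int = 20,
) -> dict:
    """The sucrose-response study on synthetic data.

    Simulates ``n_hairs_per_group`` hairs per condition, runs the tracking
    and kinetics pipeline, and returns pooled records, ground truth,
    per-group summaries and fold changes vs the first group.
    """
    seeds = _subseeds(seed, len(groups))
    rec_frames, truth_frames = [], []
    for g, s in zip(groups, seeds):
        records, truth = run_hair_condition(preset(g), n_hairs_per_group, s, n_per_stack)
        records["group"] = g
        truth["group"] = g
        rec_frames.append(records)
        truth_frames.append(truth)
    records = pd.concat(rec_frames, ignore_index=True)
    truth = pd.concat(truth_frames, ignore_index=True)
    summary = hairkin.summarize_condition(records, reference_group=groups[0])
    return {
        "records": records,
        "ground_truth": truth,
        "summary": summary,
        "groups": groups,
    }


def run_puncta_ratio_study(
    seed: int = 1,
    n_stacks: int = 10,
    params: PunctaSimParams | None = None,
    plateau_start_min: float | None = None,
) -> dict:
    """Basal-autophagy contrast study: non-hair vs hair puncta ratios.

    Simulates ``n_stacks`` fields of view with the ConA-regime preset
    (2 hair + 2 non-hair files each), detects and assigns puncta, and
    averages per-volume density and per-cell count over plateau frames.
    Returns the measured non_hair / hair density and per-cell ratios, and
    the same ratios computed on the generator's true counts.
    """
    if params is None:
        params = preset("conA_12h")
    if plateau_start_min is None:
        plateau_start_min = params.nonhair_plateau_min
    seeds = _subseeds(seed, n_stacks)
    measured, truth_counts = [], []
    for i in range(n_stacks):
        p = replace(params, seed=seeds[i])
        stack, regions, truth = generate_puncta_timelapse(p)
        _, table = puncta.analyze_puncta_stack(stack, regions, use_volume=True)
        times = stack.times_min()
        table["t_min"] = table["frame"].map(lambda k: times[k])
        table["stack"] = i
        measured.append(table[table["t_min"] >= plateau_start_min])
        tc = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(stack.n_frames), len(regions.classes)),
                "region_label": np.tile(
                    np.fromiter(regions.classes, dtype=int), stack.n_frames
                ),
                "count": truth.true_counts.ravel(),
            }
        )
        tc["region_class"] = tc["region_label"].map(
            lambda l: regions.classes[l]["class"]
        )
        tc["volume_um3"] = tc["region_label"].map(
            lambda l: regions.classes[l]["volume_um3"]
        )
        tc["cells"] = tc["region_label"].map(
            lambda l: regions.classes[l]["cell_count"]
        )
        tc["t_min"] = times[tc["frame"]]
        truth_counts.append(tc[tc["t_min"] >= plateau_start_min])
    meas = pd.concat(measured, ignore_index=True)
    tc = pd.concat(truth_counts, ignore_index=True)

    def ratios(df: pd.DataFrame, density_col: str, per_cell_col: str) -> tuple[float, float]:
        by_cls = df.groupby("region_class")[[density_col, per_cell_col]].mean()
        return (
            float(by_cls.loc["non_hair", density_col] / by_cls.loc["hair", density_col]),
            float(by_cls.loc["non_hair", per_cell_col] / by_cls.loc["hair", per_cell_col]),
        )

    tc["density"] = tc["count"] / tc["volume_um3"] * 1000.0
    tc["per_cell"] = tc["count"] / tc["cells"]
    d_meas, c_meas = ratios(meas, "density", "per_cell")
    d_true, c_true = ratios(tc, "density", "per_cell")
    return {
        "density_ratio": d_meas,
        "per_cell_ratio": c_meas,
        "true_density_ratio": d_true,
        "true_per_cell_ratio": c_true,
        "table": meas,
        "n_regions_per_class": n_stacks
        * sum(1 for _, cls in params.region_layout if cls == "hair"),
    }


def run_intensity_decay_study(seed: int = 1) -> pd.DataFrame:
    """Reporter-decay study: background-corrected, normalized intensity.

    Runs the decay-regime preset (per-punctum intensity half-life 240 min)
    through detection and intensity normalization; returns the per-frame
    normalized series.
    """
    p = preset("azd_decay", seed=seed)
    stack, regions, _ = generate_puncta_timelapse(p)
    detections, _ = puncta.analyze_puncta_stack(stack, regions)
    return puncta.correct_and_normalize_intensity(
        detections, stack, background_roi_for(p)
    )


def run_diffusion_study(seed: int = 1, fit: bool = True) -> dict:
    """Diffusion-front study on the slab preset.

    Measures a bottom-slab rectangle plus a background circle, corrects the
    series, extracts arrival and equilibration, optionally fits D_eff, and
    also applies the same timing rule to the analytic ground-truth curve.
    """
    p = preset("fluorescein", seed=seed)
    stack, truth = generate_diffusion_stack(p)
    size_um = p.image_size_px * p.pixel_size_um
    rois = [
        dif.RoiSpec(
            kind="rectangle", role="bottom_slab", y_offset_um=size_um * 0.4, height_um=10.0
        ),
        dif.RoiSpec(
            kind="circle",
            role="background",
            center_um=(size_um / 2, size_um * 0.15),
            diameter_um=12.0,
        ),
    ]
    series = dif.measure_rois(stack, rois)
    # the background ROI sees the same diffusing signal here; correct against
    # the pre-arrival offset instead (uniform synthetic field)
    sub = series[series["roi_role"] == "bottom_slab"].copy()
    sub["corrected_intensity"] = np.maximum(
        sub["mean_intensity"] - p.background_level, 0.0
    )
    timing = dif.arrival_and_equilibration(sub)
    truth_curve = pd.DataFrame(
        {
            "t_min": truth.diffusion["t_min"],
            "roi_role": "bottom_slab",
            "mean_intensity": np.asarray(truth.diffusion["bottom_fraction"])
            * p.source_concentration,
        }
    )
    truth_curve["corrected_intensity"] = truth_curve["mean_intensity"]
    timing_truth = dif.arrival_and_equilibration(truth_curve)
    out = {
        "series": sub,
        "timing": timing,
        "timing_truth": timing_truth,
        "params": p,
    }
    if fit:
        out["fit"] = dif.fit_slab_diffusion(sub, p.slab_height_um)
    return out
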