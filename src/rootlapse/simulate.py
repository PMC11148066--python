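"""Synthetic fluorescence time-lapses with known ground truth.

Three generators emulate the three imaging assays the pipeline analyzes:

* :func:`generate_hair_timelapse` — a root rendered as a bright band at the
  left image edge, with tubular root hairs that initiate at random times and
  elongate linearly at per-hair rates until a per-hair termination time
  (length(t) = clamp(rate * (t - t_init), 0, rate * duration)).
* :func:`generate_puncta_timelapse` — alternating epidermal cell files of
  hair / non-hair class accumulating diffraction-limited puncta at
  class-specific per-volume rates, rendered as 3-D Gaussians in a z-stack,
  with optional per-punctum intensity decay.
* :func:`generate_diffusion_stack` — the bottom plane of an agar slab whose
  signal follows the analytic fixed-source slab-diffusion solution.

Every generator returns the rendered stack together with the exact
per-object parameters it used (:class:`GroundTruth`), the reference for all
parameter-recovery tests. Identical parameters and seed give bit-identical
output. Named presets encode the measured parameter regimes of the assays
(control / sucrose hair growth; ConA-treated puncta accumulation with a
12-fold density contrast; a fluorescein-like diffusion run).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .diffusion import RoiSpec, slab_bottom_fraction
from .stack import ImageStack

__all__ = [
    "HairSimParams",
    "PunctaSimParams",
    "DiffusionSimParams",
    "GroundTruth",
    "RegionSet",
    "generate_hair_timelapse",
    "generate_puncta_timelapse",
    "generate_diffusion_stack",
    "preset",
    "PRESET_NAMES",
]

BIT_MAX = 65535


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class HairSimParams:
    """Parameters of the root-hair growth simulation.

    Rates are µm/min, durations minutes; per-hair rate and duration are
    drawn independently from normals truncated at 0, so ground-truth final
    length = rate * duration for every hair.
    """

    n_hairs: int = 20
    rate_mean: float = 0.75
    rate_sd: float = 0.15
    duration_mean: float = 132.0
    duration_sd: float = 30.0
    initiation_window: tuple[float, float] = (0.0, 240.0)
    hair_diameter_um: float = 9.0
    emergence_angle_deg: tuple[float, float] = (85.0, 95.0)
    root_width_um: float = 120.0
    hair_spacing_um: float = 40.0
    field_beyond_root_um: float = 560.0
    record_duration_min: float = 720.0
    frame_interval_min: float = 8.0
    pixel_size_um: float = 0.92
    background_level: float = 100.0
    signal_level: float = 3000.0
    noise_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_mean <= 0 or self.duration_mean <= 0:
            raise ValueError("rate_mean and duration_mean must be > 0")
        if self.n_hairs < 0:
            raise ValueError("n_hairs must be >= 0")


@dataclass
class PunctaSimParams:
    """Parameters of the cell-file puncta simulation.

    ``region_layout`` is a sequence of (width_um, class) cell files laid side
    by side along x; puncta rates are per 1000 µm³ of cell volume, volume =
    file area * class depth. Per frame, each region receives an independent
    Poisson number of puncta with mean lambda * volume * profile(t), placed
    uniformly in the file, rendered as 3-D Gaussians. ``accumulation`` gives
    the per-class count-vs-time shape: the hair class rises to plateau, the
    non-hair class lags then rises (plateau times in minutes).
    """

    region_layout: tuple[tuple[float, str], ...] = (
        (20.0, "hair"),
        (20.0, "non_hair"),
        (20.0, "hair"),
        (20.0, "non_hair"),
    )
    lambda_hair: float = 8.0 / 90.0  # puncta per 1000 um^3
    lambda_nonhair: float = 8.0 / 90.0 * 12.0
    cell_depth_hair_um: float = 30.0
    cell_depth_nonhair_um: float = 20.0
    file_length_um: float = 150.0
    cells_per_file: int = 2
    punctum_sigma_um: float = 1.0
    punctum_sigma_z_um: float = 2.5
    punctum_peak: float = 3000.0
    intensity_decay_halflife_min: float = math.inf
    hair_plateau_min: float = 300.0
    nonhair_lag_min: float = 240.0
    nonhair_plateau_min: float = 600.0
    flat_profile: bool = False
    duration_min: float = 720.0
    frame_interval_min: float = 15.0
    pixel_size_um: float = 0.29
    z_step_um: float = 2.5
    background_margin_um: float = 15.0
    field_width_um: float | None = None  # default: margin + layout width
    background_level: float = 100.0
    noise_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_hair < 0 or self.lambda_nonhair < 0:
            raise ValueError("puncta rates must be >= 0")
        if self.punctum_sigma_um <= 0:
            raise ValueError("punctum sigma must be > 0")

    def profile(self, cls: str, t_min: np.ndarray | float) -> np.ndarray | float:
        """Accumulation profile in [0, 1] for a cell-file class at time t."""
        t = np.asarray(t_min, dtype=float)
        if self.flat_profile:
            return np.ones_like(t)
        if cls == "hair":
            return np.clip(t / self.hair_plateau_min, 0.0, 1.0)
        rise = self.nonhair_plateau_min - self.nonhair_lag_min
        return np.clip((t - self.nonhair_lag_min) / rise, 0.0, 1.0)


@dataclass
class DiffusionSimParams:
    """Parameters of the slab-diffusion bottom-plane simulation."""

    d_eff_um2_s: float = 400.0
    slab_height_um: float = 4000.0
    source_concentration: float = 2000.0
    duration_min: float = 1000.0
    frame_interval_min: float = 5.0
    image_size_px: int = 64
    pixel_size_um: float = 1.14
    background_level: float = 100.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_eff_um2_s <= 0:
            raise ValueError("d_eff_um2_s must be > 0")
        if self.slab_height_um <= 0:
            raise ValueError("slab_height_um must be > 0")


@dataclass
class RegionSet:
    """Labelled cell-file regions: label image + per-label metadata.

    ``classes`` maps label -> {"class", "area_um2", "volume_um3",
    "cell_count"}; label 0 is unassigned background.
    """

    labels: np.ndarray
    classes: dict[int, dict]

    def class_of(self, label: int) -> str:
        return self.classes[label]["class"] if label in self.classes else "excluded"


@dataclass
class GroundTruth:
    """Exact per-object simulation parameters, for recovery tests."""

    hairs: list[dict] = field(default_factory=list)
    regions: list[dict] = field(default_factory=list)
    true_counts: np.ndarray | None = None  # (T, n_regions) true puncta counts
    puncta: list[dict] = field(default_factory=list)
    diffusion: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "hairs": self.hairs,
            "regions": self.regions,
            "puncta": self.puncta,
            "diffusion": self.diffusion,
        }
        if self.true_counts is not None:
            d["true_counts"] = self.true_counts.tolist()
        return d


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = ("control", "sucrose", "conA_12h", "azd_decay", "fluorescein")


def preset(name: str, seed: int = 0):
    """Named parameter sets encoding the measured assay regimes.

    control / sucrose: root-hair growth at 0.75 / 1.14 µm/min mean rate and
    2.2 h / 3.5 h mean duration. conA_12h: basal autophagy readout with a
    12-fold non-hair/hair puncta density contrast and a 1.5 hair:non-hair
    cell-volume ratio (hence an 8-fold per-cell count contrast). azd_decay:
    induced autophagy with reporter intensity decaying with a 240 min
    half-life. fluorescein: dye front through a 4 mm slab at 400 µm²/s.
    """
    if name == "control":
        return HairSimParams(rate_mean=0.75, duration_mean=2.2 * 60, seed=seed)
    if name == "sucrose":
        return HairSimParams(rate_mean=1.14, duration_mean=3.5 * 60, seed=seed)
    if name == "conA_12h":
        return PunctaSimParams(seed=seed)
    if name == "azd_decay":
        return PunctaSimParams(
            lambda_nonhair=8.0 / 90.0,
            cell_depth_nonhair_um=30.0,
            intensity_decay_halflife_min=240.0,
            flat_profile=True,
            duration_min=495.0,
            seed=seed,
        )
    if name == "fluorescein":
        return DiffusionSimParams(seed=seed)
    raise ValueError(f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}")


# ---------------------------------------------------------------------------
# hair generator


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated at 0 (redraw rejection)."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= 0
    return out


def _draw_capsule(canvas: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius_px: float, value: float) -> None:
    """Compose a soft-edged tube (capsule) onto a float canvas via maximum."""
    lo = np.floor(np.minimum(p0, p1) - radius_px - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius_px + 2).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(canvas.shape[::-1]))  # (x, y) bounds
    if (hi <= lo).any():
        return
    xs = np.arange(lo[0], hi[0])
    ys = np.arange(lo[1], hi[1])
    X, Y = np.meshgrid(xs, ys)
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0:
        dist = np.hypot(X - p0[0], Y - p0[1])
    else:
        tt = np.clip(((X - p0[0]) * d[0] + (Y - p0[1]) * d[1]) / len2, 0.0, 1.0)
        dist = np.hypot(X - (p0[0] + tt * d[0]), Y - (p0[1] + tt * d[1]))
    prof = value * np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
    region = canvas[lo[1] : hi[1], lo[0] : hi[0]]
    np.maximum(region, prof, out=region)


def generate_hair_timelapse(params: HairSimParams) -> tuple[ImageStack, GroundTruth]:
    """Render a root-hair growth time-lapse and its ground truth.

    The root is a bright band along the left image edge; hairs are straight
    bright tubes anchored on its flank, evenly spaced along the root with
    per-hair emergence angles, initiation times, rates and durations. A hair
    whose final tip would leave the field is rendered clipped and flagged
    ``truncated`` in the ground truth (not an error).
    """
    p = params
    rng = np.random.default_rng(p.seed)
    px = p.pixel_size_um
    margin_um = p.hair_spacing_um / 2 + 10.0
    height_um = max(p.n_hairs, 1) * p.hair_spacing_um + 2 * margin_um
    width_um = p.root_width_um + p.field_beyond_root_um
    ny = int(round(height_um / px))
    nx = int(round(width_um / px))
    n_frames = int(math.floor(p.record_duration_min / p.frame_interval_min)) + 1
    times = p.frame_interval_min * np.arange(n_frames)

    rates = _truncated_normal(rng, p.rate_mean, p.rate_sd, p.n_hairs)
    durations = _truncated_normal(rng, p.duration_mean, p.duration_sd, p.n_hairs)
    t_inits = rng.uniform(*p.initiation_window, p.n_hairs)
    angles = rng.uniform(*p.emergence_angle_deg, p.n_hairs)

    base_x = p.root_width_um
    hairs = []
    for i in range(p.n_hairs):
        base_y = margin_um + (i + 0.5) * p.hair_spacing_um
        theta = math.radians(angles[i])
        # angle measured from the root axis (y); 90 deg = perpendicular
        direction = np.array([math.sin(theta), -math.cos(theta)])
        final_length = rates[i] * durations[i]
        tip = np.array([base_x, base_y]) + final_length * direction
        truncated = not (
            0 <= tip[0] <= width_um - 2 * px and 0 <= tip[1] <= height_um - 2 * px
        )
        hairs.append(
            {
                "id": i,
                "t_init": float(t_inits[i]),
                "rate": float(rates[i]),
                "duration": float(durations[i]),
                "final_length": float(final_length),
                "base_x_um": float(base_x),
                "base_y_um": float(base_y),
                "angle_deg": float(angles[i]),
                "truncated": bool(truncated),
            }
        )

    pixels = np.empty((n_frames, 1, ny, nx), dtype=np.uint16)
    root_cols = int(round(p.root_width_um / px))
    radius_px = p.hair_diameter_um / 2.0 / px
    for k, t in enumerate(times):
        canvas = np.zeros((ny, nx), dtype=np.float64)
        canvas[:, :root_cols] = p.signal_level
        for h in hairs:
            length = float(np.clip(h["rate"] * (t - h["t_init"]), 0.0, h["final_length"]))
            if length <= 0:
                continue
            theta = math.radians(h["angle_deg"])
            direction = np.array([math.sin(theta), -math.cos(theta)])
            p0 = np.array([h["base_x_um"], h["base_y_um"]]) / px
            p1 = (np.array([h["base_x_um"], h["base_y_um"]]) + length * direction) / px
            _draw_capsule(canvas, p0, p1, radius_px, p.signal_level)
        frame = p.background_level + canvas
        if p.noise_sd > 0:
            frame = frame + rng.normal(0.0, p.noise_sd, frame.shape)
        pixels[k, 0] = np.clip(frame, 0, BIT_MAX).astype(np.uint16)

    stack = ImageStack(
        pixels=pixels,
        pixel_size_um=px,
        frame_interval_min=p.frame_interval_min,
        z_step_um=0.0,
        label="synthetic root-hair growth",
    )
    return stack, GroundTruth(hairs=hairs)


# ---------------------------------------------------------------------------
# puncta generator


def _puncta_regions(p: PunctaSimParams) -> tuple[np.ndarray, dict[int, dict], list[tuple[float, float, str, float]]]:
    px = p.pixel_size_um
    widths = [w for w, _ in p.region_layout]
    total_w = p.background_margin_um + sum(widths)
    if p.field_width_um is not None and p.field_width_um < total_w:
        raise ValueError(
            f"region layout ({total_w:g} µm incl. margin) wider than the "
            f"field ({p.field_width_um:g} µm)"
        )
    nx = int(round((p.field_width_um or total_w) / px))
    ny = int(round(p.file_length_um / px))
    labels = np.zeros((ny, nx), dtype=np.uint16)
    classes: dict[int, dict] = {}
    extents = []  # (x0_um, x1_um, class, depth_um) per label, in label order
    x0 = p.background_margin_um
    for i, (w, cls) in enumerate(p.region_layout):
        if cls not in ("hair", "non_hair"):
            raise ValueError(f"unknown cell-file class {cls!r}")
        label = i + 1
        c0 = int(round(x0 / px))
        c1 = int(round((x0 + w) / px))
        if c1 > nx:
            raise ValueError("region layout wider than the image field")
        labels[:, c0:c1] = label
        depth = p.cell_depth_hair_um if cls == "hair" else p.cell_depth_nonhair_um
        area = w * p.file_length_um
        classes[label] = {
            "class": cls,
            "area_um2": area,
            "volume_um3": area * depth,
            "cell_count": p.cells_per_file,
        }
        extents.append((x0, x0 + w, cls, depth))
        x0 += w
    return labels, classes, extents


def generate_puncta_timelapse(
    params: PunctaSimParams,
) -> tuple[ImageStack, RegionSet, GroundTruth]:
    """Render a puncta-accumulation z-stack time-lapse with ground truth.

    Per frame and cell file, an independent Poisson number of puncta (mean
    lambda_class * volume / 1000 * profile(t)) is placed uniformly within the
    file footprint and its class depth, and rendered as a 3-D Gaussian. The
    per-punctum peak decays from acquisition start with the configured
    half-life. A puncta-free margin strip (label 0) on the left provides a
    background region.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    px = p.pixel_size_um
    labels, classes, extents = _puncta_regions(p)
    ny, nx = labels.shape
    max_depth = max(p.cell_depth_hair_um, p.cell_depth_nonhair_um)
    nz = int(round((max_depth + 2 * p.punctum_sigma_z_um) / p.z_step_um)) + 1
    n_frames = int(math.floor(p.duration_min / p.frame_interval_min)) + 1
    times = p.frame_interval_min * np.arange(n_frames)

    sig_xy_px = p.punctum_sigma_um / px
    sig_z_sl = p.punctum_sigma_z_um / p.z_step_um
    rx = int(math.ceil(3 * sig_xy_px))
    rz = int(math.ceil(3 * sig_z_sl))

    pixels = np.empty((n_frames, nz, ny, nx), dtype=np.uint16)
    true_counts = np.zeros((n_frames, len(classes)), dtype=int)
    puncta_truth: list[dict] = []
    for k, t in enumerate(times):
        vol = np.zeros((nz, ny, nx), dtype=np.float64)
        if math.isfinite(p.intensity_decay_halflife_min):
            peak = p.punctum_peak * 2.0 ** (-t / p.intensity_decay_halflife_min)
        else:
            peak = p.punctum_peak
        for j, (x0, x1, cls, depth) in enumerate(extents):
            label = j + 1
            lam = p.lambda_hair if cls == "hair" else p.lambda_nonhair
            mean = lam * classes[label]["volume_um3"] / 1000.0 * float(p.profile(cls, t))
            n = int(rng.poisson(mean))
            true_counts[k, j] = n
            for _ in range(n):
                cx = rng.uniform(x0, x1) / px
                cy = rng.uniform(0, p.file_length_um) / px
                cz = rng.uniform(0, depth) / p.z_step_um
                _add_gaussian_3d(vol, cx, cy, cz, sig_xy_px, sig_z_sl, peak, rx, rz)
                puncta_truth.append(
                    {
                        "frame": k,
                        "t_min": float(t),
                        "x_um": float(cx * px),
                        "y_um": float(cy * px),
                        "z_um": float(cz * p.z_step_um),
                        "label": label,
                        "class": cls,
                        "peak": float(peak),
                    }
                )
        frames = p.background_level + vol
        if p.noise_sd > 0:
            frames = frames + rng.normal(0.0, p.noise_sd, frames.shape)
        pixels[k] = np.clip(frames, 0, BIT_MAX).astype(np.uint16)

    stack = ImageStack(
        pixels=pixels,
        pixel_size_um=px,
        frame_interval_min=p.frame_interval_min,
        z_step_um=p.z_step_um,
        label="synthetic puncta accumulation",
    )
    regions = RegionSet(labels=labels, classes=classes)
    truth = GroundTruth(
        regions=[{"label": lab, **meta} for lab, meta in classes.items()],
        true_counts=true_counts,
        puncta=puncta_truth,
    )
    return stack, regions, truth


def _add_gaussian_3d(
    vol: np.ndarray,
    cx: float,
    cy: float,
    cz: float,
    sig_xy: float,
    sig_z: float,
    peak: float,
    rx: int,
    rz: int,
) -> None:
    nz, ny, nx = vol.shape
    x0, x1 = max(int(cx) - rx, 0), min(int(cx) + rx + 2, nx)
    y0, y1 = max(int(cy) - rx, 0), min(int(cy) + rx + 2, ny)
    z0, z1 = max(int(cz) - rz, 0), min(int(cz) + rz + 2, nz)
    if x1 <= x0 or y1 <= y0 or z1 <= z0:
        return
    gx = np.exp(-((np.arange(x0, x1) - cx) ** 2) / (2 * sig_xy**2))
    gy = np.exp(-((np.arange(y0, y1) - cy) ** 2) / (2 * sig_xy**2))
    gz = np.exp(-((np.arange(z0, z1) - cz) ** 2) / (2 * sig_z**2))
    vol[z0:z1, y0:y1, x0:x1] += peak * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def background_roi_for(params: PunctaSimParams) -> RoiSpec:
    """A circular background ROI inside the puncta-free margin strip."""
    d = max(params.background_margin_um - 4.0, 6.0)
    c = params.background_margin_um / 2.0
    return RoiSpec(
        kind="circle",
        role="background",
        center_um=(c, params.file_length_um / 2.0),
        diameter_um=d,
    )


# ---------------------------------------------------------------------------
# diffusion generator


def generate_diffusion_stack(params: DiffusionSimParams) -> tuple[ImageStack, GroundTruth]:
    """Render the bottom-plane view of a diffusing fluorescence front.

    The mean plane intensity follows background + source_concentration *
    slab_bottom_fraction(t); the ground truth stores the analytic curve.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_frames = int(math.floor(p.duration_min / p.frame_interval_min)) + 1
    times = p.frame_interval_min * np.arange(n_frames)
    frac = slab_bottom_fraction(times * 60.0, p.d_eff_um2_s, p.slab_height_um)
    n = p.image_size_px
    pixels = np.empty((n_frames, 1, n, n), dtype=np.uint16)
    for k in range(n_frames):
        frame = np.full((n, n), p.background_level + p.source_concentration * frac[k])
        if p.noise_sd > 0:
            frame = frame + rng.normal(0.0, p.noise_sd, frame.shape)
        pixels[k, 0] = np.clip(frame, 0, BIT_MAX).astype(np.uint16)
    stack = ImageStack(
        pixels=pixels,
        pixel_size_um=p.pixel_size_um,
        frame_interval_min=p.frame_interval_min,
        label="synthetic slab-diffusion bottom plane",
    )
    truth = GroundTruth(
        diffusion={
            "d_eff_um2_s": p.d_eff_um2_s,
            "slab_height_um": p.slab_height_um,
            "source_concentration": p.source_concentration,
            "t_min": times.tolist(),
            "bottom_fraction": np.asarray(frac).tolist(),
        }
    )
    return stack, truth
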