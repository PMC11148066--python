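"""Quantifying treatment arrival and equilibration from diffusion time-lapses.

A compound applied on top of an agar slab reaches the imaged bottom plane by
diffusion. With a fixed source concentration C0 at the top (z = H), a no-flux
boundary at the bottom coverslip (z = 0) and zero initial concentration, the
bottom-plane concentration follows the classic eigenfunction series

    C(0, t) / C0 = 1 - (4/pi) * sum_n (-1)^n / (2n+1) * exp(-D lam_n^2 t),
    lam_n = (2n+1) pi / (2 H)

This module measures ROI time series on image stacks, background-corrects
them, extracts arrival and equilibration times with a declared rule
(baseline + 3 SD sustained for two frames; 95% of plateau), and optionally
fits the slab solution for an effective diffusivity D_eff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .stack import ImageStack

__all__ = [
    "RoiSpec",
    "slab_bottom_fraction",
    "roi_mask",
    "measure_rois",
    "background_correct",
    "arrival_and_equilibration",
    "fit_slab_diffusion",
]

_SERIES_TOL = 1e-9
_MAX_TERMS = 5000


def slab_bottom_fraction(t_s: np.ndarray | float, d_um2_s: float, height_um: float) -> np.ndarray:
    """Bottom-plane concentration as a fraction of the source concentration.

    Parameters are the elapsed time in seconds, the effective diffusivity in
    µm²/s and the slab height in µm. The alternating series is truncated once
    terms fall below 1e-9. Returns values in [0, 1], exactly 0 at t = 0.
    """
    if d_um2_s <= 0:
        raise ValueError("diffusivity must be > 0")
    if height_um <= 0:
        raise ValueError("slab height must be > 0")
    t = np.atleast_1d(np.asarray(t_s, dtype=float))
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = np.zeros_like(t)
    pos = t > 0
    if pos.any():
        tp = t[pos]
        acc = np.zeros_like(tp)
        for n in range(_MAX_TERMS):
            lam = (2 * n + 1) * np.pi / (2.0 * height_um)
            term = ((-1) ** n * 4.0 / ((2 * n + 1) * np.pi)) * np.exp(
                -d_um2_s * lam**2 * tp
            )
            acc += term
            if np.max(np.abs(term)) < _SERIES_TOL:
                break
        out[pos] = np.clip(1.0 - acc, 0.0, 1.0)
    if np.isscalar(t_s):
        return out[0]
    return out


@dataclass
class RoiSpec:
    """A fixed region of interest for intensity time series.

    ``circle`` ROIs have a center (µm) and diameter (µm; the assay default is
    12 µm); ``rectangle`` ROIs span the full image width with a y offset and
    height in µm (default height 10 µm for the bottom-of-slab strip).
    Membership is by pixel center (pixel index i sits at i * pixel_size µm).
    """

    kind: str  # "circle" | "rectangle"
    role: str  # "tip" | "base" | "background" | "bottom_slab"
    center_um: tuple[float, float] | None = None
    diameter_um: float | None = None
    y_offset_um: float | None = None
    height_um: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("circle", "rectangle"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if self.kind == "circle":
            if self.center_um is None or self.diameter_um is None:
                raise ValueError("circle ROI needs center_um and diameter_um")
            if self.diameter_um <= 0:
                raise ValueError("circle diameter must be > 0")
        else:
            if self.y_offset_um is None or self.height_um is None:
                raise ValueError("rectangle ROI needs y_offset_um and height_um")
            if self.height_um <= 0:
                raise ValueError("rectangle height must be > 0")

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind, "role": self.role}
        if self.kind == "circle":
            d["center_um"] = list(self.center_um)
            d["diameter_um"] = self.diameter_um
        else:
            d["y_offset_um"] = self.y_offset_um
            d["height_um"] = self.height_um
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSpec":
        kw = dict(d)
        if "center_um" in kw and kw["center_um"] is not None:
            kw["center_um"] = tuple(kw["center_um"])
        return cls(**kw)


def roi_mask(roi: RoiSpec, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
    """Boolean membership mask for an ROI on a (Y, X) image.

    A pixel belongs to a circle iff its center lies inside the circle; a
    rectangle covers the full width and the rows whose centers fall in
    [y_offset, y_offset + height). Raises if the ROI leaves the image.
    """
    ny, nx = shape
    ys = np.arange(ny) * pixel_size_um
    xs = np.arange(nx) * pixel_size_um
    if roi.kind == "circle":
        cx, cy = roi.center_um
        r = roi.diameter_um / 2.0
        if cx - r < -pixel_size_um / 2 or cy - r < -pixel_size_um / 2 or cx + r > xs[-1] + pixel_size_um / 2 or cy + r > ys[-1] + pixel_size_um / 2:
            raise ValueError(f"ROI ({roi.role}) extends outside the image")
        dx = xs[None, :] - cx
        dy = ys[:, None] - cy
        return dx**2 + dy**2 <= r**2
    y0, h = roi.y_offset_um, roi.height_um
    if y0 < 0 or y0 + h > ys[-1] + pixel_size_um:
        raise ValueError(f"ROI ({roi.role}) extends outside the image")
    return ((ys >= y0) & (ys < y0 + h))[:, None] & np.ones(nx, dtype=bool)[None, :]


def measure_rois(stack: ImageStack, rois: list[RoiSpec], z: int = 0) -> pd.DataFrame:
    """Per-frame mean intensity in each ROI.

    Returns a tidy table with columns (t_min, roi_role, mean_intensity).
    The stack should be projected (Z = 1) or a slice index designated.
    """
    masks = {}
    shape = stack.pixels.shape[2:]
    for roi in rois:
        m = roi_mask(roi, shape, stack.pixel_size_um)
        if not m.any():
            raise ValueError(f"ROI ({roi.role}) contains no pixel centers")
        masks[roi.role] = m
    times = stack.times_min()
    rows = []
    for k in range(stack.n_frames):
        frame = stack.pixels[k, z].astype(float)
        for role, m in masks.items():
            rows.append((times[k], role, float(frame[m].mean())))
    return pd.DataFrame(rows, columns=["t_min", "roi_role", "mean_intensity"])


def background_correct(series: pd.DataFrame) -> pd.DataFrame:
    """Subtract the background ROI, frame by frame, flooring at 0.

    Adds a ``corrected_intensity`` column to every non-background row.
    """
    if "background" not in set(series["roi_role"]):
        raise ValueError("series has no ROI with role 'background'")
    bg = series[series["roi_role"] == "background"].set_index("t_min")["mean_intensity"]
    out = series.copy()
    out["corrected_intensity"] = np.maximum(
        out["mean_intensity"] - out["t_min"].map(bg).to_numpy(), 0.0
    )
    return out


def arrival_and_equilibration(
    series: pd.DataFrame,
    roi_role: str = "bottom_slab",
    baseline_frames: int = 3,
    n_sd: float = 3.0,
    sustain_frames: int = 2,
    equilibration_fraction: float = 0.95,
    value_column: str = "corrected_intensity",
    min_rise: float = 0.5,
) -> dict:
    """Arrival and equilibration times from a corrected ROI series.

    plateau = mean of the last 3 frames; arrival = first time the signal
    exceeds baseline_mean + max(n_sd * baseline_sd, min_rise) and stays
    above it for ``sustain_frames`` consecutive frames; equilibration =
    first time the signal reaches ``equilibration_fraction`` * plateau.
    ``min_rise`` floors the arrival threshold at half a grey level by
    default: on integer-quantized data a smaller rise is not measurable.
    Undefined values are returned as None with a reason.
    """
    sub = series[series["roi_role"] == roi_role].sort_values("t_min")
    if len(sub) < baseline_frames + 1:
        raise ValueError("series too short for the requested baseline")
    t = sub["t_min"].to_numpy(float)
    v = sub[value_column].to_numpy(float)
    base = v[:baseline_frames]
    baseline_mean = float(base.mean())
    baseline_sd = float(base.std(ddof=1)) if baseline_frames > 1 else 0.0
    plateau = float(v[-3:].mean())
    out = {
        "arrival_time_min": None,
        "equilibration_time_min": None,
        "plateau_value": plateau,
        "baseline_mean": baseline_mean,
        "reason": None,
    }
    thresh = baseline_mean + max(n_sd * baseline_sd, min_rise)
    if plateau <= thresh:
        out["reason"] = "no signal rise"
        return out
    above = v > thresh
    for i in range(len(v) - sustain_frames + 1):
        if above[i : i + sustain_frames].all():
            out["arrival_time_min"] = float(t[i])
            break
    eq_idx = np.nonzero(v >= equilibration_fraction * plateau)[0]
    if eq_idx.size:
        out["equilibration_time_min"] = float(t[eq_idx[0]])
    if out["arrival_time_min"] is None:
        out["reason"] = "no sustained rise above baseline"
    return out


def fit_slab_diffusion(
    series: pd.DataFrame,
    slab_height_um: float,
    roi_role: str = "bottom_slab",
    value_column: str = "corrected_intensity",
) -> dict:
    """Least-squares fit of the fixed-source slab solution to a rising series.

    Fits amplitude * slab_bottom_fraction(t; D, H) over (D_eff, amplitude)
    and reports the relative RMS residual.
    """
    sub = series[series["roi_role"] == roi_role].sort_values("t_min")
    t_s = sub["t_min"].to_numpy(float) * 60.0
    v = sub[value_column].to_numpy(float)
    vmax = v.max()
    if vmax <= 0 or v[-3:].mean() <= v[:3].mean():
        raise ValueError("series is not rising; cannot fit a diffusion front")

    # crude initial D from the empirical half-rise time via t ~ 1/D scaling
    half_idx = np.nonzero(v >= 0.5 * vmax)[0]
    t_half = t_s[half_idx[0]] if half_idx.size and t_s[half_idx[0]] > 0 else t_s[-1] / 2
    ref = _half_rise_time(1.0, slab_height_um)
    d0 = max(ref / t_half, 1e-6)

    def model(ts, d, amp):
        return amp * slab_bottom_fraction(ts, d, slab_height_um)

    popt, _ = curve_fit(
        model, t_s, v, p0=[d0, vmax], bounds=([1e-9, 0.0], [np.inf, np.inf]), maxfev=2000
    )
    resid = v - model(t_s, *popt)
    rel = float(np.sqrt(np.mean(resid**2)) / max(vmax, 1e-12))
    return {"d_eff_um2_s": float(popt[0]), "amplitude": float(popt[1]), "relative_residual": rel}


def _half_rise_time(d_um2_s: float, height_um: float) -> float:
    """Time (s) for the bottom fraction to reach 0.5 at diffusivity d."""
    lo, hi = 1e-6, 1e12
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if slab_bottom_fraction(mid, d_um2_s, height_um) < 0.5:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-9:
            break
    return float(np.sqrt(lo * hi))
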