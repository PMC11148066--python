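"""Calibrated image-stack container shared by all assays.

An :class:`ImageStack` is a T×Z×Y×X array of non-negative intensities plus
the physical calibration (µm per pixel, µm per z-step, minutes per frame)
that every downstream metric depends on. Calibration is mandatory: all
reported quantities are in µm and minutes, never pixels and frames.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["ImageStack", "project_max", "reslice_xz"]


@dataclass
class ImageStack:
    """A calibrated T×Z×Y×X fluorescence time-lapse.

    Parameters
    ----------
    pixels
        Array of shape (T, Z, Y, X); non-negative intensities in the 8- or
        16-bit range. Z = 1 is valid (pre-projected data).
    pixel_size_um
        Lateral calibration, µm per pixel (> 0).
    z_step_um
        Axial step between optical slices, µm (≥ 0; 0 for single-plane data).
    frame_interval_min
        Minutes between consecutive frames (> 0).
    t0_min
        Acquisition start offset in minutes (e.g. time since treatment).
    label
        Free-text description.
    """

    pixels: np.ndarray
    pixel_size_um: float
    frame_interval_min: float
    z_step_um: float = 0.0
    t0_min: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be T x Z x Y x X, got shape {self.pixels.shape}"
            )
        if any(s < 1 for s in self.pixels.shape):
            raise ValueError(f"all dimensions must be >= 1, got {self.pixels.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.z_step_um < 0:
            raise ValueError("z_step_um must be >= 0")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_slices(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return tuple(self.pixels.shape)

    def times_min(self) -> np.ndarray:
        """Acquisition time of each frame in minutes (t0 + k * interval)."""
        return self.t0_min + self.frame_interval_min * np.arange(self.n_frames)

    def frame(self, t: int, z: int = 0) -> np.ndarray:
        """A single 2-D (Y, X) plane."""
        return self.pixels[t, z]


def project_max(stack: ImageStack) -> ImageStack:
    """Per-frame maximum-intensity projection over Z.

    Returns a stack with Z = 1 and otherwise unchanged metadata; for a
    Z = 1 input the pixel data are returned unchanged (idempotent).
    """
    if stack.n_slices == 1:
        return replace(stack, pixels=stack.pixels.copy())
    projected = stack.pixels.max(axis=1, keepdims=True)
    return replace(stack, pixels=projected, z_step_um=0.0)


def reslice_xz(stack: ImageStack, row: int) -> np.ndarray:
    """Orthogonal XZ view at a fixed image row, per frame.

    Returns a (T, Z, X) array — the time series of the axial cross-section
    used for bottom-of-slab measurements on 3-D diffusion stacks.
    """
    if not 0 <= row < stack.pixels.shape[2]:
        raise ValueError(f"row {row} outside image height {stack.pixels.shape[2]}")
    return stack.pixels[:, :, row, :]
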