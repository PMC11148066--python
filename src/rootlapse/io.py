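"""Reading and writing the on-disk interchange formats.

Stacks travel as multi-page grayscale TIFF (pages in T-then-Z order) with a
JSON sidecar holding the physical calibration and the declared page layout.
Axes order is declared metadata, never guessed from TIFF tags. Region sets
are a 16-bit label TIFF plus a JSON class map; tables are UTF-8 CSV with a
'.' decimal separator.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .stack import ImageStack

SCHEMA_VERSION = 1

KINETICS_COLUMNS = [
    "hair_id",
    "final_length_um",
    "growth_rate_um_per_min",
    "duration_h",
    "t_start_min",
    "t_stop_min",
    "truncated",
    "qc",
]

TRACK_COLUMNS = ["hair_id", "t_min", "x_um", "y_um"]


def sidecar_path(tiff_path: str | Path) -> Path:
    return Path(tiff_path).with_suffix(".json")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF (TZYX page order) + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t, z, y, x = stack.shape
    pages = stack.pixels.reshape(t * z, y, x)
    tifffile.imwrite(path, pages)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "axes_order": "TZYX",
        "n_t": t,
        "n_z": z,
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "frame_interval_min": stack.frame_interval_min,
        "t0_min": stack.t0_min,
        "label": stack.label,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(
    path: str | Path,
    sidecar: str | Path | None = None,
    *,
    pixel_size_um: float | None = None,
    frame_interval_min: float | None = None,
    z_step_um: float = 0.0,
    n_z: int | None = None,
    t0_min: float = 0.0,
) -> ImageStack:
    """Read a multi-page TIFF into a calibrated ImageStack.

    Calibration comes from the JSON sidecar (written by :func:`write_stack`)
    or from explicit keyword overrides; missing calibration is a hard error
    because every downstream metric is physical.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack not found: {path}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]

    meta: dict = {}
    side = Path(sidecar) if sidecar is not None else sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        if meta.get("axes_order", "TZYX") != "TZYX":
            raise ValueError(f"unsupported axes_order {meta['axes_order']!r}")

    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    dt = (
        frame_interval_min
        if frame_interval_min is not None
        else meta.get("frame_interval_min")
    )
    if px is None or dt is None:
        raise ValueError(
            f"{path}: physical calibration (pixel_size_um, frame_interval_min) "
            "must be supplied by sidecar or flags"
        )
    z = n_z if n_z is not None else int(meta.get("n_z", 1))
    n_pages = pages.shape[0]
    declared_t = meta.get("n_t")
    if n_pages % z != 0:
        raise ValueError(f"{path}: {n_pages} pages not divisible by Z={z}")
    t = n_pages // z
    if declared_t is not None and declared_t != t:
        raise ValueError(
            f"{path}: {n_pages} pages inconsistent with declared T={declared_t}, Z={z}"
        )
    pixels = pages.reshape(t, z, pages.shape[1], pages.shape[2])
    return ImageStack(
        pixels=pixels,
        pixel_size_um=float(px),
        frame_interval_min=float(dt),
        z_step_um=float(meta.get("z_step_um", z_step_um)),
        t0_min=float(meta.get("t0_min", t0_min)),
        label=str(meta.get("label", "")),
    )


def write_label_image(labels: np.ndarray, classes: dict, path: str | Path) -> Path:
    """Write a RegionSet as 16-bit label TIFF + JSON class map."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.astype(np.uint16))
    payload = {
        "schema_version": SCHEMA_VERSION,
        "labels": {str(k): v for k, v in classes.items()},
    }
    sidecar_path(path).write_text(json.dumps(payload, indent=2))
    return path


def read_label_image(
    path: str | Path, classes_path: str | Path | None = None
) -> tuple[np.ndarray, dict]:
    path = Path(path)
    labels = tifffile.imread(path)
    side = Path(classes_path) if classes_path is not None else sidecar_path(path)
    payload = json.loads(side.read_text())
    classes = {int(k): v for k, v in payload["labels"].items()}
    return labels, classes


def write_table(df: pd.DataFrame, path: str | Path, columns: list[str] | None = None) -> Path:
    """Write a CSV table with documented headers (UTF-8, '.' decimals)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ValueError(f"records missing documented columns: {missing}")
        df = df[columns]
    df.to_csv(path, index=False)
    return path


def write_summary_json(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"schema_version": SCHEMA_VERSION, **payload}
    path.write_text(json.dumps(payload, indent=2, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
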