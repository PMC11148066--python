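"""Independent reference implementations used to check the package.

Deliberately naive: brute-force enumeration, explicit finite differences,
global assignment. They share no code with the implementations they check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment


def fd_slab_bottom_curve(
    t_eval_s: np.ndarray, d_um2_s: float, height_um: float, n_nodes: int = 200
) -> np.ndarray:
    """Explicit finite-difference solution of 1-D slab diffusion.

    Fixed concentration 1 at the top node, no-flux at the bottom node,
    zero initial condition; returns the bottom-node value at the requested
    times.
    """
    dz = height_um / (n_nodes - 1)
    dt = 0.4 * dz**2 / d_um2_s
    c = np.zeros(n_nodes)
    c[-1] = 1.0
    out = np.empty(len(t_eval_s))
    t = 0.0
    order = np.argsort(t_eval_s)
    alpha = d_um2_s * dt / dz**2
    idx = 0
    for j in order:
        target = t_eval_s[j]
        while t < target:
            lap = np.empty(n_nodes)
            lap[1:-1] = c[2:] - 2 * c[1:-1] + c[:-2]
            lap[0] = 2 * (c[1] - c[0])  # reflecting bottom boundary
            lap[-1] = 0.0
            c = c + alpha * lap
            c[-1] = 1.0
            t += dt
        out[j] = c[0]
        idx += 1
    return out


def rasterize_tube(
    shape: tuple[int, int],
    base_um: tuple[float, float],
    tip_um: tuple[float, float],
    radius_um: float,
    pixel_size_um: float,
) -> np.ndarray:
    """Brute-force mask of a capsule (tube with round caps) on a pixel grid."""
    ny, nx = shape
    ys = np.arange(ny)[:, None] * pixel_size_um
    xs = np.arange(nx)[None, :] * pixel_size_um
    p0 = np.asarray(base_um, dtype=float)
    p1 = np.asarray(tip_um, dtype=float)
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0:
        dist = np.hypot(xs - p0[0], ys - p0[1])
    else:
        tt = np.clip(((xs - p0[0]) * d[0] + (ys - p0[1]) * d[1]) / len2, 0.0, 1.0)
        dist = np.hypot(xs - (p0[0] + tt * d[0]), ys - (p0[1] + tt * d[1]))
    return dist <= radius_um


def circle_members_bruteforce(
    shape: tuple[int, int], center_um: tuple[float, float], diameter_um: float, px: float
) -> set[tuple[int, int]]:
    """Pixel-by-pixel center-in-circle enumeration."""
    out = set()
    cx, cy = center_um
    r2 = (diameter_um / 2.0) ** 2
    for r in range(shape[0]):
        for c in range(shape[1]):
            if (c * px - cx) ** 2 + (r * px - cy) ** 2 <= r2:
                out.add((r, c))
    return out


def match_tracks_to_truth(
    tracks: list,
    truth_hairs: list[dict],
    frame_interval_min: float,
    max_mean_dist_um: float = 5.0,
) -> dict[int, int]:
    """Globally optimal one-to-one matching of tracks to true trajectories.

    For each (track, true hair) pair, the mean distance between the tracked
    tip and the true tip position at the same times is computed; pairs are
    matched by the Hungarian algorithm and accepted below the distance cap.
    Returns {track_id: hair_id}.
    """
    import math

    def true_tip(h: dict, t: float) -> tuple[float, float]:
        length = min(max(h["rate"] * (t - h["t_init"]), 0.0), h["final_length"])
        th = math.radians(h["angle_deg"])
        return (
            h["base_x_um"] + length * math.sin(th),
            h["base_y_um"] - length * math.cos(th),
        )

    cost = np.full((len(tracks), len(truth_hairs)), 1e6)
    for i, tr in enumerate(tracks):
        pts = np.asarray(tr.samples)
        if len(pts) == 0:
            continue
        for j, h in enumerate(truth_hairs):
            ref = np.array([true_tip(h, t) for t in pts[:, 0]])
            cost[i, j] = float(np.hypot(*(pts[:, 1:] - ref).T).mean())
    rows, cols = linear_sum_assignment(cost)
    return {
        tracks[i].hair_id: truth_hairs[j]["id"]
        for i, j in zip(rows, cols)
        if cost[i, j] <= max_mean_dist_um
    }
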