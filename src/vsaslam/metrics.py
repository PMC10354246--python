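"""Localization metrics and firing-map analysis."""

from __future__ import annotations

import numpy as np


def similarity_error(true_ssp, estimate) -> float:
    """1 - dot(true, estimate)."""
    a = np.asarray(true_ssp, dtype=float)
    b = np.asarray(estimate, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must share a dimension")
    return float(1.0 - np.dot(a, b))


def ate(true_positions, est_positions) -> float:
    """Absolute trajectory error: mean per-timestep Euclidean deviation."""
    t = np.atleast_2d(np.asarray(true_positions, dtype=float))
    e = np.atleast_2d(np.asarray(est_positions, dtype=float))
    if t.shape != e.shape or t.shape[0] < 1:
        raise ValueError("need matching, non-empty position series")
    return float(np.linalg.norm(t - e, axis=1).mean())


def integrated_error(true_positions, est_positions, dt: float) -> float:
    """Per-timestep Euclidean error integrated over time (sum times dt)."""
    t = np.atleast_2d(np.asarray(true_positions, dtype=float))
    e = np.atleast_2d(np.asarray(est_positions, dtype=float))
    if t.shape != e.shape:
        raise ValueError("need matching position series")
    return float(np.linalg.norm(t - e, axis=1).sum() * dt)


def firing_map(
    spike_positions: np.ndarray,
    traj_positions: np.ndarray,
    bins: int = 30,
    bounds=None,
):
    """Occupancy-normalized 2-D rate map from spike positions.

    ``spike_positions`` are the (k, 2) positions at which the neuron fired;
    ``traj_positions`` the (T, 2) visited positions (equal dwell per sample).
    Returns (rate_map, x_edges, y_edges); bins never visited are NaN.
    """
    traj_positions = np.asarray(traj_positions, dtype=float)
    spike_positions = np.asarray(spike_positions, dtype=float).reshape(-1, 2)
    if bounds is None:
        lo = traj_positions.min(axis=0)
        hi = traj_positions.max(axis=0)
    else:
        lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    edges = [np.linspace(lo[i], hi[i], bins + 1) for i in range(2)]
    occ, _, _ = np.histogram2d(
        traj_positions[:, 0], traj_positions[:, 1], bins=edges
    )
    spk, _, _ = np.histogram2d(
        spike_positions[:, 0], spike_positions[:, 1], bins=edges
    )
    rate = np.full_like(occ, np.nan)
    visited = occ > 0
    rate[visited] = spk[visited] / occ[visited]
    return rate, edges[0], edges[1]


def heading_histogram(spike_headings: np.ndarray, n_bins: int = 16):
    """Spike counts binned by heading direction (16 sectors of 22.5 degrees).

    Headings in radians; returns (counts, bin_edges).
    """
    h = np.mod(np.asarray(spike_headings, dtype=float), 2 * np.pi)
    edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    counts, _ = np.histogram(h, bins=edges)
    return counts, edges


def count_fields(rate_map: np.ndarray, threshold_frac: float = 0.5) -> int:
    """Number of connected above-threshold firing fields in a rate map."""
    filled = np.nan_to_num(rate_map, nan=0.0)
    if filled.max() <= 0:
        return 0
    mask = filled >= threshold_frac * filled.max()
    # 4-connected flood fill without scipy.ndimage dependency creep
    visited = np.zeros_like(mask, dtype=bool)
    n_fields = 0
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if mask[r0, c0] and not visited[r0, c0]:
                n_fields += 1
                stack = [(r0, c0)]
                visited[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if (
                            0 <= rr < rows
                            and 0 <= cc < cols
                            and mask[rr, cc]
                            and not visited[rr, cc]
                        ):
                            visited[rr, cc] = True
                            stack.append((rr, cc))
    return n_fields


def heading_concentration(counts: np.ndarray) -> float:
    """Resultant-vector length of a heading histogram (0=uniform, 1=delta)."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        return 0.0
    n = len(counts)
    angles = (np.arange(n) + 0.5) * 2 * np.pi / n
    c = np.sum(counts * np.cos(angles)) / counts.sum()
    s = np.sum(counts * np.sin(angles)) / counts.sum()
    return float(np.hypot(c, s))
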