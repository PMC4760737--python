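"""Analysis layer: segregation indices, density profiles, recovery,
resilience and bistability detection.

All operations consume either an agent snapshot table (columns ``kind``,
``type``, ``x``, ``y``) or a trajectory DataFrame as produced by the
engine (columns ``hours``, ``n1_sens``, ``n1_res``, ``n2_sens``,
``n2_res``, ...).

The segregation index of a bacterium is the fraction of same-type
neighbours within radius r (default 30 000 µm); a zone's index for a type
is the mean over that type's bacteria located in the zone.  The three gut
areas are the mucin layer (outer fifths of the width), the lumen (middle
three fifths) and the border bands (2D/15–4D/15 and 11D/15–13D/15, which
overlap the mucin/lumen split exactly as published).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

__all__ = [
    "ZonePartition", "zone_partitions", "per_cell_segregation",
    "zone_segregation", "density_profile", "recovery_time", "resilience_time",
    "bistability_histogram", "CENSORED", "is_steady",
]

#: default neighbourhood radius for the segregation index, µm
SEGREGATION_RADIUS = 30_000.0

#: sentinel for censored (never-reached) event times
CENSORED = math.inf


@dataclass(frozen=True)
class ZonePartition:
    """A named y-interval of the gut cross-section."""

    zone_id: str
    y_low: float
    y_high: float

    def contains(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y) >= self.y_low) & (np.asarray(y) <= self.y_high)


def zone_partitions(gut_width_D: float) -> dict[str, ZonePartition]:
    """The published three-area split (mucin, lumen, border bands)."""
    D = gut_width_D
    spec = {
        "mucin_wall_low": (0.0, D / 5.0),
        "mucin_wall_high": (4.0 * D / 5.0, D),
        "lumen": (D / 5.0, 4.0 * D / 5.0),
        "border_low": (2.0 * D / 15.0, 4.0 * D / 15.0),
        "border_high": (11.0 * D / 15.0, 13.0 * D / 15.0),
    }
    return {k: ZonePartition(k, lo, hi) for k, (lo, hi) in spec.items()}


def _bacteria_positions(snapshot: pd.DataFrame):
    bac = snapshot[snapshot["kind"] == "bacterium"]
    return (bac["x"].to_numpy(dtype=float), bac["y"].to_numpy(dtype=float),
            bac["type"].to_numpy(dtype=int))


def per_cell_segregation(snapshot: pd.DataFrame,
                         r: float = SEGREGATION_RADIUS) -> np.ndarray:
    """Same-type neighbour fraction for every bacterium (NaN if isolated).

    Neighbours are all other bacteria within Euclidean distance ``r``;
    a bacterium with no neighbour has an undefined index (NaN), which the
    zone averages exclude.
    """
    x, y, t = _bacteria_positions(snapshot)
    n = x.size
    out = np.full(n, np.nan)
    if n == 0:
        return out
    tree = cKDTree(np.column_stack([x, y]))
    neighbours = tree.query_ball_point(np.column_stack([x, y]), r=r)
    for i, idx in enumerate(neighbours):
        idx = [j for j in idx if j != i]
        if not idx:
            continue
        same = np.count_nonzero(t[idx] == t[i])
        out[i] = same / len(idx)
    return out


def zone_segregation(snapshot: pd.DataFrame, zone: ZonePartition,
                     bac_type: int, r: float = SEGREGATION_RADIUS) -> float:
    """Mean per-bacterium segregation of one type inside one zone.

    NaN when the zone holds no bacteria of that type (or only isolated
    ones).  Neighbour sets are evaluated over the whole snapshot; only the
    averaging is restricted to the zone.
    """
    x, y, t = _bacteria_positions(snapshot)
    seg = per_cell_segregation(snapshot, r=r)
    sel = (t == bac_type) & zone.contains(y)
    vals = seg[sel]
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if vals.size else math.nan


def density_profile(snapshot: pd.DataFrame, axis: str = "across",
                    bins: int = 30, extent: float | None = None) -> pd.DataFrame:
    """Binned bacterial position histogram per type along x or across y.

    Returns a DataFrame with bin edges and per-type counts; the counts sum
    to the type populations.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    if axis not in ("along", "across"):
        raise ValueError("axis must be 'along' or 'across'")
    x, y, t = _bacteria_positions(snapshot)
    coord = x if axis == "along" else y
    hi = extent if extent is not None else (float(coord.max()) if coord.size else 1.0)
    edges = np.linspace(0.0, max(hi, 1e-9), bins + 1)
    rows = {"bin_low": edges[:-1], "bin_high": edges[1:]}
    for bt in (1, 2):
        h, _ = np.histogram(coord[t == bt], bins=edges)
        rows[f"type{bt}"] = h
    return pd.DataFrame(rows)


def _totals(traj: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hours = traj["hours"].to_numpy(dtype=float)
    n1 = (traj["n1_sens"] + traj["n1_res"]).to_numpy(dtype=float)
    n2 = (traj["n2_sens"] + traj["n2_res"]).to_numpy(dtype=float)
    return hours, n1, n2


def recovery_time(traj: pd.DataFrame, course_end: float,
                  baseline_window: float = 100.0,
                  recovery_fraction: float = 0.8) -> float:
    """Hours from the end of the course until both types regain the
    recovery fraction (default 80%) of their pre-treatment baselines.

    The baseline is each type's mean count over ``baseline_window`` hours
    immediately before the course started; censored (inf) when the level
    is never reached within the trajectory.
    """
    hours, n1, n2 = _totals(traj)
    if not (hours[0] <= course_end <= hours[-1]):
        raise ValueError(f"course_end {course_end} outside trajectory "
                         f"[{hours[0]}, {hours[-1]}]")
    # locate the course start from the drug-entry record when present
    if "drug_injected" in traj.columns and traj["drug_injected"].sum() > 0:
        course_start = float(hours[np.argmax(traj["drug_injected"].to_numpy() > 0)])
    else:
        course_start = course_end
    base_sel = (hours >= course_start - baseline_window) & (hours < course_start)
    if not np.any(base_sel):
        base_sel = hours < max(course_start, hours[0] + baseline_window)
    base1 = float(np.mean(n1[base_sel]))
    base2 = float(np.mean(n2[base_sel]))
    post = hours >= course_end
    ok = (n1 >= recovery_fraction * base1) & (n2 >= recovery_fraction * base2) & post
    if not np.any(ok):
        return CENSORED
    return float(hours[np.argmax(ok)] - course_end)


def resilience_time(traj: pd.DataFrame, critical: float = 100.0) -> float:
    """First time (hours) either type's count falls to the critical number.

    Used under continuous treatment: the longer the system holds out, the
    more resilient it is.  Censored (inf) when neither type ever falls
    that low within the trajectory.
    """
    hours, n1, n2 = _totals(traj)
    hit = (n1 <= critical) | (n2 <= critical)
    if not np.any(hit):
        return CENSORED
    return float(hours[np.argmax(hit)])


def bistability_histogram(final_states, grid_size: int = 60,
                          prominence: float = 0.1,
                          bandwidth: float | None = None):
    """Mode count and smoothed 2D histogram of long-run (N1, N2) states.

    ``final_states`` is a sequence of (N1, N2) pairs (or a DataFrame with
    ``n1_final``/``n2_final`` columns) from an initial-condition sweep.
    A Gaussian KDE is evaluated on a square grid and local maxima above
    ``prominence`` times the peak density are counted as modes.
    Returns ``(n_modes, density_grid, (n1_axis, n2_axis))``.
    """
    if isinstance(final_states, pd.DataFrame):
        pts = final_states[["n1_final", "n2_final"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(final_states, dtype=float)
    if pts.shape[0] < 30:
        raise ValueError("bistability detection needs at least 30 final states")
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    lo = lo - 0.15 * span
    hi = hi + 0.15 * span
    xs = np.linspace(lo[0], hi[0], grid_size)
    ys = np.linspace(lo[1], hi[1], grid_size)
    # KDE needs non-degenerate scatter; jitter-free degenerate clouds are
    # a single mode by definition
    if np.linalg.matrix_rank(np.cov(pts.T)) < 2:
        density = np.zeros((grid_size, grid_size))
        density[grid_size // 2, grid_size // 2] = 1.0
        return 1, density, (xs, ys)
    kde = gaussian_kde(pts.T, bw_method=bandwidth)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    density = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(grid_size, grid_size)
    footprint = np.ones((5, 5), dtype=bool)
    local_max = (density == ndimage.maximum_filter(density, footprint=footprint))
    peaks = local_max & (density >= prominence * density.max())
    # merge contiguous plateau peaks
    labels, n_modes = ndimage.label(peaks)
    return int(n_modes), density, (xs, ys)


def is_steady(traj: pd.DataFrame, window_ticks: int = 1000,
              tolerance: float = 0.25, fraction: float = 1.0 / 3.0) -> bool:
    """Steady-state heuristic: over the final third of the run, both
    types' moving-average counts stay above zero and within ±tolerance of
    their window means."""
    hours, n1, n2 = _totals(traj)
    start = int(len(hours) * (1.0 - fraction))
    for series in (n1, n2):
        tail = series[start:]
        if tail.size == 0:
            return False
        win = max(1, min(window_ticks, tail.size))
        smooth = np.convolve(tail, np.ones(win) / win, mode="valid")
        mean = smooth.mean()
        if mean <= 0:
            return False
        if np.any(np.abs(smooth - mean) > tolerance * mean):
            return False
    return True
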