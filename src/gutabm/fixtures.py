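"""Deterministic synthetic snapshots and trajectories for testing.

Patterned agent configurations (layered, checkerboard, mixed, two-cluster)
exercise the segregation and density observables without running a full
simulation, and template trajectories with exactly placed crossings
exercise the recovery, resilience and outcome-classification definitions.
All outputs are byte-reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FixtureSpec", "make_snapshot", "make_trajectory"]

PATTERNS = ("layered", "checkerboard", "uniform-mixed", "two-cluster")

TRAJECTORY_TEMPLATES = (
    "recovery-at-T", "never-recover", "hit-100-at-T",
    "oscillating-R-fraction", "decaying-R-fraction", "rising-R-fraction",
)


@dataclass
class FixtureSpec:
    """A deterministic synthetic agent configuration."""

    pattern: str = "uniform-mixed"
    n_type1: int = 100
    n_type2: int = 100
    gut_length_L: float = 600_000.0
    gut_width_D: float = 60_000.0
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.n_type1 < 0 or self.n_type2 < 0:
            raise ValueError("agent counts must be non-negative")


def _table(x1, y1, x2, y2) -> pd.DataFrame:
    return pd.DataFrame({
        "kind": "bacterium",
        "type": np.concatenate([np.ones(len(x1), dtype=int),
                                np.full(len(x2), 2, dtype=int)]),
        "x": np.concatenate([x1, x2]),
        "y": np.concatenate([y1, y2]),
        "resistant": False,
    })


def make_snapshot(f: FixtureSpec) -> pd.DataFrame:
    """Agent table for the requested pattern.

    ``layered``: type 1 in the mucin (wall) zones, type 2 in the lumen.
    ``checkerboard``: the two types alternate on a square lattice.
    ``uniform-mixed``: both types uniform over the whole gut.
    ``two-cluster``: the types occupy separate halves along x.
    """
    rng = np.random.default_rng(f.seed)
    L, D = f.gut_length_L, f.gut_width_D
    n1, n2 = f.n_type1, f.n_type2

    if f.pattern == "layered":
        x1 = rng.uniform(0, L, n1)
        low = rng.random(n1) < 0.5
        y1 = np.where(low, rng.uniform(0, D / 5.0, n1),
                      rng.uniform(4.0 * D / 5.0, D, n1))
        x2 = rng.uniform(0, L, n2)
        y2 = rng.uniform(D / 5.0, 4.0 * D / 5.0, n2)
        return _table(x1, y1, x2, y2)

    if f.pattern == "checkerboard":
        n = n1 + n2
        cols = int(np.ceil(np.sqrt(n * L / D)))
        rows = int(np.ceil(n / max(cols, 1)))
        if rows * cols < n:
            cols += 1
        xs = (np.arange(cols) + 0.5) / cols * L
        ys = (np.arange(rows) + 0.5) / rows * D
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        ij = np.add.outer(np.arange(cols), np.arange(rows))
        types = np.where(ij % 2 == 0, 1, 2).ravel()[:n]
        # honor exact per-type counts by flipping trailing majority cells
        excess1 = int(np.count_nonzero(types == 1)) - n1
        if excess1 > 0:
            types[np.flatnonzero(types == 1)[-excess1:]] = 2
        elif excess1 < 0:
            types[np.flatnonzero(types == 2)[excess1:]] = 1
        x = gx.ravel()[:n]
        y = gy.ravel()[:n]
        t1 = types == 1
        return _table(x[t1], y[t1], x[~t1], y[~t1])

    if f.pattern == "uniform-mixed":
        return _table(rng.uniform(0, L, n1), rng.uniform(0, D, n1),
                      rng.uniform(0, L, n2), rng.uniform(0, D, n2))

    # two-cluster: separation along the gut length
    x1 = rng.uniform(0, 0.4 * L, n1)
    y1 = rng.uniform(0, D, n1)
    x2 = rng.uniform(0.6 * L, L, n2)
    y2 = rng.uniform(0, D, n2)
    return _table(x1, y1, x2, y2)


def make_trajectory(template: str, T: float, total_hours: float = 2000.0,
                    dt: float = 1.0, course_end: float = 100.0,
                    baseline: float = 1000.0) -> pd.DataFrame:
    """Piecewise trajectory with the named crossing placed exactly at T.

    ``recovery-at-T``: both types drop to 50% of baseline during a course
    ending at ``course_end`` and cross back over 80% exactly ``T`` hours
    later.  ``never-recover``: pinned at 50% forever.  ``hit-100-at-T``:
    counts decay and reach 100 exactly at ``T`` hours.  The ``*-R-fraction``
    templates shape the resistant share R/(R+S) after ``course_end``
    (rising to 0.9, decaying to 0, or oscillating between 0.3 and 0.7).
    """
    if template not in TRAJECTORY_TEMPLATES:
        raise ValueError(f"unknown template {template!r}")
    hours = np.arange(0.0, total_hours + dt / 2, dt)
    if T > total_hours:
        raise ValueError("T beyond the series length")
    n = hours.size
    half = baseline / 2.0
    n1 = np.full(n, baseline)
    n2 = np.full(n, baseline)
    res1 = np.zeros(n)
    res2 = np.zeros(n)
    drug = np.zeros(n, dtype=int)
    drug[(hours >= course_end - 24.0) & (hours < course_end)] = 1

    if template == "recovery-at-T":
        in_course = (hours >= course_end - 24.0) & (hours < course_end + T)
        n1[in_course] = half
        n2[in_course] = half
    elif template == "never-recover":
        n1[hours >= course_end - 24.0] = half
        n2[hours >= course_end - 24.0] = half
    elif template == "hit-100-at-T":
        # linear decay from baseline at t=0 to exactly 100 at t=T
        slope = (baseline - 100.0) / T
        n1 = np.maximum(baseline - slope * hours, 50.0)
        n2 = np.full(n, baseline)
        drug[:] = 1
    else:
        post = hours >= course_end
        if template == "rising-R-fraction":
            frac = np.where(post, 0.9, 0.0)
        elif template == "decaying-R-fraction":
            tau = max(T, dt)
            frac = np.where(post, 0.5 * np.exp(-(hours - course_end) / tau), 0.0)
            frac[-1] = 0.0
        else:  # oscillating
            frac = np.where(
                post, 0.5 + 0.2 * np.sin(2.0 * np.pi * (hours - course_end) / (4 * T)),
                0.0)
        res1 = np.round(n1 * frac)
        res2 = np.round(n2 * frac)

    return pd.DataFrame({
        "tick": np.arange(n),
        "hours": hours,
        "n1_sens": n1 - res1, "n1_res": res1,
        "n2_sens": n2 - res2, "n2_res": res2,
        "drug_injected": drug,
    })
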