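"""The virtual gut: 2D geometry, passive-particle transport and entry.

The gut is a rectangle of length ``L`` (flow axis, x) and width ``D``
(cross axis, y).  Passive particles (polysaccharides, SCFAs, toxins,
antibiotic) are advected along x with a parabolic-like velocity profile
that vanishes at the walls,

    v(y) = k_gut_out * L * (1 - |y - D/2| * 2/D)**2,

receive a small random lateral jitter, are excreted past ``x = L`` and —
for SCFAs in the wall (mucin) zones — are absorbed through the saturable
MCT transporter.  Every removal is accounted in a per-kind mass ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import PARTICLE_KINDS, SCFA_KINDS, SimulationParams

__all__ = [
    "Particle", "ParticlePool", "MassLedger", "GutWorld",
    "axial_velocity", "wall_absorption_rate", "step_particles", "inject_meal",
]


@dataclass
class Particle:
    """A single passive agent: a fixed substance quantum at a position."""

    kind: str
    x: float
    y: float
    quantum: float = 1.0


class ParticlePool:
    """Positions of all particles of one kind (structure-of-arrays)."""

    __slots__ = ("x", "y")

    def __init__(self, x=None, y=None):
        self.x = np.asarray(x if x is not None else [], dtype=float)
        self.y = np.asarray(y if y is not None else [], dtype=float)

    def __len__(self) -> int:
        return self.x.size

    def add(self, x: np.ndarray, y: np.ndarray) -> None:
        if np.size(x) == 0:
            return
        self.x = np.concatenate([self.x, np.atleast_1d(np.asarray(x, dtype=float))])
        self.y = np.concatenate([self.y, np.atleast_1d(np.asarray(y, dtype=float))])

    def remove(self, mask: np.ndarray) -> int:
        """Drop particles where ``mask`` is True; return how many."""
        n = int(np.count_nonzero(mask))
        if n:
            keep = ~mask
            self.x = self.x[keep]
            self.y = self.y[keep]
        return n


class MassLedger:
    """Cumulative quanta per kind by cause; closes exactly against pools.

    For every kind:  injected + produced + released
                   - consumed - uptaken - absorbed - excreted - decayed
                   = quanta currently in the pool.
    ``consumed`` is food eaten by bacteria, ``uptaken`` is toxin/drug
    quanta drawn into bacterial bodies, ``released`` is drug re-emitted
    from dead bacteria.
    """

    CAUSES = ("injected", "produced", "released",
              "consumed", "uptaken", "absorbed", "excreted", "decayed")

    def __init__(self):
        self.counts = {kind: dict.fromkeys(self.CAUSES, 0) for kind in PARTICLE_KINDS}

    def record(self, kind: str, cause: str, n: int) -> None:
        if n:
            self.counts[kind][cause] += int(n)

    def net(self, kind: str) -> int:
        c = self.counts[kind]
        return (c["injected"] + c["produced"] + c["released"]
                - c["consumed"] - c["uptaken"] - c["absorbed"]
                - c["excreted"] - c["decayed"])

    COLUMNS: tuple[str, ...] = ()   # filled in right after the class body

    def as_values(self) -> list[int]:
        """Cumulative counts in COLUMNS order (hot path for recording)."""
        return [self.counts[kind][cause] for kind in PARTICLE_KINDS
                for cause in self.CAUSES]

    def as_row(self) -> dict[str, int]:
        return dict(zip(self.COLUMNS, self.as_values()))


MassLedger.COLUMNS = tuple(f"led_{kind}_{cause}" for kind in PARTICLE_KINDS
                           for cause in MassLedger.CAUSES)


@dataclass
class GutWorld:
    """Geometry, particle pools, the bacterial population and the clock.

    The bacterial population is owned by :class:`gutabm.agents.BacteriaArrays`
    and attached by the engine; fixtures may leave it ``None``.
    """

    params: SimulationParams
    clock: float = 0.0
    particles: dict[str, ParticlePool] = field(default_factory=dict)
    bacteria: object = None
    ledger: MassLedger = field(default_factory=MassLedger)
    _mucus_accum: float = 0.0
    _drug_accum: float = 0.0
    _fb_accum: dict = field(default_factory=dict)

    def __post_init__(self):
        for kind in PARTICLE_KINDS:
            self.particles.setdefault(kind, ParticlePool())

    # geometry ---------------------------------------------------------------

    @property
    def L(self) -> float:
        return self.params.gut_length_L

    @property
    def D(self) -> float:
        return self.params.gut_width_D

    def mucin_mask(self, y: np.ndarray) -> np.ndarray:
        """True where y lies in the mucin (wall) zones (0, D/5) u (4D/5, D)."""
        D = self.D
        return (y < D / 5.0) | (y > 4.0 * D / 5.0)

    def zone_intervals(self) -> dict[str, tuple[float, float]]:
        """Named y-intervals of the three gut areas (borders overlap)."""
        D = self.D
        return {
            "mucin_wall_low": (0.0, D / 5.0),
            "mucin_wall_high": (4.0 * D / 5.0, D),
            "lumen": (D / 5.0, 4.0 * D / 5.0),
            "border_low": (2.0 * D / 15.0, 4.0 * D / 15.0),
            "border_high": (11.0 * D / 15.0, 13.0 * D / 15.0),
        }

    # concentration field ----------------------------------------------------

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = self.params
        ix = (np.asarray(x) / self.L * p.conc_grid_nx).astype(np.intp)
        iy = (np.asarray(y) / self.D * p.conc_grid_ny).astype(np.intp)
        np.minimum(ix, p.conc_grid_nx - 1, out=ix)
        np.maximum(ix, 0, out=ix)
        np.minimum(iy, p.conc_grid_ny - 1, out=iy)
        np.maximum(iy, 0, out=iy)
        return ix, iy

    def concentration_grid(self, kind: str) -> np.ndarray:
        """Local concentration (mM) of a kind on the estimate grid."""
        p = self.params
        pool = self.particles[kind]
        nx, ny = p.conc_grid_nx, p.conc_grid_ny
        if len(pool):
            ix, iy = self.cell_index(pool.x, pool.y)
            grid = np.bincount(ix * ny + iy, minlength=nx * ny).reshape(nx, ny)
            grid = grid.astype(float)
        else:
            grid = np.zeros((nx, ny))
        return grid * (p.particle_quantum * p.conc_mM_per_quantum)

    def count(self, kind: str) -> int:
        return len(self.particles[kind])

    def add_particles(self, kind: str, x, y, cause: str = "produced") -> None:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        self.particles[kind].add(x, y)
        self.ledger.record(kind, cause, x.size)


# ---------------------------------------------------------------------------
# transport kinetics


def axial_velocity(y, p: SimulationParams):
    """Advection speed (µm/h) at cross-position ``y``: parabolic-squared
    profile ``k_gut_out * L * (1 - |y - D/2| * 2/D)**2``, maximal on the
    centerline and zero at the walls."""
    y_arr = np.asarray(y, dtype=float)
    D = p.gut_width_D
    if np.any(y_arr < 0) or np.any(y_arr > D):
        raise ValueError("y outside the gut cross-section [0, D]")
    prof = (1.0 - np.abs(y_arr - D / 2.0) * 2.0 / D) ** 2
    out = p.k_gut_out * p.gut_length_L * prof
    return out if out.shape else float(out)


def _velocity_unchecked(y: np.ndarray, p: SimulationParams) -> np.ndarray:
    # hot path: identical arithmetic to axial_velocity, domain checks skipped
    D = p.gut_width_D
    prof = (1.0 - np.abs(y - D / 2.0) * 2.0 / D) ** 2
    return p.k_gut_out * p.gut_length_L * prof


def wall_absorption_rate(concentrations: dict[str, float], species: str,
                         p: SimulationParams) -> float:
    """MCT wall flux (mmol/h) for one SCFA at the given local concentrations.

    ``k_trans_mct * ([C]/Km) / D_MCT1`` with the shared saturation term
    ``D_MCT1 = 1 + sum_s [C_s]/Km_s`` over all three SCFAs; the summed flux
    over species is therefore strictly below ``k_trans_mct``.
    """
    if species not in SCFA_KINDS:
        raise ValueError(f"not an SCFA kind: {species!r}")
    kms = {"acetate": p.km_acetate_mct, "propionate": p.km_propionate_mct,
           "butyrate": p.km_butyrate_mct}
    sat = 1.0
    for s in SCFA_KINDS:
        c = float(concentrations.get(s, 0.0))
        if c < 0:
            raise ValueError(f"negative concentration for {s}")
        sat += c / kms[s]
    return p.k_trans_mct * (float(concentrations.get(species, 0.0)) / kms[species]) / sat


# ---------------------------------------------------------------------------
# per-tick particle dynamics


def step_particles(w: GutWorld, p: SimulationParams, dt: float,
                   rng: np.random.Generator) -> GutWorld:
    """Advect, jitter, excrete and absorb all passive particles in place.

    SCFA particles sitting in a mucin zone are absorbed stochastically with
    per-particle probability ``min(1, rate*dt / local pool mass)`` where the
    rate is the continuum MCT flux at the particle's grid cell.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    D, L = w.D, w.L

    scfa_grids = {s: w.concentration_grid(s) for s in SCFA_KINDS}
    kms = {"acetate": p.km_acetate_mct, "propionate": p.km_propionate_mct,
           "butyrate": p.km_butyrate_mct}
    sat_grid = 1.0
    for s in SCFA_KINDS:
        sat_grid = sat_grid + scfa_grids[s] / kms[s]

    for kind in PARTICLE_KINDS:
        pool = w.particles[kind]
        n = len(pool)
        if n == 0:
            continue
        # advection + lateral jitter (reflecting walls)
        pool.x = pool.x + _velocity_unchecked(pool.y, p) * dt
        y = pool.y + rng.uniform(-p.jitter_step, p.jitter_step, size=n)
        y = np.abs(y)
        y = np.where(y > D, 2.0 * D - y, y)
        pool.y = np.minimum(np.maximum(y, 0.0), D)

        # excretion at the outlet
        excreted = pool.remove(pool.x > L)
        w.ledger.record(kind, "excreted", excreted)

        # MCT absorption of wall-adjacent SCFA particles
        if kind in SCFA_KINDS and len(pool):
            in_mucin = w.mucin_mask(pool.y)
            if np.any(in_mucin):
                ix, iy = w.cell_index(pool.x[in_mucin], pool.y[in_mucin])
                rate = (p.k_trans_mct * (scfa_grids[kind][ix, iy] / kms[kind])
                        / sat_grid[ix, iy])
                local_mass = scfa_grids[kind][ix, iy] / p.conc_mM_per_quantum
                with np.errstate(divide="ignore", invalid="ignore"):
                    prob = np.where(local_mass > 0,
                                    np.minimum(1.0, rate * dt / local_mass), 0.0)
                hit = rng.random(prob.size) < prob
                mask = np.zeros(len(pool), dtype=bool)
                mask[np.flatnonzero(in_mucin)[hit]] = True
                absorbed = pool.remove(mask)
                w.ledger.record(kind, "absorbed", absorbed)

        # spontaneous toxin degradation
        if kind == "toxin1" and p.k_antitoxin1 > 0 and len(pool):
            gone = pool.remove(rng.random(len(pool)) < min(1.0, p.k_antitoxin1 * dt))
            w.ledger.record(kind, "decayed", gone)
        elif kind in ("toxin2_vs1", "toxin2_vs2") and p.k_antitoxin2 > 0 and len(pool):
            gone = pool.remove(rng.random(len(pool)) < min(1.0, p.k_antitoxin2 * dt))
            w.ledger.record(kind, "decayed", gone)
    return w


def inject_meal(w: GutWorld, p: SimulationParams, rng: np.random.Generator) -> GutWorld:
    """Add one meal's worth of dietary polysaccharide near the inlet.

    ``round(k_intake * eat_period / particle_quantum)`` PS particles enter
    at small x, spread uniformly across the lumen.
    """
    n = int(round(p.k_intake * p.eat_period / p.particle_quantum))
    if n <= 0:
        return w
    x = rng.uniform(0.0, 0.02 * w.L, size=n)
    y = rng.uniform(w.D / 5.0, 4.0 * w.D / 5.0, size=n)
    w.add_particles("ps", x, y, cause="injected")
    return w


def host_mucus_step(w: GutWorld, p: SimulationParams, dt: float,
                    rng: np.random.Generator) -> None:
    """Continuous host polysaccharide production along the walls.

    Fractional quanta accumulate across ticks so that the long-run entry
    rate is exactly ``k_ps_mucus`` regardless of the tick length.
    """
    w._mucus_accum += p.k_ps_mucus * dt / p.particle_quantum
    n = int(w._mucus_accum)
    if n <= 0:
        return
    w._mucus_accum -= n
    x = rng.uniform(0.0, w.L, size=n)
    wall_band = w.D / 10.0
    low = rng.random(n) < 0.5
    y = np.where(low, rng.uniform(0.0, wall_band, size=n),
                 rng.uniform(w.D - wall_band, w.D, size=n))
    w.add_particles("ps_gut", x, y, cause="injected")
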