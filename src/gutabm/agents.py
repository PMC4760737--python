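"""Bacterial agents: food search, movement, division, starvation and toxin death.

Two representations are provided.  :class:`Bacterium` is the single-agent
reference type used by the per-agent operations (`choose_action`, `move`,
`divide`, `apply_toxins`) that document the lifecycle contract.  The engine
holds the whole population in :class:`BacteriaArrays`, a structure-of-arrays
mirror of the same state, and applies the identical rules vectorised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import RESISTANT, SimulationParams

__all__ = ["Bacterium", "BacteriaArrays", "choose_action", "move", "divide",
           "apply_toxins", "draw_starvation_limit"]

#: lifecycle states of the behaviour flow chart
STATES = ("searching", "moving", "converting", "dividing", "dying")


@dataclass
class Bacterium:
    """One active agent."""

    type: int                      # 1 or 2
    x: float
    y: float
    state: str = "searching"
    hunger_clock: float = 0.0      # hours since last feeding
    starvation_limit: float = 24.0  # hours; drawn from U(0, n*eat_period]
    energy: float = 0.0            # quanta converted since last division
    accumulated_antibiotic: float = 0.0
    accumulated_toxin1: float = 0.0
    accumulated_toxin2: float = 0.0
    resistant: bool = False

    def sensitivity(self, substance: str, p: SimulationParams) -> float:
        if substance == "antibiotic" and self.resistant:
            return RESISTANT
        return p.sensitivity(self.type, substance)


def draw_starvation_limit(p: SimulationParams, rng: np.random.Generator,
                          size: int | None = None):
    """Lifetime without nutrients: uniform on (0, n * eat_period]."""
    hi = p.eat_range_multiplier_n * p.eat_period
    u = rng.random(size)
    return hi * (1.0 - u) if size is not None else hi * (1.0 - float(u))


# ---------------------------------------------------------------------------
# per-agent reference operations


def choose_action(b: Bacterium, nearest_edible_distance: float | None,
                  p: SimulationParams) -> str:
    """Next lifecycle state from hunger, energy and the local food situation.

    Priority: starvation death, then division, then feeding within contact
    range, then directed movement within the search radius, else random
    search.  ``nearest_edible_distance`` is ``None`` when no edible particle
    exists within the search radius.
    """
    if b.hunger_clock > b.starvation_limit:
        return "dying"
    if b.energy >= p.division_threshold:
        return "dividing"
    if nearest_edible_distance is not None:
        if nearest_edible_distance <= p.contact_radius:
            return "converting"
        if nearest_edible_distance <= p.search_radius_R:
            return "moving"
    return "searching"


def move(b: Bacterium, direction: tuple[float, float] | None,
         p: SimulationParams, dt: float, rng: np.random.Generator) -> Bacterium:
    """Displace by ``speed * dt`` along ``direction`` (or a random direction),
    reflecting at the walls and clamping to the gut."""
    step = p.bacterial_speed * dt
    if direction is None:
        theta = rng.uniform(0.0, 2.0 * math.pi)
        dx, dy = math.cos(theta), math.sin(theta)
    else:
        norm = math.hypot(*direction)
        dx, dy = (direction[0] / norm, direction[1] / norm) if norm > 0 else (0.0, 0.0)
    x = min(max(b.x + dx * step, 0.0), p.gut_length_L)
    y = b.y + dy * step
    y = abs(y)
    if y > p.gut_width_D:
        y = 2.0 * p.gut_width_D - y
    b.x, b.y = x, min(max(y, 0.0), p.gut_width_D)
    return b


def divide(b: Bacterium, p: SimulationParams, rng: np.random.Generator,
           offset: float = 20.0) -> tuple[Bacterium, Bacterium]:
    """Split into two daughters at the parent position (± a small offset).

    Energy resets to zero in both; each daughter independently redraws its
    starvation limit; type, sensitivities and resistance are inherited.
    Resistance mutation of sensitive daughters is the antibiotic module's
    job and is applied by the caller.
    """
    daughters = []
    for sign in (-1.0, 1.0):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        d = Bacterium(
            type=b.type,
            x=min(max(b.x + sign * offset * math.cos(theta), 0.0), p.gut_length_L),
            y=min(max(b.y + sign * offset * math.sin(theta), 0.0), p.gut_width_D),
            state="searching",
            hunger_clock=0.0,
            starvation_limit=draw_starvation_limit(p, rng),
            energy=0.0,
            resistant=b.resistant,
        )
        daughters.append(d)
    return daughters[0], daughters[1]


def apply_toxins(b: Bacterium, local_toxins, p: SimulationParams):
    """Contact with toxin particles: detoxify, accumulate or die.

    ``local_toxins`` is a list of Particles of kinds toxin1/toxin2_vs1/
    toxin2_vs2 within contact range.  Returns ``(b_or_None, survivors)``
    where ``None`` means death and ``survivors`` are the particles left in
    the medium (detoxified and absorbed quanta are removed).
    """
    from .metabolism import edible_kinds

    detox = set(edible_kinds(b.type, p)) & {"toxin1"}
    survivors = []
    for part in local_toxins:
        harmful = (
            (part.kind == "toxin1" and "toxin1" not in detox)
            or part.kind == f"toxin2_vs{b.type}"
        )
        if part.kind == "toxin1" and "toxin1" in detox:
            continue  # consumed without harm
        if not harmful:
            survivors.append(part)
            continue
        substance = "toxin1" if part.kind == "toxin1" else "toxin2"
        threshold = b.sensitivity(substance, p)
        if math.isinf(threshold):
            survivors.append(part)  # immune: toxin stays in the medium
            continue
        if substance == "toxin1":
            b.accumulated_toxin1 += 1.0
        else:
            b.accumulated_toxin2 += 1.0
    dead = (
        (not math.isinf(b.sensitivity("toxin1", p))
         and b.accumulated_toxin1 >= max(b.sensitivity("toxin1", p), 1.0))
        or (not math.isinf(b.sensitivity("toxin2", p))
            and b.accumulated_toxin2 >= max(b.sensitivity("toxin2", p), 1.0))
    )
    return (None if dead else b), survivors


# ---------------------------------------------------------------------------
# population structure-of-arrays


class BacteriaArrays:
    """The whole population as parallel numpy arrays (engine representation)."""

    FIELDS = ("x", "y", "type", "hunger", "starve_limit", "energy",
              "acc_toxin1", "acc_toxin2", "acc_drug", "resistant")

    def __init__(self, n: int = 0):
        self.x = np.zeros(n)
        self.y = np.zeros(n)
        self.type = np.ones(n, dtype=np.int8)
        self.hunger = np.zeros(n)
        self.starve_limit = np.zeros(n)
        self.energy = np.zeros(n)
        self.acc_toxin1 = np.zeros(n)
        self.acc_toxin2 = np.zeros(n)
        self.acc_drug = np.zeros(n)
        self.resistant = np.zeros(n, dtype=bool)

    def __len__(self) -> int:
        return self.x.size

    @classmethod
    def initial(cls, p: SimulationParams, rng: np.random.Generator) -> "BacteriaArrays":
        """Uniform-random placement of the configured initial counts."""
        n1, n2 = p.initial_bacteria_1, p.initial_bacteria_2
        n = n1 + n2
        pop = cls(n)
        pop.x = rng.uniform(0.0, p.gut_length_L, size=n)
        pop.y = rng.uniform(0.0, p.gut_width_D, size=n)
        pop.type = np.concatenate([np.ones(n1, dtype=np.int8),
                                   np.full(n2, 2, dtype=np.int8)])
        pop.starve_limit = draw_starvation_limit(p, rng, size=n)
        if p.initial_resistant_fraction > 0:
            pop.resistant = rng.random(n) < p.initial_resistant_fraction
        return pop

    def select(self, mask: np.ndarray) -> None:
        for name in self.FIELDS:
            setattr(self, name, getattr(self, name)[mask])

    def append(self, other: "BacteriaArrays") -> None:
        for name in self.FIELDS:
            setattr(self, name,
                    np.concatenate([getattr(self, name), getattr(other, name)]))

    def counts(self) -> dict[str, int]:
        t1 = self.type == 1
        t2 = self.type == 2
        return {
            "n1_sens": int(np.count_nonzero(t1 & ~self.resistant)),
            "n1_res": int(np.count_nonzero(t1 & self.resistant)),
            "n2_sens": int(np.count_nonzero(t2 & ~self.resistant)),
            "n2_res": int(np.count_nonzero(t2 & self.resistant)),
        }

    def to_bacteria(self) -> list[Bacterium]:
        out = []
        for i in range(len(self)):
            out.append(Bacterium(
                type=int(self.type[i]), x=float(self.x[i]), y=float(self.y[i]),
                hunger_clock=float(self.hunger[i]),
                starvation_limit=float(self.starve_limit[i]),
                energy=float(self.energy[i]),
                accumulated_antibiotic=float(self.acc_drug[i]),
                accumulated_toxin1=float(self.acc_toxin1[i]),
                accumulated_toxin2=float(self.acc_toxin2[i]),
                resistant=bool(self.resistant[i]),
            ))
        return out
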