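"""Antibiotic dosing, bacterial drug uptake and death, resistance evolution.

The course is a sequence of daily gavage windows.  Drug particles enter at
the inlet, flow with the luminal stream, and are taken up by bacteria on
contact.  A bacterium dies when its accumulated drug reaches its lethal
threshold, re-releasing the accumulated quanta into the gut.  On division,
sensitive daughters mutate to resistance with probability
``min(1, alpha * C / Rc)`` (C = local drug quanta); resistance costs a
division of all conversion rates by the retardation constant Rc.
"""

from __future__ import annotations

import math

import numpy as np

from .environment import GutWorld
from .params import DoseSchedule, ResistanceModel, SimulationParams

__all__ = ["DoseSchedule", "ResistanceModel", "gavage_open", "antibiotic_entry",
           "drug_uptake_and_death", "mutation_on_division", "classify_outcome",
           "InsufficientDataError"]


def class1_corner_params(seed: int) -> SimulationParams:
    """Desk-scale study conditions for the resistant-dominance corner.

    A stabilized two-feedback community (toxin–antitoxin coupling plus gut
    abundance control) under one 3-day once-daily course, with no fitness
    cost (Rc = 1) and a mutation scale that saturates the per-division
    mutation probability wherever drug is present.
    """
    from .feedbacks import apply_screen_calibration
    from .params import desk_scale_params

    p = desk_scale_params(seed=seed)
    apply_screen_calibration(p, ("FB1", "FB3"))
    p.feedbacks.fb3_abundance_threshold = 30.0
    p.feedbacks.gut_toxin_rate = 120.0
    p.resistance.retardation_constant_Rc = 1.0
    p.resistance.mutation_rate_scale_alpha = 5.0
    p.antibiotic.k_ant_intake = 2500.0
    p.antibiotic.course_start = 48.0
    p.antibiotic.course_days = 3.0
    p.antibiotic.gavages_per_day = 1
    p.antibiotic.gavage_duration = 1.0
    return p


class InsufficientDataError(ValueError):
    """Raised when a trajectory is too short for outcome classification."""


def gavage_open(s: DoseSchedule, clock: float) -> bool:
    """True while a gavage window is open at time ``clock`` (hours)."""
    if s.k_ant_intake <= 0:
        return False
    t = clock - s.course_start
    if t < 0:
        return False
    if not s.continuous and t >= s.course_days * 24.0:
        return False
    spacing = 24.0 / s.gavages_per_day
    return (t % spacing) < s.gavage_duration


def antibiotic_entry(w: GutWorld, s: DoseSchedule, clock: float, dt: float,
                     rng: np.random.Generator) -> int:
    """Inject drug particles at the inlet during open gavage windows.

    Entry rate is ``k_ant_intake`` (mmol/h) while a window is open;
    fractional quanta carry over between ticks so the delivered mass is
    exact over a window.  Returns the number of quanta injected.
    """
    if not gavage_open(s, clock):
        return 0
    p = w.params
    w._drug_accum += s.k_ant_intake * dt / p.particle_quantum
    n = int(w._drug_accum)
    if n <= 0:
        return 0
    w._drug_accum -= n
    x = rng.uniform(0.0, 0.02 * w.L, size=n)
    y = rng.uniform(w.D / 5.0, 4.0 * w.D / 5.0, size=n)
    w.add_particles("antibiotic", x, y, cause="injected")
    return n


def drug_uptake_and_death(b, local_drug_particles, p: SimulationParams):
    """Per-bacterium reference for drug absorption and lethality.

    The bacterium absorbs every contacted drug quantum (they leave the
    pool); when the accumulated amount reaches its lethal threshold it
    dies and all accumulated quanta are re-released at its position.
    Resistant bacteria (infinite threshold) absorb but never die of drug.
    Returns ``(b_or_None, released_particles)``.
    """
    from .environment import Particle

    b.accumulated_antibiotic += len(local_drug_particles)
    threshold = b.sensitivity("antibiotic", p)
    if (not math.isinf(threshold)
            and b.accumulated_antibiotic > 0
            and b.accumulated_antibiotic >= max(threshold, 1.0)):
        released = [Particle("antibiotic", b.x, b.y, p.particle_quantum)
                    for _ in range(int(round(b.accumulated_antibiotic)))]
        return None, released
    return b, []


def mutation_on_division(parent_resistant: bool, local_drug_quanta: float,
                         model: ResistanceModel, rng: np.random.Generator,
                         n_daughters: int = 2) -> np.ndarray:
    """Resistance states of the daughters of one division.

    Resistant parents breed true (no back-mutation); each sensitive
    daughter independently mutates with ``min(1, alpha*C/Rc)``.
    """
    if parent_resistant:
        return np.ones(n_daughters, dtype=bool)
    p_mut = model.mutation_probability(local_drug_quanta)
    return rng.random(n_daughters) < p_mut


def classify_outcome(times: np.ndarray, resistant_fraction: np.ndarray,
                     course_end: float, window: float | None = None,
                     course_length: float | None = None,
                     resistant_counts: np.ndarray | None = None) -> int:
    """Three-class post-treatment community structure.

    Over the classification window after the course (default 10x the
    course length): class 1 when the mean resistant fraction R/(R+S)
    exceeds 0.7 (resistant strains dominate); class 3 when it falls below
    0.1 and the final resistant count is zero (sensitive strains recover);
    class 2 otherwise (sustained fluctuation of the ratio).
    """
    times = np.asarray(times, dtype=float)
    frac = np.asarray(resistant_fraction, dtype=float)
    if window is None:
        if course_length is None:
            raise ValueError("need either window or course_length")
        window = 10.0 * course_length
    if times.size == 0 or times[-1] < course_end + window:
        raise InsufficientDataError(
            f"trajectory ends at {times[-1] if times.size else 'n/a'} h; "
            f"classification needs {course_end + window} h")
    sel = times >= course_end
    vals = frac[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InsufficientDataError("no post-course resistant-fraction samples")
    mean_frac = float(np.mean(vals))
    if mean_frac > 0.7:
        return 1
    final_res = None
    if resistant_counts is not None:
        final_res = float(np.asarray(resistant_counts)[-1])
    else:
        final_res = float(frac[-1]) if np.isfinite(frac[-1]) else 0.0
    if mean_frac < 0.1 and final_res == 0:
        return 3
    return 2
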