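"""Conversion kinetics of the SCFA cross-feeding scheme.

Bacterial type 1 ferments dietary and host polysaccharide to acetate and
acetate to butyrate; type 2 ferments dietary polysaccharide to acetate and
propionate.  Each reaction follows saturating Michaelis–Menten kinetics

    V = 100 * k * [S] / (Km + [S])     [mmol/h],

which the agent layer discretises into per-tick Bernoulli consumption
events of one substance quantum.  Stoichiometry is 1 quantum substrate ->
1 quantum product, so metabolism conserves total substance mass exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import SimulationParams

__all__ = ["ReactionRate", "conversion_rate", "edible_kinds", "total_uptake_rate",
           "product_for", "consume_and_convert"]


@dataclass
class ReactionRate:
    """A resolved reaction: substrate -> product by an actor, in mmol/h."""

    reaction_id: str
    substrate: str
    product: str
    actor: str          # "type1", "type2" or "gut"
    rate: float

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("reaction rate must be non-negative")


def conversion_rate(substrate_conc: float, k: float, km: float) -> float:
    """Michaelis–Menten conversion velocity ``100*k*[S]/(Km+[S])`` in mmol/h.

    Monotone increasing in ``[S]`` and saturating at ``100*k``.
    """
    if km <= 0:
        raise ValueError("Michaelis constant must be > 0")
    if substrate_conc < 0:
        raise ValueError("substrate concentration must be non-negative")
    return 100.0 * k * substrate_conc / (km + substrate_conc)


def _km_for(substrate: str, p: SimulationParams) -> float:
    return {
        "ps": p.km_acetate_conv,        # PS fermentation senses the acetate-branch Km
        "ps_gut": p.km_acetate_conv,
        "acetate": p.km_butyrate_conv,  # acetate->butyrate branch
    }[substrate]


def edible_kinds(bac_type: int, p: SimulationParams) -> tuple[str, ...]:
    """Substrate kinds a bacterial type can ingest under the active network.

    Type 1 additionally detoxifies toxin1 by eating it.  Enabling FB1 grants
    type 2 the acetate-consuming (toxin-producing) pathway; the inverted
    orientation moves that pathway to type 1 (which already eats acetate)
    and the detoxifier role to type 2.
    """
    fb = p.feedbacks
    fb1 = "FB1" in fb.enabled
    detox_type = 2 if (fb1 and fb.orientation_inverted) else 1
    if bac_type == 1:
        kinds = ["ps", "ps_gut", "acetate"]
    else:
        kinds = ["ps"]
        if fb1 and not fb.orientation_inverted:
            kinds.append("acetate")
    if bac_type == detox_type:
        kinds.append("toxin1")
    return tuple(kinds)


def uptake_constants(bac_type: int, substrate: str,
                     p: SimulationParams) -> tuple[float, float] | None:
    """(summed rate constant k, Km) for one (type, substrate) pairing.

    Returns ``None`` for toxin1 detoxification, which is contact-limited
    rather than Michaelis–Menten and proceeds at the saturated velocity
    ``100 * k_toxin1``.  For PS the acetate and propionate branches draw on
    the same substrate, so their constants add.
    """
    ks = p.conversion_constants(bac_type)
    fb = p.feedbacks
    if substrate == "ps":
        return ks["ps_to_acetate"] + ks["ps_to_propionate"], _km_for("ps", p)
    if substrate == "ps_gut":
        return ks["psgut_to_acetate"], _km_for("ps_gut", p)
    if substrate == "acetate":
        k = ks["acetate_to_butyrate"]
        if "FB1" in fb.enabled:
            fb1_type = 1 if fb.orientation_inverted else 2
            if bac_type == fb1_type:
                k = k + fb.fb1_rate
        return k, _km_for("acetate", p)
    if substrate == "toxin1":
        return None
    return 0.0, 1.0


def total_uptake_rate(bac_type: int, substrate: str, conc,
                      p: SimulationParams, resistant=False):
    """Summed conversion velocity (mmol/h) of a bacterium on one substrate.

    Accepts scalar or array ``conc``/``resistant``.  Resistant bacteria pay
    the fitness cost: every rate is divided by the retardation constant Rc.
    """
    const = uptake_constants(bac_type, substrate, p)
    if const is None:
        rate = 100.0 * p.k_toxin1
        rate = np.broadcast_to(rate, np.shape(conc)).astype(float) \
            if np.ndim(conc) else rate
    else:
        k, km = const
        rate = 100.0 * k * np.asarray(conc, dtype=float) / (km + np.asarray(conc))
        if not np.ndim(conc):
            rate = float(rate)
    rc = p.resistance.retardation_constant_Rc
    if np.ndim(resistant):
        return np.where(resistant, rate / rc, rate)
    return rate / rc if resistant else rate


def product_for(bac_type: int, substrate: str, p: SimulationParams,
                rng: np.random.Generator) -> str | None:
    """Product kind for one consumed quantum (None = detoxified, no product).

    Where two branches compete for the same substrate the product is drawn
    proportionally to the branch rate constants.  Under FB1 the acetate
    branch of the toxin-producing type yields toxin1 with the configured
    percentage and butyrate otherwise.
    """
    ks = p.conversion_constants(bac_type)
    fb = p.feedbacks
    if substrate == "ps":
        ka, kp = ks["ps_to_acetate"], ks["ps_to_propionate"]
        if kp == 0.0:
            return "acetate"
        if ka == 0.0:
            return "propionate"
        return "acetate" if rng.random() < ka / (ka + kp) else "propionate"
    if substrate == "ps_gut":
        return "acetate"
    if substrate == "acetate":
        if "FB1" in fb.enabled:
            fb1_type = 1 if fb.orientation_inverted else 2
            if bac_type == fb1_type:
                if rng.random() * 100.0 < fb.fb1_toxin_percentage:
                    return "toxin1"
                return "butyrate"
        return "butyrate"
    if substrate == "toxin1":
        return None
    raise ValueError(f"inedible substrate {substrate!r}")


def consume_and_convert(b, local_particles, p: SimulationParams,
                        rng: np.random.Generator):
    """Reference per-bacterium feeding step over an explicit particle list.

    ``local_particles`` is a sequence of :class:`gutabm.environment.Particle`
    within contact range of ``b``.  At most one quantum is consumed per call
    (one tick), with probability ``rate*dt/quantum`` evaluated on the local
    concentration implied by the particle count.  Returns
    ``(remaining_particles, emitted_products, energy_gained)``.

    The vectorised engine implements the same event semantics over arrays;
    this function is the documented single-agent contract used by the tests.
    """
    kinds_here = {}
    for part in local_particles:
        kinds_here.setdefault(part.kind, []).append(part)
    edible = [k for k in edible_kinds(b.type, p) if k in kinds_here]
    if not edible:
        return list(local_particles), [], 0.0
    # nearest-edible preference: the caller passes contact-range particles,
    # so pick the kind with the closest member
    def dist(part):
        return (part.x - b.x) ** 2 + (part.y - b.y) ** 2
    target_kind = min(edible, key=lambda k: min(dist(q) for q in kinds_here[k]))
    conc = len(kinds_here[target_kind]) * p.particle_quantum * p.conc_mM_per_quantum
    rate = total_uptake_rate(b.type, target_kind, conc, p, resistant=b.resistant)
    prob = min(1.0, rate * p.tick_hours / p.particle_quantum)
    if rng.random() >= prob:
        return list(local_particles), [], 0.0
    eaten = min(kinds_here[target_kind], key=dist)
    remaining = [q for q in local_particles if q is not eaten]
    product = product_for(b.type, target_kind, p, rng)
    emitted = []
    if product is not None:
        from .environment import Particle
        emitted.append(Particle(product, b.x, b.y, p.particle_quantum))
    return remaining, emitted, eaten.quantum / p.particle_quantum
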