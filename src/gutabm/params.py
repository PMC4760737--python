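"""Model parameters: Table-level constants, config file I/O and validation.

All tunable constants of the simulator live in :class:`SimulationParams`.
Defaults encode the published constant set for the two-species SCFA
cross-feeding community (rate constants in mmol/h, Michaelis constants in
mM, lengths in µm, times in hours).  Parameters are read from a flat
``key = value`` text file at startup and can be written back as a run
manifest that round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

#: sentinel threshold meaning "resistant to this substance"
RESISTANT = math.inf

#: all recognised feedback mechanism names
ALL_FEEDBACKS = ("FB1", "FB2", "FB3", "FB4", "FB5", "FB6", "FB7")

#: passive particle kinds, in canonical (serialisation) order
PARTICLE_KINDS = (
    "ps", "ps_gut", "acetate", "propionate", "butyrate",
    "toxin1", "toxin2_vs1", "toxin2_vs2", "antibiotic",
)

#: SCFA kinds subject to MCT wall transport
SCFA_KINDS = ("acetate", "propionate", "butyrate")


def desk_scale_params(seed: int = 0) -> "SimulationParams":
    """Desk-scale study profile: the published rate constants and initial
    counts in a reduced gut (150 000 x 30 000 µm), 0.02 h ticks, strong
    lateral mixing (600 µm/tick) and a 3 mM-per-quantum concentration
    scale.  This is the regime used by the test suite and the experiment
    drivers: single runs take seconds and the base model reproduces its
    published failure mode at tractable horizons."""
    p = SimulationParams()
    p.gut_length_L = 150_000.0
    p.gut_width_D = 30_000.0
    p.tick_hours = 0.02
    p.jitter_step = 600.0
    p.conc_mM_per_quantum = 3.0
    p.rng_seed = int(seed)
    return p


class ConfigError(ValueError):
    """Raised when a parameter file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a loaded parameter set violates a model invariant."""


@dataclass
class FeedbackConfig:
    """Configuration of the seven feedback mechanisms.

    ``enabled`` lists the active mechanisms.  Thresholds are in agent
    counts (abundances) or substance quanta; emission rates in quanta per
    hour.  ``fb1_orientation_inverted`` (and the FB2/FB3 analogue) swap the
    producer/consumer roles of the two species, mirroring the inverted-edge
    variants examined alongside the canonical wiring.
    """

    enabled: tuple[str, ...] = ()
    fb1_toxin_percentage: float = 60.0      # % of type-2 acetate conversions yielding toxin1
    fb1_rate: float = 0.31                  # mmol/h, type-2 acetate uptake constant under FB1
    fb2_abundance_threshold: float = 100.0  # counts, N2 - N1 trigger
    fb3_abundance_threshold: float = 50.0   # counts, N2 - N1 trigger
    fb4_scfa_difference_threshold: float = 100.0  # quanta, sensed SCFA difference trigger
    fb4_sense: str = "propionate-butyrate"  # or "butyrate-propionate" (printed form)
    fb5_butyrate_threshold: float = 30.0    # quanta
    fb6_propionate_threshold: float = 100.0  # quanta
    fb7_butyrate_threshold: float = 300.0   # quanta
    gut_toxin_rate: float = 60.0            # quanta/h emitted while a gut FB condition holds
    fb7_ps_rate: float = 30.0               # quanta/h of host PS while FB7 condition holds
    orientation_inverted: bool = False      # swap species roles in FB1/FB2/FB3


@dataclass
class DoseSchedule:
    """Antibiotic course: dose rate during a gavage, frequency and period."""

    k_ant_intake: float = 0.0        # mmol/h while a gavage window is open (0 = no treatment)
    gavages_per_day: int = 1
    course_days: float = 3.0         # math.inf = continuous treatment
    course_start: float = 0.0        # hours
    gavage_duration: float = 1.0     # hours per gavage window

    @property
    def continuous(self) -> bool:
        return math.isinf(self.course_days)

    @property
    def course_end(self) -> float:
        """End of the course in hours (inf for continuous schedules)."""
        if self.continuous:
            return math.inf
        return self.course_start + self.course_days * 24.0


@dataclass
class ResistanceModel:
    """Resistance acquisition: fitness cost Rc and mutation-rate scale.

    A resistant bacterium's nutrient conversion rates are divided by the
    retardation constant ``Rc`` (>= 1).  On division, a sensitive daughter
    mutates with probability ``min(1, alpha * C / Rc)`` where ``C`` is the
    local antibiotic quanta count around the dividing parent.
    """

    retardation_constant_Rc: float = 2.0
    mutation_rate_scale_alpha: float = 0.5   # 1/quanta

    def mutation_probability(self, local_drug_quanta: float) -> float:
        p = self.mutation_rate_scale_alpha * local_drug_quanta / self.retardation_constant_Rc
        return min(1.0, max(0.0, p))


@dataclass
class SimulationParams:
    """The full external parameter set of the model.

    Rate constants and initial agent counts default to the published
    parameter table; geometry, tick length and the particle quantum are
    simulator-level conventions exposed for override.
    """

    # -- conversion rate constants, mmol/h (per bacterial type) -------------
    k_ps_to_acetate_1: float = 0.16
    k_ps_to_acetate_2: float = 0.16
    k_psgut_to_acetate_1: float = 0.16
    k_psgut_to_acetate_2: float = 0.0
    k_ps_to_propionate_1: float = 0.0
    k_ps_to_propionate_2: float = 0.26
    k_acetate_to_butyrate_1: float = 0.31
    k_acetate_to_butyrate_2: float = 0.0
    k_toxin1: float = 0.31          # substrate->toxin1 conversion (network-dependent)
    k_antitoxin1: float = 0.1       # 1/h toxin1 degradation
    k_antitoxin2: float = 0.1       # 1/h toxin2 degradation

    # -- lethal-dose sensitivity thresholds, quanta (inf = resistant) -------
    sensitive_toxin1_1: float = RESISTANT   # type 1 detoxifies toxin1
    sensitive_toxin1_2: float = 2.0
    sensitive_toxin2_1: float = 2.0
    sensitive_toxin2_2: float = 2.0
    sensitive_antibiotic_1: float = 2.0
    sensitive_antibiotic_2: float = 2.0

    # -- gut-level transport and intake -------------------------------------
    k_gut_out: float = 0.02         # 1/h clearance
    k_intake: float = 40.0          # mmol/h dietary polysaccharide
    k_ps_mucus: float = 1.0         # mmol/h host polysaccharide
    k_trans_mct: float = 8.3        # mmol/h MCT transport capacity
    km_acetate_mct: float = 15.0    # mM
    km_propionate_mct: float = 15.0  # mM
    km_butyrate_mct: float = 21.3   # mM
    km_acetate_conv: float = 15.0   # mM (conversion reactions; borrow transport Km)
    km_propionate_conv: float = 15.0
    km_butyrate_conv: float = 21.3

    # -- bacterial behaviour -------------------------------------------------
    search_radius_R: float = 3500.0   # µm, food search radius
    bacterial_speed: float = 7000.0   # µm/h
    eat_period: float = 8.0           # h between meals
    eat_range_multiplier_n: float = 3.0  # starvation limit ~ U(0, n*eat_period]
    contact_radius: float = 100.0     # µm, ingestion/toxin-contact radius
    division_threshold: float = 4.0   # quanta of converted substrate per division

    # -- initial agent counts ------------------------------------------------
    initial_bacteria_1: int = 400
    initial_bacteria_2: int = 400
    initial_resistant_fraction: float = 0.0  # per-type share starting resistant
    initial_ps: int = 1200
    initial_acetate: int = 200
    initial_propionate: int = 200
    initial_butyrate: int = 200

    # -- geometry and discretisation ----------------------------------------
    gut_length_L: float = 600_000.0   # µm
    gut_width_D: float = 60_000.0     # µm
    tick_hours: float = 0.01          # h per tick
    particle_quantum: float = 1.0     # mmol per passive agent
    jitter_step: float = 50.0         # µm lateral random step per tick
    conc_grid_nx: int = 20            # concentration-estimate grid cells
    conc_grid_ny: int = 10
    conc_mM_per_quantum: float = 1.0  # mM contributed by one quantum in one cell

    # -- sub-configurations --------------------------------------------------
    feedbacks: FeedbackConfig = field(default_factory=FeedbackConfig)
    antibiotic: DoseSchedule = field(default_factory=DoseSchedule)
    resistance: ResistanceModel = field(default_factory=ResistanceModel)

    rng_seed: int = 0

    # Mapping helpers -------------------------------------------------------

    def copy(self) -> "SimulationParams":
        return dataclasses.replace(
            self,
            feedbacks=dataclasses.replace(self.feedbacks),
            antibiotic=dataclasses.replace(self.antibiotic),
            resistance=dataclasses.replace(self.resistance),
        )

    def conversion_constants(self, bac_type: int) -> dict[str, float]:
        """Per-type substrate conversion constants (mmol/h)."""
        if bac_type == 1:
            return {
                "ps_to_acetate": self.k_ps_to_acetate_1,
                "psgut_to_acetate": self.k_psgut_to_acetate_1,
                "ps_to_propionate": self.k_ps_to_propionate_1,
                "acetate_to_butyrate": self.k_acetate_to_butyrate_1,
            }
        if bac_type == 2:
            return {
                "ps_to_acetate": self.k_ps_to_acetate_2,
                "psgut_to_acetate": self.k_psgut_to_acetate_2,
                "ps_to_propionate": self.k_ps_to_propionate_2,
                "acetate_to_butyrate": self.k_acetate_to_butyrate_2,
            }
        raise ValueError(f"unknown bacterial type {bac_type!r}")

    def sensitivity(self, bac_type: int, substance: str) -> float:
        key = f"sensitive_{substance}_{bac_type}"
        return getattr(self, key)


# ---------------------------------------------------------------------------
# flat key <-> dataclass mapping

_SUBCONFIGS = ("feedbacks", "antibiotic", "resistance")


def _leaf_fields() -> list[tuple[str, str | None, dataclasses.Field]]:
    """(flat key, subconfig name or None, field) for every scalar field."""
    out: list[tuple[str, str | None, dataclasses.Field]] = []
    for f in dataclasses.fields(SimulationParams):
        if f.name in _SUBCONFIGS:
            sub_cls = {"feedbacks": FeedbackConfig,
                       "antibiotic": DoseSchedule,
                       "resistance": ResistanceModel}[f.name]
            for sf in dataclasses.fields(sub_cls):
                out.append((sf.name, f.name, sf))
        else:
            out.append((f.name, None, f))
    return out


def as_flat_dict(p: SimulationParams) -> dict[str, object]:
    """Flatten a parameter set to the config-file key space."""
    flat: dict[str, object] = {}
    for key, sub, f in _leaf_fields():
        obj = getattr(p, sub) if sub else p
        flat[key] = getattr(obj, f.name)
    return flat


def _parse_value(key: str, raw: str) -> object:
    raw = raw.strip()
    if key == "enabled":
        if not raw or raw.lower() == "none":
            return ()
        names = tuple(s.strip().upper() for s in raw.split(",") if s.strip())
        for n in names:
            if n not in ALL_FEEDBACKS:
                raise ConfigError(f"unknown feedback name {n!r} in key 'enabled'")
        return names
    if key == "fb4_sense":
        if raw not in ("propionate-butyrate", "butyrate-propionate"):
            raise ConfigError(f"key {key!r}: unknown sense {raw!r}")
        return raw
    if key == "orientation_inverted":
        low = raw.lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ConfigError(f"key {key!r}: cannot parse boolean from {raw!r}")
    low = raw.lower()
    if low in ("inf", "+inf", "infinity", "resistant"):
        return math.inf
    try:
        if "." in raw or "e" in low or low == "nan":
            return float(raw)
        return int(raw)
    except ValueError:
        try:
            return float(raw)
        except ValueError as exc:
            raise ConfigError(f"key {key!r}: cannot parse value {raw!r}") from exc


def from_flat_dict(flat: dict[str, object]) -> SimulationParams:
    p = SimulationParams()
    known = {key: (sub, f) for key, sub, f in _leaf_fields()}
    for key, value in flat.items():
        if key not in known:
            raise ConfigError(f"unknown parameter key {key!r}")
        sub, f = known[key]
        target = getattr(p, sub) if sub else p
        # coerce ints written as floats and vice versa
        if f.type in ("int", int) and isinstance(value, float) and value.is_integer():
            value = int(value)
        if f.type in ("float", float) and isinstance(value, int):
            value = float(value)
        setattr(target, f.name, value)
    return p


def load_params(path: str | Path) -> SimulationParams:
    """Read a flat ``key = value`` parameter file.

    Omitted keys keep their defaults.  Raises :class:`ConfigError` on
    parse failures and :class:`ValidationError` if the resulting set
    violates a model invariant.
    """
    path = Path(path)
    flat: dict[str, object] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, raw = stripped.partition("=")
        key = key.strip()
        flat[key] = _parse_value(key, raw)
    p = from_flat_dict(flat)
    violations = validate_params(p)
    if violations:
        raise ValidationError("; ".join(violations))
    return p


def _fmt(value: object) -> str:
    if isinstance(value, tuple):
        return ",".join(value) if value else "none"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float) and math.isinf(value):
        return "inf"
    if isinstance(value, str):
        return value
    return repr(value)


def write_run_manifest(p: SimulationParams, path: str | Path) -> None:
    """Serialise every parameter (including rng_seed) to a reloadable file."""
    lines = ["# gutabm run manifest"]
    for key, value in as_flat_dict(p).items():
        lines.append(f"{key} = {_fmt(value)}")
    Path(path).write_text("\n".join(lines) + "\n")


def validate_params(p: SimulationParams) -> list[str]:
    """Return a list of invariant violations (empty iff the set is valid)."""
    v: list[str] = []

    def nonneg(name: str, value: float) -> None:
        if value < 0:
            v.append(f"{name} = {value}: must be non-negative")

    for name in (
        "k_ps_to_acetate_1", "k_ps_to_acetate_2", "k_psgut_to_acetate_1",
        "k_psgut_to_acetate_2", "k_ps_to_propionate_1", "k_ps_to_propionate_2",
        "k_acetate_to_butyrate_1", "k_acetate_to_butyrate_2", "k_toxin1",
        "k_antitoxin1", "k_antitoxin2", "k_gut_out", "k_intake", "k_ps_mucus",
        "k_trans_mct", "search_radius_R", "bacterial_speed", "contact_radius",
        "jitter_step",
    ):
        nonneg(name, getattr(p, name))
    for name in (
        "sensitive_toxin1_1", "sensitive_toxin1_2", "sensitive_toxin2_1",
        "sensitive_toxin2_2", "sensitive_antibiotic_1", "sensitive_antibiotic_2",
    ):
        nonneg(name, getattr(p, name))
    for name in (
        "km_acetate_mct", "km_propionate_mct", "km_butyrate_mct",
        "km_acetate_conv", "km_propionate_conv", "km_butyrate_conv",
    ):
        if getattr(p, name) <= 0:
            v.append(f"{name} = {getattr(p, name)}: Michaelis constant must be > 0")
    if p.eat_range_multiplier_n <= 0:
        v.append(f"eat_range_multiplier_n = {p.eat_range_multiplier_n}: must be > 0")
    if p.eat_period <= 0:
        v.append(f"eat_period = {p.eat_period}: must be > 0")
    if p.division_threshold <= 0:
        v.append(f"division_threshold = {p.division_threshold}: must be > 0")
    for name in ("gut_length_L", "gut_width_D", "tick_hours", "particle_quantum",
                 "conc_mM_per_quantum"):
        if getattr(p, name) <= 0:
            v.append(f"{name} = {getattr(p, name)}: must be > 0")
    for name in ("initial_bacteria_1", "initial_bacteria_2", "initial_ps",
                 "initial_acetate", "initial_propionate", "initial_butyrate"):
        if getattr(p, name) < 0:
            v.append(f"{name} = {getattr(p, name)}: must be non-negative")
    if p.conc_grid_nx < 1 or p.conc_grid_ny < 1:
        v.append("conc_grid_nx/conc_grid_ny: must be >= 1")
    if not 0.0 <= p.initial_resistant_fraction <= 1.0:
        v.append(f"initial_resistant_fraction = {p.initial_resistant_fraction}: "
                 "must be in [0, 1]")

    fb = p.feedbacks
    for n in fb.enabled:
        if n not in ALL_FEEDBACKS:
            v.append(f"feedbacks.enabled contains unknown mechanism {n!r}")
    if fb.fb4_sense not in ("propionate-butyrate", "butyrate-propionate"):
        v.append(f"feedbacks.fb4_sense = {fb.fb4_sense!r}: unknown sense")
    if not 0.0 <= fb.fb1_toxin_percentage <= 100.0:
        v.append(f"fb1_toxin_percentage = {fb.fb1_toxin_percentage}: must be in [0, 100]")
    for name in ("fb1_rate", "fb2_abundance_threshold", "fb3_abundance_threshold",
                 "fb4_scfa_difference_threshold", "fb5_butyrate_threshold",
                 "fb6_propionate_threshold", "fb7_butyrate_threshold",
                 "gut_toxin_rate", "fb7_ps_rate"):
        if getattr(fb, name) < 0:
            v.append(f"feedbacks.{name} = {getattr(fb, name)}: must be non-negative")

    ab = p.antibiotic
    if ab.k_ant_intake < 0:
        v.append(f"antibiotic.k_ant_intake = {ab.k_ant_intake}: must be non-negative")
    if ab.gavages_per_day < 1:
        v.append(f"antibiotic.gavages_per_day = {ab.gavages_per_day}: must be >= 1")
    if not (ab.course_days > 0):
        v.append(f"antibiotic.course_days = {ab.course_days}: must be > 0 (inf = continuous)")
    if ab.gavage_duration <= 0:
        v.append(f"antibiotic.gavage_duration = {ab.gavage_duration}: must be > 0")
    if ab.gavage_duration * ab.gavages_per_day > 24.0:
        v.append("antibiotic gavage windows exceed 24 h per day")

    rm = p.resistance
    if rm.retardation_constant_Rc < 1.0:
        v.append(f"resistance.retardation_constant_Rc = {rm.retardation_constant_Rc}: must be >= 1")
    if rm.mutation_rate_scale_alpha < 0:
        v.append(f"resistance.mutation_rate_scale_alpha = {rm.mutation_rate_scale_alpha}: "
                 "must be non-negative")

    # published zero constraints of the base network
    if p.k_ps_to_propionate_1 != 0.0:
        v.append("k_ps_to_propionate_1 must be 0 (type 1 does not produce propionate)")
    if p.k_acetate_to_butyrate_2 != 0.0:
        v.append("k_acetate_to_butyrate_2 must be 0 (type 2 does not ferment acetate "
                 "in the base network)")
    if p.k_psgut_to_acetate_2 != 0.0:
        v.append("k_psgut_to_acetate_2 must be 0 (host polysaccharide is digestible "
                 "only by type 1)")
    return v
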