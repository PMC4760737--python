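# Methods

`gutabm` is an agent-based model of a minimal gut microbial community: two
bacterial species that compete for dietary polysaccharide and cross-feed
through short-chain fatty acids (SCFAs) inside a two-dimensional virtual
gut, together with the feedback, antibiotic and resistance machinery needed
to study the community's stability, spatial structure and response to
perturbation.

## The model

**Agents.** Bacteria are active agents with a position, a hunger clock, an
energy store, accumulated toxin/drug loads and a resistance flag.
Metabolites (dietary polysaccharide `ps`, host polysaccharide `ps_gut`,
acetate, propionate, butyrate, two toxin families and antibiotic) are
passive agents: each carries one substance quantum (default 1 mmol) at a
position. The gut itself acts through boundary fluxes: nutrient entry,
wall absorption, outlet excretion and feedback-triggered emissions.

**Metabolic network.** Type 1 ferments `ps` and `ps_gut` to acetate
(k = 0.16 mmol/h each) and acetate to butyrate (k = 0.31); type 2 ferments
`ps` to acetate (0.16) and propionate (0.26). Host polysaccharide is
digestible only by type 1. Conversion velocities follow saturating
Michaelis–Menten kinetics `V = 100·k·[S]/(Km+[S])`. The Michaelis
constants of the conversion reactions are not independently constrained,
so they default to the corresponding transport constants (15.0 mM for the
acetate/propionate branches, 21.3 mM for butyrate).

**Event discretisation.** Continuum rates become per-tick Bernoulli events:
a bacterium in contact with a substrate consumes one quantum with
probability `V·dt/quantum` (capped at 1), emits one product quantum at its
own position (1:1 stoichiometry — the model tracks substance flow, not
yield), gains one energy unit and resets its hunger clock. Division
occurs at an energy threshold (default 4 quanta) and splits the parent
into two daughters with zero energy and freshly drawn starvation limits
`U(0, n·EatPeriod]`, n = 3. A bacterium whose hunger clock exceeds its
starvation limit dies. Where two bacteria claim the same particle in one
tick, priority is decided by a random permutation, which also serves as
the per-tick randomisation of agent order.

**Transport.** Particles are advected along the gut with
`v(y) = k_gut_out·L·(1 − |y − D/2|·2/D)²` — maximal on the centerline,
zero at the walls — jittered laterally by a uniform step with reflecting
walls, and excreted past `x = L`. SCFA particles inside the mucin zones
(outer fifths of the width) are absorbed through the shared, saturable
MCT transporter: the continuum flux
`k_trans·([C]/Km)/(1 + Σ[C_s]/Km_s)` is converted to a per-particle
absorption probability `min(1, rate·dt/local pool mass)`. The summed flux
saturates at `k_trans = 8.3 mM/h` for any concentrations, well inside the
physiological absorption cap of 33.2 mM/h. Local concentrations are
estimated on a fixed 20×10 grid with a configurable mM-per-quantum scale.
Bacteria are not advected; they move only by their own motility (7000
µm/h), pursuing the nearest edible particle within the search radius
(3500 µm) and eating within the contact radius (100 µm).

**Feedbacks.** Seven mechanisms can be enabled independently (FB1–FB7, see
`gutabm.feedbacks`): the toxin–antitoxin cross-feeding loop (FB1, the
acetate-consuming species converts acetate to a self-lethal toxin that the
partner detoxifies by eating), bacterial abundance control (FB2), and four
gut-mediated responses that emit toxins or host polysaccharide at the
walls when global abundance or metabolite conditions hold (FB3–FB7).
Toxins kill on reaching a lethal accumulation threshold (0–4 quanta, with
an infinite sentinel meaning immune) and decay spontaneously at the
antitoxin rates.

Because the published wiring statements conflict between the parameter
table and the pseudocode, this package follows the parameter table for the
base network (type 1 is the acetate consumer) and treats FB1 as granting
type 2 the acetate pathway; an orientation flag provides the inverted
variants. FB4's sensed SCFA difference is likewise a configuration choice
(`fb4_sense`): the default senses the dominant species' product
(propionate − butyrate), which is the functional equivalent of the printed
rule under this wiring; the literal printed direction remains available.

**Antibiotics and resistance.** A course is a sequence of daily gavage
windows (rate `k_ant_intake` mmol/h while open). Drug particles enter at
the inlet in the lumen, flow with the stream, and are taken into bacterial
bodies on contact; a sensitive bacterium dies when its accumulated load
reaches its lethal threshold and its body load is re-released at the death
site. Resistant bacteria absorb but never die of drug. On division each
sensitive daughter mutates to resistance with probability
`min(1, α·C/Rc)` where `C` is the antibiotic quanta within the parent's
contact neighbourhood — the linear-in-drug, cost-damped form is the
simplest that produces all three post-treatment outcome classes. The
fitness cost divides every conversion rate of a resistant cell by the
retardation constant `Rc ≥ 1` for life. Body contents (sub-lethal toxin
and sequestered drug) pass to one daughter at division so that substance
mass is conserved exactly.

**Accounting.** Every quantum movement is recorded in a per-kind ledger
(injected, produced, released, consumed, uptaken, absorbed, excreted,
decayed); at every tick the ledger closes exactly against the particle
pools, and drug inside bacteria equals uptaken − released. Births and
deaths by cause reconcile exactly with population deltas.

## Observables

The segregation index of a bacterium is its same-type fraction among all
bacteria within r = 30 000 µm; a zone index averages this over one type
inside one of the published gut areas (mucin layer, lumen, and border
bands that deliberately overlap the mucin/lumen boundary). The fast
implementation (spatial tree) is contractually identical to the all-pairs
definition and is tested against a brute-force oracle. Recovery time is
the lag from the end of a course until both species regain 80% of their
pre-treatment baseline (mean over the 100 h before the course); resilience
time is the first passage of either species below the critical count of
100 under continuous treatment; both return a censored marker when never
reached. Bistability is detected as the number of local maxima (above 10%
of the peak, on a 60×60 grid) of a Gaussian KDE over long-run (N1, N2)
means — the final third of each trajectory — from an initial-condition
sweep. A run is *steady* when both species' 1000-tick moving averages
stay above zero and within ±25% of their window means over the final third
of the run.

## Study conditions (desk-scale profile)

`desk_scale_params()` is the profile used by the test suite and the
experiment drivers, chosen once during model bring-up: a 150 000 × 30 000
µm gut, 0.02 h ticks, 600 µm/tick lateral jitter and a concentration scale
of 3 mM per quantum per grid cell, with all published rate constants,
behavioural parameters and initial counts (400 + 400 bacteria, 1200 PS,
200 of each SCFA) unchanged. In this regime single runs take seconds and
the base community reproduces its published failure mode: type 2 dominates
(it ferments shared polysaccharide 2.6× faster) while type 1 erodes, and
no steady state establishes. The full-scale geometry (600 000 × 60 000 µm)
remains the default of `SimulationParams` and is exercised by the
kinetics-level tests.

Feedback constants are not published (the supplementary table is not
reproduced in the text), so they are calibrated against the published
stability classification: the screen requires the basic model, FB2 and
FB5 to lose steadiness and FB1, FB3, FB4, FB6, FB7 to retain it across
seeds. The calibrated per-network constants live in
`gutabm.feedbacks.SCREEN_CALIBRATION` and are applied with
`apply_screen_calibration`; per-network toxin sensitivities and
degradation rates follow the parameter table's "network-dependent"
designation. Under this calibration the gut SCFA-difference mechanism
(FB4) is the one class whose steadiness remains borderline at desk
scale: it supports type 1 only indirectly, so the slow type-1 drift that
destabilises the basic model persists in a minority of seeds.

## Numerical choices

- Single `numpy` PCG64 generator per run; every stochastic step draws from
  it in a fixed order, so a run specification (including seed) reproduces
  its trajectory bit-for-bit across process restarts. Sweep cells derive
  child seeds from the base seed with `SeedSequence`.
- Fractional emission rates (mucus, gavage, gut feedbacks) accumulate
  across ticks and emit whole quanta, so long-run rates are exact.
- Degenerate inputs: empty worlds, empty zones and isolated bacteria are
  defined outcomes (no-ops or NaN/censored markers), not errors.
- Toxin/drug uptake is capped at 4 quanta per bacterium per tick, matching
  the upper end of the lethal-threshold range.
- The steadiness verdict depends on the evaluation horizon: the slow
  abundance drift that distinguishes unregulated from regulated
  communities only becomes visible after roughly 130 h, so the stability
  screen evaluates 200-h runs.

## What the synthetic fixtures do and do not show

Patterned snapshots (layered, checkerboard, mixed, two-cluster) and
template trajectories with exactly placed crossings exercise the
*definitions* of the observables — they carry no ecology. Conversely, the
emergent results (stability screen, bistability, resistance classes) are
produced only by full simulations at desk scale. Passing tests therefore
show that the definitions are implemented faithfully and that the desk-
scale community reproduces the qualitative published phenomena; they do
not calibrate the model against any real gut data, and absolute abundances
are not comparable to in vivo counts.

## Known limitations

- 2D geometry, no peristalsis, pH or oxygen fields; no biofilm matrix or
  adhesion mechanics; no intracellular metabolism or explicit biomass.
- One agent = one mmol is a bookkeeping convention; population sizes scale
  with it and with the concentration scale.
- The lateral jitter step is a per-tick convention, so spatial mixing is
  tied to the tick length; profiles should change both together.
- Resistance is a single heritable flag (no SNP/HGT distinction, no
  back-mutation); reversion is disabled.
- The desk-scale sweep grids are reduced relative to the published 14×14×3
  protocol; the full grid is available through the same drivers.
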