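"""The tick loop and experiment harness.

One tick applies, in order: (1) scheduled entries (meal, host mucus,
antibiotic gavage), (2) gut-mediated feedback emissions, (3) bacterial
actions (feed/move/divide/die, toxin and drug contact) with randomised
conflict resolution, (4) passive-particle transport, absorption and
excretion, (5) trajectory recording.  A single seeded generator drives
every random draw, so identical run specifications reproduce identical
trajectories across process restarts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import antibiotics, feedbacks, metabolism
from .agents import BacteriaArrays, draw_starvation_limit
from .environment import (GutWorld, host_mucus_step, inject_meal,
                          step_particles)
from .params import PARTICLE_KINDS, SimulationParams

__all__ = ["RunSpec", "RunResult", "new_world", "run",
           "sweep_initial_conditions", "resistance_parameter_map",
           "derive_seed", "long_run_means"]

#: maximum toxin/antibiotic quanta a bacterium can take up per tick
MAX_UPTAKE_PER_TICK = 4

#: daughter placement offset at division, µm
DIVISION_OFFSET = 20.0


@dataclass
class RunSpec:
    """A single experiment: parameters, duration and output cadence."""

    params: SimulationParams
    total_ticks: int = 10_000
    snapshot_every: int = 0          # 0 = final snapshot only
    tag: str = ""
    stop_below: float | None = None  # stop early when either type's count <= this

    def __post_init__(self):
        if self.total_ticks <= 0:
            raise ValueError("total_ticks must be > 0")


@dataclass
class RunResult:
    trajectory: pd.DataFrame
    snapshots: dict[int, pd.DataFrame] = field(default_factory=dict)
    world: GutWorld | None = None
    spec: RunSpec | None = None


def derive_seed(base_seed: int, *indices: int) -> int:
    """Deterministic, distinct child seed below 2**31 for a sweep cell."""
    ss = np.random.SeedSequence([int(base_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


def new_world(p: SimulationParams, rng: np.random.Generator) -> GutWorld:
    """Initial world: configured particle pools and uniform-random bacteria."""
    w = GutWorld(params=p)
    init = {"ps": p.initial_ps, "acetate": p.initial_acetate,
            "propionate": p.initial_propionate, "butyrate": p.initial_butyrate}
    for kind, n in init.items():
        if n > 0:
            w.add_particles(kind,
                            rng.uniform(0.0, p.gut_length_L, size=n),
                            rng.uniform(0.0, p.gut_width_D, size=n),
                            cause="injected")
    w.bacteria = BacteriaArrays.initial(p, rng)
    return w


def snapshot_table(w: GutWorld) -> pd.DataFrame:
    """Agent table (kind, type, x, y, resistant) for the current state."""
    frames = []
    pop = w.bacteria
    if pop is not None and len(pop):
        frames.append(pd.DataFrame({
            "kind": "bacterium", "type": pop.type.astype(int),
            "x": pop.x, "y": pop.y, "resistant": pop.resistant,
        }))
    for kind in PARTICLE_KINDS:
        pool = w.particles[kind]
        if len(pool):
            frames.append(pd.DataFrame({
                "kind": kind, "type": 0, "x": pool.x, "y": pool.y,
                "resistant": False,
            }))
    if not frames:
        return pd.DataFrame(columns=["kind", "type", "x", "y", "resistant"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# vectorised bacterial phase


def _feeding_step(w: GutWorld, p: SimulationParams, rng: np.random.Generator,
                  fb2_on: bool) -> None:
    """Food search, directed/random movement and conversion for all bacteria."""
    pop = w.bacteria
    n = len(pop)
    if n == 0:
        return
    dt = p.tick_hours
    step = p.bacterial_speed * dt

    conc_grids: dict[str, np.ndarray] = {}
    trees: dict[str, cKDTree] = {}

    def tree_for(kind: str) -> cKDTree | None:
        if kind not in trees:
            pool = w.particles[kind]
            trees[kind] = (cKDTree(np.column_stack([pool.x, pool.y]))
                           if len(pool) else None)
        return trees[kind]

    move_dx = np.zeros(n)
    move_dy = np.zeros(n)
    needs_random = np.zeros(n, dtype=bool)
    # claims[kind] = (bacteria indices, particle indices)
    claims: dict[str, list[np.ndarray]] = {}

    for bac_type in (1, 2):
        sel = np.flatnonzero(pop.type == bac_type)
        if sel.size == 0:
            continue
        pos = np.column_stack([pop.x[sel], pop.y[sel]])
        kinds = [k for k in metabolism.edible_kinds(bac_type, p)
                 if tree_for(k) is not None]
        if not kinds:
            needs_random[sel] = True
            continue
        dists = np.full((sel.size, len(kinds)), np.inf)
        idxs = np.zeros((sel.size, len(kinds)), dtype=np.intp)
        for j, kind in enumerate(kinds):
            d, i = tree_for(kind).query(pos, k=1)
            dists[:, j] = d
            idxs[:, j] = i
        best = np.argmin(dists, axis=1)
        rows = np.arange(sel.size)
        best_dist = dists[rows, best]
        best_idx = idxs[rows, best]

        in_contact = best_dist <= p.contact_radius
        in_search = (~in_contact) & (best_dist <= p.search_radius_R)
        lost = best_dist > p.search_radius_R
        needs_random[sel[lost]] = True

        # directed movement toward the nearest edible particle
        if np.any(in_search):
            tgt_sel = np.flatnonzero(in_search)
            for j, kind in enumerate(kinds):
                pick = tgt_sel[best[tgt_sel] == j]
                if pick.size == 0:
                    continue
                tdata = trees[kind].data[best_idx[pick]]
                dx = tdata[:, 0] - pos[pick, 0]
                dy = tdata[:, 1] - pos[pick, 1]
                dist = np.maximum(np.hypot(dx, dy), 1e-12)
                reach = np.minimum(step, dist)
                move_dx[sel[pick]] = dx / dist * reach
                move_dy[sel[pick]] = dy / dist * reach

        # conversion attempts within contact range
        if np.any(in_contact):
            con = np.flatnonzero(in_contact)
            gi = sel[con]
            ix, iy = w.cell_index(pop.x[gi], pop.y[gi])
            prob = np.zeros(con.size)
            for j, kind in enumerate(kinds):
                pick = con[best[con] == j]
                if pick.size == 0:
                    continue
                if kind not in conc_grids:
                    conc_grids[kind] = w.concentration_grid(kind)
                sub = np.flatnonzero(best[con] == j)
                conc = conc_grids[kind][ix[sub], iy[sub]]
                rate = metabolism.total_uptake_rate(
                    bac_type, kind, conc, p, resistant=pop.resistant[gi[sub]])
                prob[sub] = np.minimum(1.0, rate * dt / p.particle_quantum)
            success = rng.random(con.size) < prob
            for j, kind in enumerate(kinds):
                pick = con[(best[con] == j) & success]
                if pick.size == 0:
                    continue
                claims.setdefault(kind, []).append(
                    np.column_stack([sel[pick], best_idx[pick]]))

    # random-walk movement for bacteria with no target
    n_rand = int(np.count_nonzero(needs_random))
    if n_rand:
        theta = rng.uniform(0.0, 2.0 * math.pi, size=n_rand)
        move_dx[needs_random] = step * np.cos(theta)
        move_dy[needs_random] = step * np.sin(theta)

    pop.x = np.clip(pop.x + move_dx, 0.0, w.L)
    y = np.abs(pop.y + move_dy)
    pop.y = np.clip(np.where(y > w.D, 2.0 * w.D - y, y), 0.0, w.D)

    # resolve claims: one consumer per particle, randomised priority
    fb2_producers_x: list[np.ndarray] = []
    fb2_producers_y: list[np.ndarray] = []
    for kind, parts in claims.items():
        pairs = np.concatenate(parts, axis=0)
        order = rng.permutation(pairs.shape[0])
        pairs = pairs[order]
        _, first = np.unique(pairs[:, 1], return_index=True)
        winners_b = pairs[first, 0]
        winners_p = pairs[first, 1]

        pool = w.particles[kind]
        mask = np.zeros(len(pool), dtype=bool)
        mask[winners_p] = True
        pool.remove(mask)
        w.ledger.record(kind, "consumed", winners_p.size)

        pop.energy[winners_b] += 1.0
        pop.hunger[winners_b] = 0.0

        # product emission (1:1 stoichiometry; toxin1 detox emits nothing)
        bx, by = pop.x[winners_b], pop.y[winners_b]
        btype = pop.type[winners_b]
        if kind == "toxin1":
            pass
        elif kind == "ps_gut":
            w.add_particles("acetate", bx, by, cause="produced")
        elif kind == "ps":
            for t in (1, 2):
                m = btype == t
                if not np.any(m):
                    continue
                ks = p.conversion_constants(t)
                ka, kp = ks["ps_to_acetate"], ks["ps_to_propionate"]
                if kp == 0.0:
                    w.add_particles("acetate", bx[m], by[m], cause="produced")
                elif ka == 0.0:
                    w.add_particles("propionate", bx[m], by[m], cause="produced")
                else:
                    to_a = rng.random(int(np.count_nonzero(m))) < ka / (ka + kp)
                    if np.any(to_a):
                        w.add_particles("acetate", bx[m][to_a], by[m][to_a],
                                        cause="produced")
                    if np.any(~to_a):
                        w.add_particles("propionate", bx[m][~to_a], by[m][~to_a],
                                        cause="produced")
        elif kind == "acetate":
            fb = p.feedbacks
            fb1_type = (1 if fb.orientation_inverted else 2) \
                if "FB1" in fb.enabled else None
            m_fb1 = btype == fb1_type if fb1_type is not None \
                else np.zeros(btype.size, dtype=bool)
            if np.any(m_fb1):
                tox = rng.random(int(np.count_nonzero(m_fb1))) * 100.0 \
                    < fb.fb1_toxin_percentage
                if np.any(tox):
                    w.add_particles("toxin1", bx[m_fb1][tox], by[m_fb1][tox],
                                    cause="produced")
                if np.any(~tox):
                    w.add_particles("butyrate", bx[m_fb1][~tox], by[m_fb1][~tox],
                                    cause="produced")
            if np.any(~m_fb1):
                w.add_particles("butyrate", bx[~m_fb1], by[~m_fb1],
                                cause="produced")

        if fb2_on and kind in ("ps", "ps_gut"):
            producer = 2 if p.feedbacks.orientation_inverted else 1
            m = btype == producer
            if np.any(m):
                fb2_producers_x.append(bx[m])
                fb2_producers_y.append(by[m])

    if fb2_producers_x:
        feedbacks.fb2_bacterial_toxin_step(
            w, p.feedbacks, p,
            (np.concatenate(fb2_producers_x), np.concatenate(fb2_producers_y)))


def _uptake_step(w: GutWorld, p: SimulationParams,
                 rng: np.random.Generator) -> None:
    """Toxin and antibiotic contact: absorption into bacterial bodies."""
    pop = w.bacteria
    if pop is None or len(pop) == 0:
        return
    detox_type = 2 if ("FB1" in p.feedbacks.enabled
                       and p.feedbacks.orientation_inverted) else 1

    def victims_for(kind: str) -> np.ndarray:
        if kind == "toxin1":
            vuln = (pop.type != detox_type)
            thr = np.where(pop.type == 1, p.sensitive_toxin1_1, p.sensitive_toxin1_2)
            return vuln & np.isfinite(thr)
        if kind == "toxin2_vs1":
            return (pop.type == 1) & np.isfinite(np.full(len(pop), p.sensitive_toxin2_1))
        if kind == "toxin2_vs2":
            return (pop.type == 2) & np.isfinite(np.full(len(pop), p.sensitive_toxin2_2))
        if kind == "antibiotic":
            return np.ones(len(pop), dtype=bool)
        raise ValueError(kind)

    for kind, attr in (("toxin1", "acc_toxin1"), ("toxin2_vs1", "acc_toxin2"),
                       ("toxin2_vs2", "acc_toxin2"), ("antibiotic", "acc_drug")):
        pool = w.particles[kind]
        if len(pool) == 0:
            continue
        vic = np.flatnonzero(victims_for(kind))
        if vic.size == 0:
            continue
        tree = cKDTree(np.column_stack([pool.x, pool.y]))
        kq = min(MAX_UPTAKE_PER_TICK, len(pool))
        d, i = tree.query(np.column_stack([pop.x[vic], pop.y[vic]]),
                          k=kq, distance_upper_bound=p.contact_radius)
        d = np.atleast_2d(d.T).T if kq == 1 else d
        i = np.atleast_2d(i.T).T if kq == 1 else i
        valid = np.isfinite(d)
        if not np.any(valid):
            continue
        rows, cols = np.nonzero(valid)
        pairs = np.column_stack([vic[rows], i[rows, cols]])
        order = rng.permutation(pairs.shape[0])
        pairs = pairs[order]
        _, first = np.unique(pairs[:, 1], return_index=True)
        takers = pairs[first, 0]
        taken = pairs[first, 1]
        acc = getattr(pop, attr)
        np.add.at(acc, takers, 1.0)
        mask = np.zeros(len(pool), dtype=bool)
        mask[taken] = True
        pool.remove(mask)
        w.ledger.record(kind, "uptaken", taken.size)


def _death_step(w: GutWorld, p: SimulationParams) -> dict[str, int]:
    """Starvation, toxin and drug deaths; dead bodies release their drug."""
    pop = w.bacteria
    n = len(pop)
    if n == 0:
        return {}
    thr_t1 = np.where(pop.type == 1, p.sensitive_toxin1_1, p.sensitive_toxin1_2)
    thr_t2 = np.where(pop.type == 1, p.sensitive_toxin2_1, p.sensitive_toxin2_2)
    thr_ab = np.where(pop.type == 1, p.sensitive_antibiotic_1, p.sensitive_antibiotic_2)

    def lethal(acc, thr):
        return np.isfinite(thr) & (acc > 0) & (acc >= np.maximum(thr, 1.0))

    drug_dead = lethal(pop.acc_drug, thr_ab) & ~pop.resistant
    tox1_dead = lethal(pop.acc_toxin1, thr_t1)
    tox2_dead = lethal(pop.acc_toxin2, thr_t2)
    starved = pop.hunger > pop.starve_limit
    dead = drug_dead | tox1_dead | tox2_dead | starved
    if not np.any(dead):
        return {}

    causes: dict[str, int] = {}
    assigned = np.zeros(n, dtype=bool)
    for name, mask in (("antibiotic", drug_dead), ("toxin1", tox1_dead),
                       ("toxin2", tox2_dead), ("starved", starved)):
        for t in (1, 2):
            c = int(np.count_nonzero(mask & ~assigned & (pop.type == t)))
            if c:
                causes[f"deaths_{name}_{t}"] = c
        assigned |= mask

    # post-mortem drug release at the body position
    release = dead & (pop.acc_drug > 0)
    if np.any(release):
        counts = pop.acc_drug[release].astype(int)
        xs = np.repeat(pop.x[release], counts)
        ys = np.repeat(pop.y[release], counts)
        w.add_particles("antibiotic", xs, ys, cause="released")

    pop.select(~dead)
    return causes


def _division_step(w: GutWorld, p: SimulationParams,
                   rng: np.random.Generator) -> dict[str, int]:
    """Energy-threshold division with resistance mutation of daughters."""
    pop = w.bacteria
    parents = np.flatnonzero(pop.energy >= p.division_threshold)
    if parents.size == 0:
        return {}
    npar = parents.size

    drug_pool = w.particles["antibiotic"]
    if len(drug_pool):
        tree = cKDTree(np.column_stack([drug_pool.x, drug_pool.y]))
        local_c = np.asarray(tree.query_ball_point(
            np.column_stack([pop.x[parents], pop.y[parents]]),
            r=p.contact_radius, return_length=True), dtype=float)
    else:
        local_c = np.zeros(npar)

    daughters = BacteriaArrays(2 * npar)
    theta = rng.uniform(0.0, 2.0 * math.pi, size=2 * npar)
    px = np.repeat(pop.x[parents], 2)
    py = np.repeat(pop.y[parents], 2)
    daughters.x = np.clip(px + DIVISION_OFFSET * np.cos(theta), 0.0, w.L)
    daughters.y = np.clip(py + DIVISION_OFFSET * np.sin(theta), 0.0, w.D)
    daughters.type = np.repeat(pop.type[parents], 2)
    daughters.starve_limit = draw_starvation_limit(p, rng, size=2 * npar)
    # body contents (sub-lethal toxin and sequestered drug) stay with one
    # daughter so substance mass is conserved through division
    daughters.acc_drug[0::2] = pop.acc_drug[parents]
    daughters.acc_toxin1[0::2] = pop.acc_toxin1[parents]
    daughters.acc_toxin2[0::2] = pop.acc_toxin2[parents]

    p_mut = np.minimum(1.0, p.resistance.mutation_rate_scale_alpha * local_c
                       / p.resistance.retardation_constant_Rc)
    inherited = np.repeat(pop.resistant[parents], 2)
    mutated = rng.random(2 * npar) < np.repeat(p_mut, 2)
    daughters.resistant = inherited | (mutated & ~inherited)

    births = {f"births_{t}": int(np.count_nonzero(daughters.type == t) // 2)
              for t in (1, 2) if np.any(daughters.type == t)}
    keep = np.ones(len(pop), dtype=bool)
    keep[parents] = False
    pop.select(keep)
    pop.append(daughters)
    return births


# ---------------------------------------------------------------------------
# the run loop


def run(spec: RunSpec) -> RunResult:
    """Execute one simulation, returning the trajectory and snapshots."""
    p = spec.params
    rng = np.random.default_rng(p.rng_seed)
    w = new_world(p, rng)
    dt = p.tick_hours
    meal_every = max(1, int(round(p.eat_period / dt)))

    from .environment import MassLedger

    columns = (["tick", "hours", "n1_sens", "n1_res", "n2_sens", "n2_res"]
               + [f"p_{kind}" for kind in PARTICLE_KINDS])
    for t in (1, 2):
        columns.append(f"births_{t}")
        columns += [f"deaths_{cause}_{t}"
                    for cause in ("starved", "toxin1", "toxin2", "antibiotic")]
    columns += ["drug_injected", "drug_in_bacteria",
                "fb_FB3", "fb_FB4", "fb_FB5", "fb_FB6", "fb_FB7"]
    columns += list(MassLedger.COLUMNS)

    rows: list[list] = []
    snapshots: dict[int, pd.DataFrame] = {}

    for tick in range(spec.total_ticks):
        w.clock = tick * dt

        # (1) scheduled entries
        if tick % meal_every == 0:
            inject_meal(w, p, rng)
        host_mucus_step(w, p, dt, rng)
        drug_in = antibiotics.antibiotic_entry(w, p.antibiotic, w.clock, dt, rng)

        # (2) gut feedback emissions
        fb_emitted = feedbacks.gut_feedback_step(w, p.feedbacks, p, dt, rng)
        fb2_on = feedbacks.fb2_active(w, p.feedbacks)

        # (3) bacterial actions
        pop = w.bacteria
        events: dict[str, int] = {}
        if len(pop):
            pop.hunger += dt
            _feeding_step(w, p, rng, fb2_on)
            _uptake_step(w, p, rng)
            events.update(_death_step(w, p))
            events.update(_division_step(w, p, rng))

        # (4) passive transport
        step_particles(w, p, dt, rng)

        # (5) record
        c = pop.counts()
        row = [tick, round(w.clock, 10),
               c["n1_sens"], c["n1_res"], c["n2_sens"], c["n2_res"]]
        row += [w.count(kind) for kind in PARTICLE_KINDS]
        for t in (1, 2):
            row.append(events.get(f"births_{t}", 0))
            row += [events.get(f"deaths_{cause}_{t}", 0)
                    for cause in ("starved", "toxin1", "toxin2", "antibiotic")]
        row += [drug_in, int(np.sum(pop.acc_drug)) if len(pop) else 0]
        row += [fb_emitted.get(n, 0)
                for n in ("FB3", "FB4", "FB5", "FB6", "FB7")]
        row += w.ledger.as_values()
        rows.append(row)

        if spec.snapshot_every and (tick + 1) % spec.snapshot_every == 0:
            snapshots[tick + 1] = snapshot_table(w)

        if spec.stop_below is not None:
            if len(pop) == 0:
                break
            if (c["n1_sens"] + c["n1_res"] <= spec.stop_below
                    or c["n2_sens"] + c["n2_res"] <= spec.stop_below):
                break

    last_tick = rows[-1][0]
    w.clock = (last_tick + 1) * dt
    traj = pd.DataFrame(rows, columns=columns)
    snapshots.setdefault(last_tick + 1, snapshot_table(w))
    return RunResult(trajectory=traj, snapshots=snapshots, world=w, spec=spec)


# ---------------------------------------------------------------------------
# experiment drivers


def long_run_means(traj: pd.DataFrame, fraction: float = 1.0 / 3.0) -> tuple[float, float]:
    """Mean (N1, N2) over the final ``fraction`` of a trajectory."""
    tail = traj.iloc[int(len(traj) * (1.0 - fraction)):]
    n1 = (tail["n1_sens"] + tail["n1_res"]).mean()
    n2 = (tail["n2_sens"] + tail["n2_res"]).mean()
    return float(n1), float(n2)


def sweep_initial_conditions(base: RunSpec,
                             grid: tuple[int, ...] | None = None,
                             replicates: int = 3) -> pd.DataFrame:
    """Run the initial-condition grid and tabulate long-run states.

    The full published protocol enumerates initial counts 200..3000 in
    steps of 200 (14x14 cells, 3 replicates = 588 runs); a reduced grid
    can be passed for desk-scale sweeps.  Each run's seed derives
    deterministically from the base seed and its grid cell.
    """
    if grid is None:
        grid = tuple(range(200, 3001, 200))
    rows = []
    for i, n1_init in enumerate(grid):
        for j, n2_init in enumerate(grid):
            for rep in range(replicates):
                p = base.params.copy()
                p.initial_bacteria_1 = int(n1_init)
                p.initial_bacteria_2 = int(n2_init)
                p.rng_seed = derive_seed(base.params.rng_seed, i, j, rep)
                res = run(RunSpec(params=p, total_ticks=base.total_ticks,
                                  tag=f"sweep_{n1_init}_{n2_init}_{rep}"))
                n1, n2 = long_run_means(res.trajectory)
                rows.append({"n1_init": n1_init, "n2_init": n2_init,
                             "replicate": rep, "seed": p.rng_seed,
                             "n1_final": n1, "n2_final": n2})
    return pd.DataFrame(rows)


def resistance_parameter_map(base: RunSpec, rc_grid, dose_grid,
                             replicates: int = 3,
                             classification_window: float | None = None) -> pd.DataFrame:
    """Modal outcome class over the (Rc, dose) parameter plane.

    Each cell runs ``replicates`` seeded courses and classifies the
    post-treatment resistant fraction; the modal class is reported.
    """
    rows = []
    for i, rc in enumerate(rc_grid):
        for j, dose in enumerate(dose_grid):
            labels = []
            for rep in range(replicates):
                p = base.params.copy()
                p.resistance.retardation_constant_Rc = float(rc)
                p.antibiotic.k_ant_intake = float(dose)
                p.rng_seed = derive_seed(base.params.rng_seed, 1000 + i, j, rep)
                res = run(RunSpec(params=p, total_ticks=base.total_ticks))
                traj = res.trajectory
                r = traj["n1_res"] + traj["n2_res"]
                s = traj["n1_sens"] + traj["n2_sens"]
                with np.errstate(invalid="ignore"):
                    frac = np.where((r + s) > 0, r / (r + s), np.nan)
                labels.append(antibiotics.classify_outcome(
                    traj["hours"].to_numpy(), frac,
                    course_end=p.antibiotic.course_end,
                    window=classification_window,
                    course_length=p.antibiotic.course_days * 24.0,
                    resistant_counts=r.to_numpy()))
            vals, counts = np.unique(labels, return_counts=True)
            rows.append({"Rc": rc, "dose": dose,
                         "modal_class": int(vals[np.argmax(counts)]),
                         "labels": ",".join(str(x) for x in labels)})
    return pd.DataFrame(rows)
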