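"""Dosing schedules, drug lethality, mutation model, outcome classes."""

import math

import numpy as np
import pytest

from gutabm.agents import Bacterium
from gutabm.antibiotics import (DoseSchedule, InsufficientDataError,
                                ResistanceModel, antibiotic_entry,
                                classify_outcome, drug_uptake_and_death,
                                gavage_open, mutation_on_division)
from gutabm.environment import GutWorld, Particle
from gutabm.fixtures import make_trajectory
from gutabm.params import SimulationParams


class TestSchedule:
    def test_closed_before_course_start(self):
        s = DoseSchedule(k_ant_intake=10.0, course_start=48.0)
        assert not gavage_open(s, 47.9)
        assert gavage_open(s, 48.0)

    def test_three_day_once_daily_course_has_three_windows(self):
        s = DoseSchedule(k_ant_intake=10.0, gavages_per_day=1, course_days=3.0,
                         course_start=0.0, gavage_duration=1.0)
        hours = np.arange(0.0, 5 * 24.0, 0.05)
        open_ = np.array([gavage_open(s, h) for h in hours])
        n_windows = int(np.sum(np.diff(open_.astype(int)) == 1)) \
            + int(open_[0])
        assert n_windows == 3
        assert not open_[hours >= 72.0].any()

    def test_daily_mass_equal_when_dose_split(self, rng):
        """1x3h vs 3x1h at the same rate deliver the same daily drug mass."""
        p = SimulationParams()
        masses = []
        for gpd, dur in ((1, 3.0), (3, 1.0)):
            w = GutWorld(params=p)
            s = DoseSchedule(k_ant_intake=60.0, gavages_per_day=gpd,
                             course_days=1.0, gavage_duration=dur)
            total = sum(antibiotic_entry(w, s, h, 0.05, rng)
                        for h in np.arange(0.0, 24.0, 0.05))
            masses.append(total)
        assert masses[0] == masses[1] == 180   # 60 mmol/h * 3 h


class TestDrugUptake:
    def test_lethal_threshold_releases_quanta(self, params):
        b = Bacterium(type=1, x=5.0, y=5.0)   # sensitive_antibiotic_1 = 2
        parts = [Particle("antibiotic", 5.0, 5.0)] * 2
        out, released = drug_uptake_and_death(b, parts, params)
        assert out is None
        assert len(released) == 2
        assert all(q.kind == "antibiotic" for q in released)

    def test_resistant_absorbs_but_survives(self, params):
        b = Bacterium(type=1, x=0.0, y=0.0, resistant=True)
        parts = [Particle("antibiotic", 0.0, 0.0)] * 10
        out, released = drug_uptake_and_death(b, parts, params)
        assert out is b and released == []
        assert b.accumulated_antibiotic == 10

    def test_no_drug_no_change(self, params):
        b = Bacterium(type=2, x=0.0, y=0.0)
        out, released = drug_uptake_and_death(b, [], params)
        assert out is b and b.accumulated_antibiotic == 0.0


class TestMutation:
    def test_no_drug_no_mutation(self, rng):
        m = ResistanceModel(retardation_constant_Rc=2.0,
                            mutation_rate_scale_alpha=0.5)
        states = mutation_on_division(False, 0.0, m, rng)
        assert not states.any()

    def test_probability_saturates_at_boundary(self, rng):
        m = ResistanceModel(retardation_constant_Rc=2.0,
                            mutation_rate_scale_alpha=1.0)
        assert m.mutation_probability(2.0) == 1.0   # alpha*C == Rc
        states = mutation_on_division(False, 2.0, m, rng)
        assert states.all()

    def test_probability_halves_when_rc_doubles(self):
        lo = ResistanceModel(retardation_constant_Rc=1.0,
                             mutation_rate_scale_alpha=0.1)
        hi = ResistanceModel(retardation_constant_Rc=2.0,
                             mutation_rate_scale_alpha=0.1)
        assert hi.mutation_probability(3.0) \
            == pytest.approx(lo.mutation_probability(3.0) / 2.0, rel=1e-12)

    def test_resistant_parent_breeds_true(self, rng):
        m = ResistanceModel()
        assert mutation_on_division(True, 0.0, m, rng).all()


class TestClassification:
    def _frac(self, traj):
        r = traj["n1_res"] + traj["n2_res"]
        s = traj["n1_sens"] + traj["n2_sens"]
        return traj["hours"].to_numpy(), (r / (r + s)).to_numpy(), r.to_numpy()

    def test_resistant_domination_is_class_1(self):
        t, f, r = self._frac(make_trajectory("rising-R-fraction", T=50.0))
        assert classify_outcome(t, f, course_end=100.0, window=500.0,
                                resistant_counts=r) == 1

    def test_sensitive_recovery_is_class_3(self):
        t, f, r = self._frac(make_trajectory("decaying-R-fraction", T=50.0))
        assert classify_outcome(t, f, course_end=100.0, window=500.0,
                                resistant_counts=r) == 3

    def test_sustained_fluctuation_is_class_2(self):
        t, f, r = self._frac(make_trajectory("oscillating-R-fraction", T=50.0))
        assert classify_outcome(t, f, course_end=100.0, window=500.0,
                                resistant_counts=r) == 2

    def test_short_series_raises(self):
        t, f, r = self._frac(make_trajectory("rising-R-fraction", T=50.0,
                                             total_hours=300.0))
        with pytest.raises(InsufficientDataError):
            classify_outcome(t, f, course_end=100.0, window=500.0,
                             resistant_counts=r)

    def test_continuous_schedule_properties(self):
        s = DoseSchedule(k_ant_intake=5.0, course_days=math.inf)
        assert s.continuous and math.isinf(s.course_end)
        assert gavage_open(s, 24.0 * 41_667 + 0.5)   # in-window far in the future
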