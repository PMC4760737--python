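"""Transport kinetics, particle dynamics and the per-kind mass ledger."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutabm.environment import (GutWorld, axial_velocity, host_mucus_step,
                                inject_meal, step_particles,
                                wall_absorption_rate)
from gutabm.params import PARTICLE_KINDS, SCFA_KINDS, SimulationParams


def test_axial_velocity_profile(params):
    D, L, k = params.gut_width_D, params.gut_length_L, params.k_gut_out
    assert axial_velocity(0.0, params) == 0.0
    assert axial_velocity(D, params) == 0.0
    assert axial_velocity(D / 2.0, params) == pytest.approx(k * L)  # 12000 µm/h
    assert axial_velocity(D / 4.0, params) == pytest.approx(0.25 * k * L)


def test_axial_velocity_domain_error(params):
    with pytest.raises(ValueError):
        axial_velocity(-1.0, params)
    with pytest.raises(ValueError):
        axial_velocity(params.gut_width_D + 1.0, params)


def test_wall_absorption_hand_values(params):
    zero = {s: 0.0 for s in SCFA_KINDS}
    assert wall_absorption_rate(zero, "acetate", params) == 0.0
    # acetate at its Km, others zero: 8.3 * (15/15) / (1 + 15/15) = 4.15
    c = dict(zero, acetate=15.0)
    assert wall_absorption_rate(c, "acetate", params) == pytest.approx(4.15, rel=1e-12)
    # saturating limit -> k_trans_mct
    c = dict(zero, acetate=1e12)
    assert wall_absorption_rate(c, "acetate", params) == pytest.approx(8.3, rel=1e-9)


def test_wall_absorption_rejects_negative(params):
    with pytest.raises(ValueError):
        wall_absorption_rate({"acetate": -1.0}, "acetate", params)
    with pytest.raises(ValueError):
        wall_absorption_rate({}, "ps", params)


@settings(deadline=None, max_examples=60)
@given(a=st.floats(0, 1e6), b=st.floats(0, 1e6), c=st.floats(0, 1e6))
def test_summed_flux_below_transport_capacity_and_printed_cap(a, b, c):
    """The total SCFA absorption flux saturates strictly below k_trans_mct,
    hence below the published 33.2 mM/h bound."""
    p = SimulationParams()
    conc = {"acetate": a, "propionate": b, "butyrate": c}
    total = sum(wall_absorption_rate(conc, s, p) for s in SCFA_KINDS)
    assert total < p.k_trans_mct + 1e-12
    assert total <= 33.2


def test_step_particles_empty_world_unchanged(params, rng):
    w = GutWorld(params=params)
    step_particles(w, params, params.tick_hours, rng)
    assert all(w.count(k) == 0 for k in PARTICLE_KINDS)


def test_wall_particle_only_jitters(params, rng):
    w = GutWorld(params=params)
    w.add_particles("ps", [1000.0] * 50, [0.0] * 50, cause="injected")
    step_particles(w, params, params.tick_hours, rng)
    pool = w.particles["ps"]
    assert np.allclose(pool.x, 1000.0)          # zero advection at the wall
    assert np.all(np.abs(pool.y) <= params.jitter_step)


def test_centerline_advection_mean_displacement(params):
    """1000 centerline particles advance by k_gut_out*L*dt = 120 µm."""
    p = SimulationParams()
    p.jitter_step = 0.0
    rng = np.random.default_rng(0)
    w = GutWorld(params=p)
    w.add_particles("ps", [1000.0] * 1000, [p.gut_width_D / 2.0] * 1000,
                    cause="injected")
    step_particles(w, p, 0.01, rng)
    disp = w.particles["ps"].x - 1000.0
    assert np.allclose(disp, 0.02 * 600_000.0 * 0.01)  # 120 µm exactly


def test_outlet_excretion_logged(params, rng):
    w = GutWorld(params=params)
    w.add_particles("butyrate", [params.gut_length_L - 1.0] * 20,
                    [params.gut_width_D / 2.0] * 20, cause="injected")
    step_particles(w, params, 1.0, rng)
    assert w.count("butyrate") == 0
    assert w.ledger.counts["butyrate"]["excreted"] == 20
    assert w.ledger.net("butyrate") == 0


def test_mucin_scfa_absorption_conserves_ledger(rng):
    p = SimulationParams()
    p.jitter_step = 0.0
    w = GutWorld(params=p)
    # park acetate deep in the mucin zone; absorption should fire over time
    w.add_particles("acetate", list(np.linspace(1000, 2000, 400)), [100.0] * 400,
                    cause="injected")
    for _ in range(200):
        step_particles(w, p, 0.01, rng)
    c = w.ledger.counts["acetate"]
    assert c["absorbed"] > 0
    assert w.ledger.net("acetate") == w.count("acetate")


def test_inject_meal_quanta_count(params, rng):
    w = GutWorld(params=params)
    inject_meal(w, params, rng)
    # 40 mmol/h * 8 h / 1 mmol per quantum
    assert w.count("ps") == 320
    lumen = (w.particles["ps"].y >= params.gut_width_D / 5.0) \
        & (w.particles["ps"].y <= 4.0 * params.gut_width_D / 5.0)
    assert np.all(lumen)


def test_inject_meal_zero_intake(rng):
    p = SimulationParams()
    p.k_intake = 0.0
    w = GutWorld(params=p)
    inject_meal(w, p, rng)
    assert w.count("ps") == 0


def test_host_mucus_rate_is_exact_over_time(rng):
    p = SimulationParams()  # k_ps_mucus = 1 mmol/h
    w = GutWorld(params=p)
    for _ in range(100):    # 1 hour of 0.01 h ticks
        host_mucus_step(w, p, 0.01, rng)
    assert w.count("ps_gut") == 1
    band = p.gut_width_D / 10.0
    y = w.particles["ps_gut"].y
    assert np.all((y <= band) | (y >= p.gut_width_D - band))


def test_zone_intervals_match_published_split(params):
    w = GutWorld(params=params)
    D = params.gut_width_D
    z = w.zone_intervals()
    assert z["mucin_wall_low"] == (0.0, D / 5.0)
    assert z["mucin_wall_high"] == (4.0 * D / 5.0, D)
    assert z["lumen"] == (D / 5.0, 4.0 * D / 5.0)
    assert z["border_low"] == (2.0 * D / 15.0, 4.0 * D / 15.0)
    assert z["border_high"] == (11.0 * D / 15.0, 13.0 * D / 15.0)
    # the border bands straddle the mucin/lumen boundary (published overlap)
    assert z["border_low"][0] < D / 5.0 < z["border_low"][1]
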