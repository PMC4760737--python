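"""Segregation indices against a brute-force oracle, profiles, recovery,
resilience and bistability detection."""

import math

import numpy as np
import pandas as pd
import pytest

from gutabm.fixtures import FixtureSpec, make_snapshot, make_trajectory
from gutabm.observables import (CENSORED, bistability_histogram,
                                density_profile, per_cell_segregation,
                                recovery_time, resilience_time,
                                zone_partitions, zone_segregation)


def brute_force_zone_segregation(snapshot, zone, bac_type, r):
    """All-pairs reference implementation of the published definition."""
    bac = snapshot[snapshot["kind"] == "bacterium"]
    x = bac["x"].to_numpy(float)
    y = bac["y"].to_numpy(float)
    t = bac["type"].to_numpy(int)
    per = []
    for i in range(x.size):
        same = total = 0
        for j in range(x.size):
            if i == j:
                continue
            if (x[i] - x[j]) ** 2 + (y[i] - y[j]) ** 2 <= r * r:
                total += 1
                same += int(t[i] == t[j])
        per.append(same / total if total else math.nan)
    per = np.asarray(per)
    sel = (t == bac_type) & (y >= zone.y_low) & (y <= zone.y_high)
    vals = per[sel]
    vals = vals[np.isfinite(vals)]
    return float(np.mean(vals)) if vals.size else math.nan


def _snap(rows):
    return pd.DataFrame(rows, columns=["kind", "type", "x", "y", "resistant"])


class TestPerCellSegregation:
    def test_hand_micro_configurations(self):
        rows = [("bacterium", 1, 0.0, 0.0, False)] \
            + [("bacterium", 1, float(i), 0.0, False) for i in (1, 2)] \
            + [("bacterium", 2, 3.0, 0.0, False),
               ("bacterium", 2, 4.0, 0.0, False)]
        seg = per_cell_segregation(_snap(rows), r=10.0)
        assert seg[0] == pytest.approx(2 / 4)     # 2 same of 4 neighbours
        rows_same = [("bacterium", 1, float(i), 0.0, False) for i in range(5)]
        seg = per_cell_segregation(_snap(rows_same), r=10.0)
        assert np.allclose(seg, 1.0)

    def test_isolated_bacterium_undefined(self):
        rows = [("bacterium", 1, 0.0, 0.0, False),
                ("bacterium", 2, 1e9, 1e9, False)]
        seg = per_cell_segregation(_snap(rows), r=10.0)
        assert np.isnan(seg).all()


@pytest.mark.parametrize("pattern,seed", [
    ("uniform-mixed", 1), ("uniform-mixed", 2), ("layered", 3),
    ("checkerboard", 4), ("two-cluster", 5),
])
def test_zone_segregation_matches_bruteforce_oracle(pattern, seed):
    f = FixtureSpec(pattern=pattern, n_type1=120, n_type2=120,
                    gut_length_L=100_000.0, gut_width_D=30_000.0, seed=seed)
    snap = make_snapshot(f)
    zones = zone_partitions(f.gut_width_D)
    for zone in zones.values():
        for t in (1, 2):
            got = zone_segregation(snap, zone, t, r=8000.0)
            want = brute_force_zone_segregation(snap, zone, t, r=8000.0)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=0.0)


def test_fully_separated_clusters_score_one():
    f = FixtureSpec(pattern="two-cluster", n_type1=80, n_type2=80,
                    gut_length_L=600_000.0, gut_width_D=60_000.0, seed=9)
    snap = make_snapshot(f)  # clusters separated by 0.2 L = 120 000 µm > r
    lumen = zone_partitions(f.gut_width_D)["lumen"]
    assert zone_segregation(snap, lumen, 1, r=30_000.0) == 1.0
    assert zone_segregation(snap, lumen, 2, r=30_000.0) == 1.0


def test_checkerboard_is_half_mixed():
    f = FixtureSpec(pattern="checkerboard", n_type1=200, n_type2=200,
                    gut_length_L=100_000.0, gut_width_D=50_000.0, seed=0)
    snap = make_snapshot(f)
    lumen = zone_partitions(f.gut_width_D)["lumen"]
    assert zone_segregation(snap, lumen, 1, r=25_000.0) \
        == pytest.approx(0.5, abs=0.05)


def test_type_swap_symmetry():
    f = FixtureSpec(pattern="uniform-mixed", n_type1=90, n_type2=110, seed=6,
                    gut_length_L=100_000.0, gut_width_D=30_000.0)
    snap = make_snapshot(f)
    mirrored = snap.copy()
    mirrored["type"] = np.where(mirrored["type"] == 1, 2, 1)
    zones = zone_partitions(f.gut_width_D)
    for zone in zones.values():
        a = zone_segregation(snap, zone, 1, r=8000.0)
        b = zone_segregation(mirrored, zone, 2, r=8000.0)
        assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)


def test_translation_invariance_along_gut():
    f = FixtureSpec(pattern="uniform-mixed", n_type1=100, n_type2=100, seed=7,
                    gut_length_L=100_000.0, gut_width_D=30_000.0)
    snap = make_snapshot(f)
    shifted = snap.copy()
    shifted["x"] = shifted["x"] + 12_345.0
    lumen = zone_partitions(f.gut_width_D)["lumen"]
    assert zone_segregation(snap, lumen, 1, r=8000.0) \
        == zone_segregation(shifted, lumen, 1, r=8000.0)


class TestDensityProfile:
    def test_empty_snapshot_all_zero(self):
        prof = density_profile(_snap([]), axis="across", bins=10)
        assert (prof["type1"] == 0).all() and (prof["type2"] == 0).all()

    def test_layered_mass_in_wall_bins(self):
        f = FixtureSpec(pattern="layered", n_type1=100, n_type2=0,
                        gut_width_D=60_000.0, seed=1)
        snap = make_snapshot(f)
        prof = density_profile(snap, axis="across", bins=10, extent=60_000.0)
        wall = prof[(prof["bin_high"] <= 12_000.0)
                    | (prof["bin_low"] >= 48_000.0)]
        assert wall["type1"].sum() == 100

    def test_profile_sums_to_population(self):
        f = FixtureSpec(pattern="uniform-mixed", n_type1=73, n_type2=41, seed=2)
        snap = make_snapshot(f)
        for axis in ("along", "across"):
            prof = density_profile(snap, axis=axis, bins=17)
            assert prof["type1"].sum() == 73
            assert prof["type2"].sum() == 41

    def test_bins_validation(self):
        with pytest.raises(ValueError):
            density_profile(_snap([]), bins=1)


class TestRecoveryTime:
    def test_constructed_crossing(self):
        traj = make_trajectory("recovery-at-T", T=37.0)
        assert recovery_time(traj, course_end=100.0) == 37.0

    def test_untreated_run_recovers_immediately(self):
        traj = make_trajectory("recovery-at-T", T=37.0)
        flat = traj.copy()
        flat[["n1_sens", "n2_sens"]] = 1000.0
        flat["drug_injected"] = 0
        assert recovery_time(flat, course_end=100.0) == 0.0

    def test_pinned_series_censored(self):
        traj = make_trajectory("never-recover", T=37.0)
        assert recovery_time(traj, course_end=100.0) == CENSORED

    def test_course_end_outside_trajectory(self):
        traj = make_trajectory("recovery-at-T", T=37.0, total_hours=500.0)
        with pytest.raises(ValueError):
            recovery_time(traj, course_end=1e6)

    def test_monotone_in_recovery_fraction(self):
        traj = make_trajectory("recovery-at-T", T=37.0)
        t_strict = recovery_time(traj, 100.0, recovery_fraction=0.8)
        t_loose = recovery_time(traj, 100.0, recovery_fraction=0.7)
        assert t_loose <= t_strict


class TestResilienceTime:
    def test_already_below_threshold(self):
        traj = make_trajectory("hit-100-at-T", T=412.0)
        traj.loc[0, "n1_sens"] = 90.0
        assert resilience_time(traj) == 0.0

    def test_constructed_crossing(self):
        traj = make_trajectory("hit-100-at-T", T=412.0)
        assert resilience_time(traj) == 412.0

    def test_stable_run_censored(self):
        traj = make_trajectory("never-recover", T=1.0)
        assert resilience_time(traj) == CENSORED


class TestBistability:
    def test_two_gaussian_clusters_two_modes(self):
        rng = np.random.default_rng(5)
        a = rng.normal([200.0, 800.0], 30.0, size=(60, 2))
        b = rng.normal([900.0, 150.0], 30.0, size=(60, 2))
        n, density, _ = bistability_histogram(np.vstack([a, b]))
        assert n == 2

    def test_single_cluster_one_mode(self):
        rng = np.random.default_rng(6)
        pts = rng.normal([400.0, 400.0], 40.0, size=(80, 2))
        n, _, _ = bistability_histogram(pts)
        assert n == 1

    def test_insufficient_states_rejected(self):
        with pytest.raises(ValueError):
            bistability_histogram(np.zeros((10, 2)))
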