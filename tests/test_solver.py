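"""Annealing solver, exhaustive oracle, repeated runs and calibration."""

import itertools

import numpy as np
import pytest

import reefplan as rp
from reefplan.tessellation import PUStatus

from conftest import chain_tessellation, random_instance


def _singleton_instance():
    """One zero-cost PU holds the whole feature; another is a seed."""
    tess = chain_tessellation(5)
    for u in tess.units:
        u.cost = 1.0
    tess.units[2].cost = 0.0
    tess.units[4].status = PUStatus.SEED
    features = rp.FeatureTable(
        features=[rp.Feature(1, "habitat", 0.05)], amounts={1: {3: 0.05}}
    )
    sc = rp.ScenarioConfig(
        target_fraction=0.9, blm=0.0, spf=50.0, n_runs=1,
        iterations_per_run=2000, rng_seed=0,
    )
    return tess, features, sc


class TestAnneal:
    def test_finds_obvious_singleton(self):
        tess, features, sc = _singleton_instance()
        sol = rp.anneal(tess, features, sc, seed=1)
        assert sol.selected == {3, 5}  # the free PU holding the feature + seed

    def test_respects_lockouts_and_seeds(self):
        for seed in range(5):
            tess, features, sc = random_instance(seed)
            tess.units[0].status = PUStatus.SEED
            sol = rp.anneal(tess, features, sc, seed=seed)
            assert 1 in sol.selected
            for u in tess.units:
                if u.status is PUStatus.LOCKOUT:
                    assert u.id not in sol.selected

    def test_deterministic_given_seed(self):
        tess, features, sc = random_instance(3)
        a = rp.anneal(tess, features, sc, seed=42)
        b = rp.anneal(tess, features, sc, seed=42)
        assert a.selected == b.selected
        assert a.objective == b.objective

    def test_zero_temperature_descends_monotonically(self):
        """With no uphill acceptance the accepted-move trace never rises."""
        tess, features, sc = random_instance(7)
        schedule = rp.AnnealSchedule(t_init=0.0)
        sol = rp.anneal(
            tess, features, sc, schedule=schedule, seed=7, record_history=True
        )
        hist = sol.history
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_all_lockout_is_infeasible(self):
        tess = chain_tessellation(3)
        for u in tess.units:
            u.status = PUStatus.LOCKOUT
        features = rp.FeatureTable(features=[], amounts={})
        with pytest.raises(rp.InfeasibleInstanceError):
            rp.anneal(tess, features, rp.ScenarioConfig(), seed=0)


class TestBruteForce:
    def test_no_decision_units_returns_seeds_only(self):
        tess = chain_tessellation(3)
        tess.units[0].status = PUStatus.SEED
        tess.units[1].status = PUStatus.LOCKOUT
        tess.units[2].status = PUStatus.LOCKOUT
        features = rp.FeatureTable(features=[], amounts={})
        sol = rp.brute_force_optimum(tess, features, rp.ScenarioConfig())
        assert sol.selected == {1}

    def test_two_pu_instance_picks_feature_holder(self):
        tess = chain_tessellation(2)
        features = rp.FeatureTable(
            features=[rp.Feature(1, "habitat", 0.05)], amounts={1: {1: 0.05}}
        )
        sc = rp.ScenarioConfig(target_fraction=0.5, spf=50.0)
        sol = rp.brute_force_optimum(tess, features, sc)
        assert 1 in sol.selected and 2 not in sol.selected

    def test_matches_direct_enumeration(self):
        """Global optimum over every subset, enumerated independently."""
        tess, features, sc = random_instance(17, extent=(60.0, 80.0), n_lockout=0)
        ids = [u.id for u in tess.units]
        assert 2 <= len(ids) <= 12
        best_total = np.inf
        best_sets = []
        for r in range(len(ids) + 1):
            for combo in itertools.combinations(ids, r):
                total = rp.objective(set(combo), tess, features, sc).total
                if total < best_total - 1e-9:
                    best_total, best_sets = total, [set(combo)]
                elif abs(total - best_total) <= 1e-9:
                    best_sets.append(set(combo))
        sol = rp.brute_force_optimum(tess, features, sc)
        assert sol.objective.total == pytest.approx(best_total, abs=1e-9)
        assert sol.selected in best_sets

    def test_size_limit_enforced(self):
        tess = rp.build_hex_tessellation((200.0, 200.0), 15.0)
        features = rp.FeatureTable(features=[], amounts={})
        with pytest.raises(rp.InstanceSizeError):
            rp.brute_force_optimum(tess, features, rp.ScenarioConfig())


class TestRunRepeats:
    def test_single_run_scores_are_binary(self):
        tess, features, sc = random_instance(2)
        freq, _, _ = rp.run_repeats(tess, features, sc.replace(n_runs=1))
        assert set(np.unique(freq.score)) <= {0.0, 1000.0}

    def test_score_scaling(self):
        counts = np.array([750, 0, 1000])
        freq = rp.SelectionFrequency(
            pu_ids=np.array([1, 2, 3]), counts=counts, n_runs=1000
        )
        assert freq.score.tolist() == [750.0, 0.0, 1000.0]

    def test_frozen_master_seed_reproduces_frequencies(self):
        tess, features, sc = random_instance(4)
        sc = sc.replace(n_runs=8, iterations_per_run=2000)
        f1, b1, s1 = rp.run_repeats(tess, features, sc)
        f2, b2, s2 = rp.run_repeats(tess, features, sc)
        assert np.array_equal(f1.counts, f2.counts)
        assert b1.selected == b2.selected and s1 == s2

    def test_lockout_scores_zero_seed_scores_full(self):
        tess, features, sc = random_instance(5)
        tess.units[5].status = PUStatus.SEED
        freq, _, _ = rp.run_repeats(tess, features, sc.replace(n_runs=5))
        score = freq.score
        for u in tess.units:
            if u.status is PUStatus.LOCKOUT:
                assert score[u.id - 1] == 0.0
            if u.status is PUStatus.SEED:
                assert score[u.id - 1] == 1000.0


class TestCalibration:
    def test_single_point_grids_returned_verbatim(self):
        tess, features, sc = random_instance(6)
        sc = sc.replace(n_runs=3, iterations_per_run=3000, spf=100.0)
        res = rp.calibrate(tess, features, sc, blm_grid=[0.05], spf_grid=[100.0])
        assert res.blm == 0.05 and res.spf == 100.0
        assert len(res.table) == 2  # one spf row + one blm row

    def test_blm_zero_anchors_maximal_boundary(self):
        tess, features, sc = random_instance(8)
        sc = sc.replace(n_runs=4, iterations_per_run=3000)
        res = rp.calibrate(
            tess, features, sc, blm_grid=[0.0, 0.05, 0.5], spf_grid=[50.0]
        )
        blm_rows = res.table[res.table.parameter == "blm"].sort_values("value")
        boundaries = blm_rows.boundary.tolist()
        assert boundaries[0] == max(boundaries)

    def test_knee_matches_hand_geometry(self):
        """On a 3-point sweep the knee is the max-distance point by hand.

        Curve (boundary, cost): (10, 0), (4, 1), (0, 5); chord from (10, 0)
        to (0, 5): distances 0, ~2.24, 0 -> knee at the middle point.
        """
        from reefplan.solver import _knee_index

        x = np.array([10.0, 4.0, 0.0])
        y = np.array([0.0, 1.0, 5.0])
        assert _knee_index(x, y) == 1

    def test_unmeetable_targets_fail_loudly(self):
        tess, features, sc = random_instance(9)
        sc = sc.replace(n_runs=2, iterations_per_run=500)
        # SPF so small the penalty never forces the feature in
        with pytest.raises(rp.CalibrationError) as err:
            rp.calibrate(tess, features, sc, blm_grid=[0.0], spf_grid=[1e-9])
        assert not err.value.table.empty
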