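"""Objectives, nondominated filtering, the NSGA-II search and sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import caulocycle as cc
from caulocycle.fitting import (
    SENTINEL,
    CycleObjectives,
    hypervolume_2d,
    nondominated_filter,
    nondominated_mask,
    nsga2,
    perturbation_sensitivity,
)


class _StubTrajectory:
    """Minimal trajectory stand-in for misfit arithmetic tests."""

    def __init__(self, series):
        self.series = series

    def at(self, name, times):
        return np.asarray([self.series[name](t) for t in np.atleast_1d(times)])


def _stub_objectives(obs, params, box):
    return CycleObjectives(obs, params, box)


class TestMisfit:
    def test_hand_example_one_species_two_points(self, params, box, wt600):
        # sim [1, 2] vs obs [1, 3] -> mean squared error 0.5
        obs = cc.ObservationSet.from_raw(
            {"CtrA": (np.array([10.0, 20.0]), np.array([1.0, 3.0]))},
            ranges={"CtrA": (1.0, 3.0)},
        )
        objs = _stub_objectives(obs, params, box)
        stub = _StubTrajectory({"CtrA": lambda t: 1.0 if t < 15 else 2.0})
        assert objs.misfit(stub) == pytest.approx(0.5)

    def test_extra_perfect_species_changes_divisor_not_sum(self, params, box):
        obs1 = cc.ObservationSet.from_raw(
            {"CtrA": (np.array([10.0, 20.0]), np.array([1.0, 3.0]))},
            ranges={"CtrA": (1.0, 3.0)},
        )
        obs2 = cc.ObservationSet.from_raw(
            {
                "CtrA": (np.array([10.0, 20.0]), np.array([1.0, 3.0])),
                "DnaA": (np.array([10.0, 20.0]), np.array([5.0, 6.0])),
            },
            ranges={"CtrA": (1.0, 3.0), "DnaA": (5.0, 6.0)},
        )
        stub = _StubTrajectory({
            "CtrA": lambda t: 1.0 if t < 15 else 2.0,
            "DnaA": lambda t: 5.0 if t < 15 else 6.0,  # zero error
        })
        m1 = _stub_objectives(obs1, params, box).misfit(stub)
        m2 = _stub_objectives(obs2, params, box).misfit(stub)
        assert m1 == pytest.approx(0.5)
        assert m2 == pytest.approx(0.25)  # species mean halves

    def test_pooled_weighting_switch(self, params, box):
        obs = cc.ObservationSet.from_raw(
            {
                "CtrA": (np.array([10.0, 20.0]), np.array([1.0, 3.0])),
                "DnaA": (np.array([10.0, 20.0, 30.0, 40.0]), np.array([5.0, 6.0, 5.0, 6.0])),
            },
            ranges={"CtrA": (1.0, 3.0), "DnaA": (5.0, 6.0)},
        )
        stub = _StubTrajectory({
            "CtrA": lambda t: 1.0 if t < 15 else 2.0,
            "DnaA": lambda t: 5.5,
        })
        per = CycleObjectives(obs, params, box, weighting="per_species").misfit(stub)
        pooled = CycleObjectives(obs, params, box, weighting="pooled").misfit(stub)
        # per-species: mean(0.5, 0.25) = 0.375 ; pooled: (1 + 4*0.25)/6
        assert per == pytest.approx(0.375)
        assert pooled == pytest.approx(2.0 / 6.0)


class TestObjectivesOnModel:
    def test_truth_interpolates_noiseless_fixture(self, params, box, noiseless_obs):
        objs = CycleObjectives(noiseless_obs, params, box,
                               duration=700.0, rtol=1e-6, atol=1e-9)
        truth = np.array([params[n] for n in box.names])
        f1, f2 = objs(truth)
        assert f1 < 1e-12
        assert f2 <= 0.1  # published set holds the period at 150 min

    def test_arrested_candidate_gets_sentinel_period(self, params, box, noiseless_obs):
        objs = CycleObjectives(noiseless_obs, params, box,
                               duration=700.0, rtol=1e-6, atol=1e-9)
        chi = np.array([params[n] for n in box.names])
        chi[list(box.names).index("ks_dnaA")] = 0.0  # replication never initiates
        f1, f2 = objs(chi)
        assert f2 == SENTINEL
        assert f1 < SENTINEL  # the misfit itself is still well-defined


class TestNondominated:
    def test_exhaustive_example(self):
        ps = nondominated_filter([(1, 2), (2, 1), (2, 2)])
        assert sorted(map(tuple, ps.F)) == [(1, 2), (2, 1)]

    def test_singleton_and_identical_points(self):
        assert len(nondominated_filter([(3, 3)])) == 1
        assert len(nondominated_filter([(1, 1), (1, 1), (1, 1)])) == 3

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 8), st.integers(0, 8)),
                    min_size=1, max_size=40))
    def test_matches_bruteforce_dominance(self, points):
        F = np.asarray(points, dtype=float)
        mask = nondominated_mask(F)

        def dominated(i):
            return any(
                (F[j, 0] <= F[i, 0] and F[j, 1] <= F[i, 1])
                and (F[j, 0] < F[i, 0] or F[j, 1] < F[i, 1])
                for j in range(len(F))
            )

        for i in range(len(F)):
            assert mask[i] == (not dominated(i))


class TestNsga2:
    @staticmethod
    def _toy(x):
        return (float(x[0] ** 2), float((x[0] - 2.0) ** 2))

    def test_toy_front_hypervolume_within_5_percent(self):
        ref = (4.5, 4.5)
        xs = np.linspace(0, 2, 2001)[:, None]
        truth_hv = hypervolume_2d(np.array([self._toy(x) for x in xs]), ref)

        events = []
        res = nsga2(self._toy, [0.0], [2.0], pop_size=24, generations=30, seed=3,
                    callback=lambda gen, arch: events.append(
                        (arch.is_nondominated(), arch.hypervolume(ref))))
        got_hv = res.archive.hypervolume(ref)
        assert got_hv > 0.95 * truth_hv
        # archive nondominated after every generation, hypervolume monotone
        assert all(nd for nd, _ in events)
        hvs = [hv for _, hv in events]
        assert all(b >= a - 1e-12 for a, b in zip(hvs, hvs[1:]))

    def test_identical_seed_identical_archive(self):
        a = nsga2(self._toy, [0.0], [2.0], pop_size=12, generations=8, seed=5)
        b = nsga2(self._toy, [0.0], [2.0], pop_size=12, generations=8, seed=5)
        np.testing.assert_array_equal(a.archive.X, b.archive.X)
        np.testing.assert_array_equal(a.archive.F, b.archive.F)

    def test_solutions_stay_in_box(self):
        res = nsga2(self._toy, [0.5], [1.5], pop_size=10, generations=6, seed=1)
        assert np.all(res.archive.X >= 0.5) and np.all(res.archive.X <= 1.5)

    def test_infeasible_box_rejected(self):
        with pytest.raises(ValueError):
            nsga2(self._toy, [1.0], [1.0], pop_size=4, generations=2, seed=0)

    def test_seeding_with_published_set_keeps_low_f2(self, params, box, noiseless_obs):
        """A population seeded with the published parameter vector retains an
        archive point with f2 <= 0.1 min."""
        truth = np.array([params[n] for n in box.names])
        res = cc.optimize_mop(box, noiseless_obs, params,
                              population=8, generations=2, seed=0,
                              initial=truth, duration=700.0, rtol=1e-5, atol=1e-8)
        assert res.archive.F[:, 1].min() <= 0.1
        assert res.archive.is_nondominated()
        assert np.all(res.archive.X >= box.lower) and np.all(res.archive.X <= box.upper)


class TestSensitivity:
    def test_zero_magnitude_zero_change(self):
        out = perturbation_sensitivity(
            [np.array([1.0, 2.0])], 0.0,
            lambda x: (float(np.sum(x)), float(np.sum(x))),
            n_draws=4, seed=0, exclude_f2_below=0.0,
        )
        assert out["f1"] == 0.0 and out["f2"] == 0.0

    def test_linear_model_closed_form(self):
        # homogeneous linear objective: a 10 % perturbation changes it by 10 %
        out = perturbation_sensitivity(
            [np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])], 0.10,
            lambda x: (float(np.sum(x)), float(np.sum(x))),
            n_draws=6, seed=1, exclude_f2_below=0.0,
        )
        assert out["f1"] == pytest.approx(0.10, rel=1e-12)
        assert out["f2"] == pytest.approx(0.10, rel=1e-12)

    def test_near_zero_f2_points_excluded(self):
        out = perturbation_sensitivity(
            [np.array([1.0])], 0.1,
            lambda x: (float(x[0]), 1e-6),
            n_draws=3, seed=0,
        )
        assert out["n_f2"] == 0
        assert "below" in out["status"]


class TestRecovery:
    def test_five_parameters_recovered_from_noiseless_fixture(self, recovery_errors):
        """Perturb 5 randomly chosen free parameters by +-20 %, refit them
        against a noiseless self-fixture, recover within 10 % (majority of
        3 seeds)."""
        successes = sum(e < 0.10 for e in recovery_errors)
        assert successes >= 2
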