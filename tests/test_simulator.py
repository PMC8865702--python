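"""Hybrid integration, cycle metrics, limit-cycle behavior and the QSSA variant."""

import numpy as np
import pytest

import caulocycle as cc
from caulocycle.simulate import EventRecord, Trajectory


class TestSimulate:
    def test_wildtype_600min_has_at_least_three_initiations(self, wt600):
        assert len(wt600.event_times("initiation")) >= 3

    def test_zero_duration_returns_initial_state_only(self, params, init_state):
        traj = cc.simulate(params, init_state, duration=0.0)
        assert traj.t.shape == (1,)
        np.testing.assert_array_equal(traj.y[:, 0], init_state.y)

    def test_dense_sampling_at_most_one_minute(self, wt600):
        assert np.max(np.diff(wt600.t)) <= 1.0 + 1e-9

    def test_deterministic_given_inputs(self, params):
        a = cc.simulate(params, duration=400.0)
        b = cc.simulate(params, duration=400.0)
        np.testing.assert_array_equal(a.t, b.t)
        np.testing.assert_array_equal(a.y, b.y)

    def test_trajectory_nonnegative_and_ccka_pool_conserved(self, settled_wt, params):
        assert settled_wt.y.min() >= 0.0
        ckap = settled_wt.species("CckAP")
        assert np.all(ckap <= params.CckA_T + 1e-9)

    def test_hemimethylation_monotone_between_events(self, wt600):
        """h_* only decreases between events; upward jumps happen exactly at
        initiation/fork events."""
        ev_times = np.array([e.time for e in wt600.events])
        for name in ("hCori", "hccrM", "hctrA"):
            h = wt600.species(name)
            rising = np.flatnonzero(np.diff(h) > 1e-9)
            for i in rising:
                assert np.min(np.abs(ev_times - wt600.t[i])) < 1.0 + 1e-9

    def test_provenance_recorded(self, wt600, params):
        assert wt600.params_digest == params.digest()
        assert wt600.solver["rtol"] == 1e-6


class TestCyclePeriod:
    def test_synthetic_event_log(self, wt600):
        traj = Trajectory(
            t=np.array([0.0, 300.0]),
            y=np.zeros((len(cc.STATE_NAMES), 2)),
            ks_zring=np.zeros(2), dna=np.ones(2), count=np.ones(2, dtype=int),
            events=[EventRecord("initiation", t, i) for i, t in enumerate((0.0, 100.0, 200.0))],
            params_digest="synthetic",
        )
        cp = cc.cycle_period(traj, discard=0)
        assert cp.period == pytest.approx(100.0)

    def test_settled_wildtype_period_converges(self, settled_wt):
        cp = cc.cycle_period(settled_wt)
        assert cp.converged
        assert np.all(np.abs(np.diff(cp.intervals[-5:])) < 0.01 * cp.period)

    def test_arrested_run_raises(self, panel_trajectories):
        with pytest.raises(cc.ArrestedCycleError):
            cc.cycle_period(panel_trajectories["dnaA_del"])

    def test_period_robust_to_tolerance_tightening(self, params):
        a = cc.cycle_period(cc.simulate(params, duration=1500.0, rtol=1e-8, atol=1e-10))
        b = cc.cycle_period(cc.simulate(params, duration=1500.0, rtol=1e-9, atol=1e-11))
        assert abs(a.period - b.period) < 0.1


class TestSPhase:
    def test_interval_matches_linear_clock(self, settled_wt, params):
        got = cc.sphase_interval(settled_wt)
        assert got == pytest.approx(1.0 / params.ks_Zring_on, abs=1e-3)

    def test_doubling_clock_rate_halves_interval(self, params, init_state):
        fast = params.with_updates(ks_Zring_on=2 * params.ks_Zring_on)
        traj = cc.simulate(fast, init_state, duration=300.0, rtol=1e-6, atol=1e-9)
        assert cc.sphase_interval(traj) == pytest.approx(
            0.5 / params.ks_Zring_on, abs=1e-3
        )

    def test_arrested_run_has_no_interval(self, panel_trajectories):
        arrested = panel_trajectories["dnaA_del"]
        if len(arrested.event_times("zring")) == 0:
            with pytest.raises(cc.ArrestedCycleError):
                cc.sphase_interval(arrested)
        else:  # the single transient cycle may complete its constriction
            assert len(arrested.event_times("initiation")) <= 2


class TestLimitCycle:
    def test_cycle_over_cycle_closure(self, settled_wt):
        """After the transient, the state at successive initiation events
        repeats to within 2 % of each species' cycle amplitude."""
        inits = settled_wt.event_times("initiation")
        t1, t2 = inits[-2], inits[-1]
        sel = (settled_wt.t >= t1) & (settled_wt.t <= t2)
        for i, name in enumerate(cc.STATE_NAMES):
            series = settled_wt.y[i]
            amp = series[sel].max() - series[sel].min()
            scale = max(amp, 1e-6)
            a = np.interp(t1, settled_wt.t, series)
            b = np.interp(t2, settled_wt.t, series)
            assert abs(a - b) / scale < 0.02, name

    def test_successive_periods_within_one_percent(self, settled_wt):
        iv = cc.cycle_period(settled_wt).intervals
        assert np.all(np.abs(np.diff(iv)) / iv[1:] < 0.01)


class TestQssa:
    def test_period_agrees_with_full_model(self, qssa_pair):
        full, red = (cc.cycle_period(t) for t in qssa_pair)
        assert abs(red.period - full.period) / full.period < 0.05

    def test_fast_unbinding_limit_empties_complex3(self, params, init_state):
        fast = params.with_updates(k3_minus=1e6)
        a = cc.simulate(fast, init_state, duration=200.0, rtol=1e-6, atol=1e-9)
        b = cc.simulate_qssa(fast, init_state, duration=200.0, rtol=1e-6, atol=1e-9)
        assert a.species("Complex3")[-1] < 1e-3
        assert b.species("Complex3")[-1] < 1e-3

    def test_ctra_course_close_to_full_model(self, qssa_pair):
        # phase-aligned comparison over one settled cycle of each variant
        phase = np.linspace(0.0, 1.0, 200, endpoint=False)
        curves = []
        for traj in qssa_pair:
            inits = traj.event_times("initiation")
            t0, t1 = inits[-2], inits[-1]
            curves.append(traj.at("CtrA", t0 + phase * (t1 - t0)))
        cf, cq = curves
        # the reduction preserves the cycle's shape and timing; Complex3's
        # instantaneous equilibration does shave CtrA amplitude
        assert np.corrcoef(cf, cq)[0, 1] > 0.7
        ratio = np.ptp(cq) / np.ptp(cf)
        assert 1 / 3 < ratio < 3


class TestPhenotypeClassification:
    def test_wildtype_oscillatory(self, settled_wt):
        m = cc.classify_phenotype(settled_wt)
        assert m.phenotype == "oscillatory"
        assert m.period == pytest.approx(150.0, abs=0.5)

    def test_arrested_mutant(self, panel_trajectories):
        m = cc.classify_phenotype(panel_trajectories["dnaA_del"])
        assert m.phenotype == "arrested"
        assert m.period is None

    def test_metrics_table_covers_all_species(self, settled_wt):
        m = cc.classify_phenotype(settled_wt)
        assert set(m.species_range["species"]) == set(cc.STATE_NAMES)
        assert (m.species_range["amplitude"] >= 0).all()


class TestTrajectoryIO:
    def test_wide_and_long_tables_roundtrip_values(self, wt600):
        wide = wt600.to_frame()
        assert list(wide.columns[:1]) == ["time_min"]
        long = wt600.to_long()
        ctra = long[long.variable == "CtrA"]["value"].to_numpy()
        np.testing.assert_array_equal(ctra, wt600.species("CtrA"))

    def test_event_frame(self, wt600):
        ef = wt600.event_frame()
        assert {"event", "time_min", "cycle"} == set(ef.columns)
        assert (ef.time_min.diff().dropna() >= 0).all()
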